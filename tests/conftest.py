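"""Shared fixtures: tiny hand-built datasets and CSV writers."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pytest

from beeflora.data import Dataset


def make_dataset(sites, bees, plants, pollen) -> Dataset:
    """Build a validated Dataset from row tuples.

    sites: (point_id, landscape_id, habitat)
    bees: (bee_id, point_id, species)
    plants: (point_id, taxon) or (point_id, taxon, layer, abundance_code, entomophilous)
    pollen: (bee_id, pollen_taxon)
    """
    plant_rows = []
    for row in plants:
        if len(row) == 2:
            row = (*row, "herbaceous", "+", True)
        plant_rows.append(dict(zip(
            ("point_id", "taxon", "layer", "abundance_code", "entomophilous"), row
        )))
    ds = Dataset(
        sites=pd.DataFrame(sites, columns=["point_id", "landscape_id", "habitat"]),
        bees=pd.DataFrame(bees, columns=["bee_id", "point_id", "species"]),
        plants=pd.DataFrame(
            plant_rows,
            columns=["point_id", "taxon", "layer", "abundance_code", "entomophilous"],
        ),
        pollen=pd.DataFrame(pollen, columns=["bee_id", "pollen_taxon"]),
    )
    return ds.validate()


@pytest.fixture
def toy_dataset() -> Dataset:
    """3 points (one per habitat), 5 bees, 6 plant rows, 4 pollen rows."""
    return make_dataset(
        sites=[("p1", "L1", "hedgerow"), ("p2", "L1", "grassland"),
               ("p3", "L2", "forest_edge")],
        bees=[("b1", "p1", "Bombus a"), ("b2", "p1", "Bombus a"),
              ("b3", "p2", "Halictus b"), ("b4", "p2", "Bombus a"),
              ("b5", "p3", "Andrena c")],
        plants=[("p1", "Trifolium x"), ("p1", "Rosa y"), ("p2", "Trifolium x"),
                ("p2", "Lotus z"), ("p3", "Rosa y"), ("p3", "Hedera w")],
        pollen=[("b1", "Trifolium x"), ("b2", "Rosa y"), ("b3", "Trifolium x"),
                ("b5", "Hedera w")],
    )


@pytest.fixture
def toy_csv_dir(tmp_path: Path, toy_dataset: Dataset) -> Path:
    from beeflora.data import write_dataset

    write_dataset(toy_dataset, tmp_path)
    return tmp_path
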