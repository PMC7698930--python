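"""Bipartite bee-pollen network construction and habitat-removal robustness.

The study-site network has one edge per unique (bee species, pollen taxon)
pair, with a frequency (supporting record count) and the set of habitats
whose sampling points contributed the edge.  Robustness to losing one
habitat type is measured over equal-effort resampled networks: per
replicate, the same number of points is drawn per habitat without
replacement, a full and a reduced (habitat-removed) network are built, and
the percentages of remnant interactions / plant nodes / bee nodes recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace
from typing import Iterable

import numpy as np
import pandas as pd

from .data import (
    HABITATS,
    Dataset,
    InsufficientDataError,
    ValidationError,
)

logger = logging.getLogger("beeflora")


@dataclass(frozen=True)
class BipartiteNetwork:
    """Unique (bee species, pollen taxon) interactions with provenance.

    ``edges`` columns: bee_species, pollen_taxon, frequency, habitats
    (frozenset).  Node dicts map species -> habitat provenance.
    """

    edges: pd.DataFrame
    bee_nodes: dict[str, frozenset[str]]
    plant_nodes: dict[str, frozenset[str]]

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def abundant_species_filter(dataset: Dataset, min_individuals: int = 5) -> Dataset:
    """Keep bees (and their pollen loads) of species with >= min_individuals
    captures in the whole dataset (default 5, i.e. more than 4)."""
    counts = dataset.bees["species"].value_counts()
    kept_species = set(counts[counts >= min_individuals].index)
    bees = dataset.bees[dataset.bees["species"].isin(kept_species)].reset_index(drop=True)
    kept_bees = set(bees["bee_id"])
    pollen = dataset.pollen[dataset.pollen["bee_id"].isin(kept_bees)].reset_index(drop=True)
    logger.info(
        "abundance filter (>=%d): kept %d/%d species, %d/%d bees",
        min_individuals, len(kept_species), counts.size, len(bees), len(dataset.bees),
    )
    return dc_replace(dataset, bees=bees, pollen=pollen)


def _interaction_table(dataset: Dataset) -> pd.DataFrame:
    """One row per pollen record with bee species, point and habitat joined."""
    habitat = dataset.habitat_of()
    bees = dataset.bees.set_index("bee_id")
    table = dataset.pollen.copy()
    table["bee_species"] = table["bee_id"].map(bees["species"])
    table["point_id"] = table["bee_id"].map(bees["point_id"])
    table["habitat"] = table["point_id"].map(habitat)
    return table


def build_network(dataset: Dataset) -> BipartiteNetwork:
    """Aggregate pollen records into the unique-interaction network."""
    table = _interaction_table(dataset)
    if table.empty:
        raise InsufficientDataError("no pollen records to build a network from")
    grouped = (
        table.groupby(["bee_species", "pollen_taxon"])
        .agg(frequency=("bee_id", "size"), habitats=("habitat", lambda s: frozenset(s)))
        .reset_index()
    )
    bee_nodes = {
        sp: frozenset().union(*grouped.loc[grouped["bee_species"] == sp, "habitats"])
        for sp in grouped["bee_species"].unique()
    }
    plant_nodes = {
        tx: frozenset().union(*grouped.loc[grouped["pollen_taxon"] == tx, "habitats"])
        for tx in grouped["pollen_taxon"].unique()
    }
    return BipartiteNetwork(edges=grouped, bee_nodes=bee_nodes, plant_nodes=plant_nodes)


def unique_interaction_share(network: BipartiteNetwork, habitat_group: Iterable[str]) -> float:
    """Fraction of edges observed only at points of the given habitats."""
    group = frozenset(habitat_group)
    if network.n_edges == 0:
        raise InsufficientDataError("network has no edges")
    mask = network.edges["habitats"].map(lambda h: h <= group)
    return float(mask.mean())


@dataclass(frozen=True)
class RemovalResult:
    """Bootstrap distribution of remnant percentages after habitat removal."""

    removed_habitat: str
    n_boot: int
    subsample_size: int | None
    seed: int
    pct_remnant_interactions: np.ndarray
    pct_remnant_plants: np.ndarray
    pct_remnant_bees: np.ndarray

    def summary(self) -> dict[str, float]:
        return {
            "mean_pct_remnant_interactions": float(self.pct_remnant_interactions.mean()),
            "sd_pct_remnant_interactions": float(self.pct_remnant_interactions.std(ddof=1))
            if len(self.pct_remnant_interactions) > 1 else 0.0,
            "mean_pct_remnant_plants": float(self.pct_remnant_plants.mean()),
            "sd_pct_remnant_plants": float(self.pct_remnant_plants.std(ddof=1))
            if len(self.pct_remnant_plants) > 1 else 0.0,
            "mean_pct_remnant_bees": float(self.pct_remnant_bees.mean()),
            "sd_pct_remnant_bees": float(self.pct_remnant_bees.std(ddof=1))
            if len(self.pct_remnant_bees) > 1 else 0.0,
        }


def habitat_removal_robustness(
    dataset: Dataset,
    removed_habitat: str | Iterable[str],
    n_boot: int = 5000,
    subsample_size: int | None = 24,
    seed: int = 0,
    *,
    with_replacement: bool = False,
) -> RemovalResult:
    """Remnant interaction/species percentages after removing habitat(s).

    ``subsample_size=None`` disables resampling and computes a single
    deterministic replicate on all points.  The reference network of each
    replicate is rebuilt from that replicate's own subsampled points, so
    percentages compare equal sampling effort.
    """
    removed = (
        frozenset([removed_habitat]) if isinstance(removed_habitat, str)
        else frozenset(removed_habitat)
    )
    if not removed <= set(HABITATS):
        raise ValidationError(f"unknown habitat(s) {sorted(removed - set(HABITATS))}")
    table = _interaction_table(dataset)
    if table.empty:
        raise InsufficientDataError("no pollen records")

    # intern edges / nodes; boolean incidence of edges at each point
    edge_key = table["bee_species"] + "\x1f" + table["pollen_taxon"]
    edge_ids, edge_index = pd.factorize(edge_key)
    n_edges = len(edge_index)
    bee_of_edge = pd.factorize(
        pd.Series(edge_index).str.split("\x1f").str[0]
    )[0]
    plant_of_edge = pd.factorize(
        pd.Series(edge_index).str.split("\x1f").str[1]
    )[0]
    n_bees = bee_of_edge.max() + 1
    n_plants = plant_of_edge.max() + 1

    points = dataset.sites["point_id"].tolist()
    point_pos = {p: i for i, p in enumerate(points)}
    incidence = np.zeros((len(points), n_edges), dtype=bool)
    for pid, eid in zip(table["point_id"], edge_ids):
        incidence[point_pos[pid], eid] = True

    habitat_rows = {
        h: np.array([point_pos[p] for p in dataset.points_in(h)], dtype=int)
        for h in HABITATS
    }
    present_habitats = [h for h in HABITATS if len(habitat_rows[h])]

    rng = np.random.default_rng(seed)
    if subsample_size is None:
        replicate_rows = [np.arange(len(points))]
        n_rep = 1
    else:
        for h in present_habitats:
            if len(habitat_rows[h]) < subsample_size and not with_replacement:
                raise InsufficientDataError(
                    f"habitat {h!r} has {len(habitat_rows[h])} points; "
                    f"need >= {subsample_size}"
                )
        n_rep = n_boot
        replicate_rows = []
        for _ in range(n_rep):
            chosen = [
                rng.choice(habitat_rows[h], size=subsample_size, replace=with_replacement)
                for h in present_habitats
            ]
            replicate_rows.append(np.concatenate(chosen))
    logger.info(
        "habitat removal (%s): n_boot=%d subsample=%s seed=%d",
        sorted(removed), n_rep, subsample_size, seed,
    )

    removed_rows_set: set[int] = set()
    for h in removed:
        removed_rows_set.update(habitat_rows.get(h, ()))

    def n_live_nodes(edge_mask: np.ndarray, node_of_edge: np.ndarray, n_nodes: int) -> int:
        if not edge_mask.any():
            return 0
        return int((np.bincount(node_of_edge[edge_mask], minlength=n_nodes) > 0).sum())

    pct_edges = np.empty(n_rep)
    pct_plants = np.empty(n_rep)
    pct_bees = np.empty(n_rep)
    for i, rows in enumerate(replicate_rows):
        full_mask = incidence[rows].any(axis=0)
        kept_rows = np.array([r for r in rows if r not in removed_rows_set], dtype=int)
        reduced_mask = (
            incidence[kept_rows].any(axis=0) if len(kept_rows) else np.zeros(n_edges, bool)
        )
        n_full = int(full_mask.sum())
        if n_full == 0:  # replicate saw no interactions at all
            pct_edges[i] = pct_plants[i] = pct_bees[i] = 100.0
            continue
        pct_edges[i] = 100.0 * reduced_mask.sum() / n_full
        pct_bees[i] = 100.0 * (
            n_live_nodes(reduced_mask, bee_of_edge, n_bees)
            / n_live_nodes(full_mask, bee_of_edge, n_bees)
        )
        pct_plants[i] = 100.0 * (
            n_live_nodes(reduced_mask, plant_of_edge, n_plants)
            / n_live_nodes(full_mask, plant_of_edge, n_plants)
        )

    return RemovalResult(
        removed_habitat=";".join(sorted(removed)) if len(removed) != 1 else next(iter(removed)),
        n_boot=n_rep,
        subsample_size=subsample_size,
        seed=seed,
        pct_remnant_interactions=pct_edges,
        pct_remnant_plants=pct_plants,
        pct_remnant_bees=pct_bees,
    )
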