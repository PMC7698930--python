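"""Domain tables, CSV readers/writers, taxon harmonization, and shared errors.

The whole pipeline consumes four long-format tables:

* ``sites``  — one row per sampling point (``point_id, landscape_id, habitat``)
* ``bees``   — one row per captured individual (``bee_id, point_id, species``)
* ``plants`` — one row per plant occurrence
  (``point_id, taxon, layer, abundance_code, entomophilous``)
* ``pollen`` — one row per pollen taxon per bee (``bee_id, pollen_taxon``)

Braun-Blanquet abundance codes (including ``+`` and ``r``) are treated
strictly as presence; no code is ever used quantitatively.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger("beeflora")

HABITATS: tuple[str, ...] = ("hedgerow", "forest_edge", "grassland")
LAYERS: tuple[str, ...] = ("herbaceous", "shrub", "tree")

SITE_COLUMNS = ("point_id", "landscape_id", "habitat")
BEE_COLUMNS = ("bee_id", "point_id", "species")
PLANT_COLUMNS = ("point_id", "taxon", "layer", "abundance_code", "entomophilous")
POLLEN_COLUMNS = ("bee_id", "pollen_taxon")


class BeefloraError(Exception):
    """Base class for all package errors."""


class FormatError(BeefloraError):
    """A CSV file is missing declared columns or is otherwise unreadable."""


class ValidationError(BeefloraError):
    """Referential-integrity or enum-domain violation in a dataset."""


class ConfigurationError(BeefloraError):
    """Invalid configuration (bad mapping, degenerate simulation, ...)."""


class InsufficientDataError(BeefloraError):
    """An operation's preconditions on data volume are not met."""


class UndefinedDissimilarityError(BeefloraError):
    """Dissimilarity requested between two empty communities."""


def normalize_taxon(name: str) -> str:
    """Whitespace-collapsed, casefolded key used for taxon matching."""
    return " ".join(str(name).split()).casefold()


@dataclass
class Dataset:
    """Validated container for the four survey tables.

    ``taxon_map`` records the harmonization applied (raw -> harmonized);
    ``absent_from_flora`` lists harmonized pollen taxa with no flora match.
    """

    sites: pd.DataFrame
    bees: pd.DataFrame
    plants: pd.DataFrame
    pollen: pd.DataFrame
    taxon_map: dict[str, str] = field(default_factory=dict)
    absent_from_flora: frozenset[str] = frozenset()

    # -- derived views -------------------------------------------------

    def habitat_of(self) -> pd.Series:
        """point_id -> habitat."""
        return self.sites.set_index("point_id")["habitat"]

    def points_in(self, habitat: str) -> list[str]:
        if habitat not in HABITATS:
            raise ValidationError(f"unknown habitat {habitat!r}")
        return self.sites.loc[self.sites["habitat"] == habitat, "point_id"].tolist()

    def plant_presence(self, entomophilous_only: bool = True) -> pd.DataFrame:
        """Unique (point_id, taxon) presence records, layers collapsed.

        A taxon recorded in several layers at one point counts once; any
        Braun-Blanquet code (or none) is presence.
        """
        plants = self.plants
        if entomophilous_only and "entomophilous" in plants.columns:
            plants = plants[plants["entomophilous"].astype(bool)]
        return plants[["point_id", "taxon"]].drop_duplicates(ignore_index=True)

    def validate(self) -> "Dataset":
        """Raise :class:`ValidationError` on any integrity violation."""
        _check_columns(self.sites, SITE_COLUMNS, "sites")
        _check_columns(self.bees, BEE_COLUMNS, "bees")
        _check_columns(self.plants, PLANT_COLUMNS[:2], "plants")
        _check_columns(self.pollen, POLLEN_COLUMNS, "pollen")

        dup_points = self.sites["point_id"][self.sites["point_id"].duplicated()]
        if len(dup_points):
            raise ValidationError(f"duplicate point_id values: {sorted(set(dup_points))}")
        bad_hab = self.sites.loc[~self.sites["habitat"].isin(HABITATS)]
        if len(bad_hab):
            raise ValidationError(
                "unknown habitat values "
                f"{sorted(set(bad_hab['habitat']))} at rows {bad_hab.index.tolist()}"
            )
        dup_bees = self.bees["bee_id"][self.bees["bee_id"].duplicated()]
        if len(dup_bees):
            raise ValidationError(f"duplicate bee_id values: {sorted(set(dup_bees))}")

        known_points = set(self.sites["point_id"])
        orphan = self.bees.loc[~self.bees["point_id"].isin(known_points)]
        if len(orphan):
            raise ValidationError(
                f"bees reference unknown point_id {sorted(set(orphan['point_id']))} "
                f"at rows {orphan.index.tolist()}"
            )
        orphan = self.plants.loc[~self.plants["point_id"].isin(known_points)]
        if len(orphan):
            raise ValidationError(
                f"plants reference unknown point_id {sorted(set(orphan['point_id']))} "
                f"at rows {orphan.index.tolist()}"
            )
        known_bees = set(self.bees["bee_id"])
        orphan = self.pollen.loc[~self.pollen["bee_id"].isin(known_bees)]
        if len(orphan):
            raise ValidationError(
                f"pollen references unknown bee_id {sorted(set(orphan['bee_id']))} "
                f"at rows {orphan.index.tolist()}"
            )
        dup = self.pollen[self.pollen.duplicated(subset=["bee_id", "pollen_taxon"])]
        if len(dup):
            raise ValidationError(
                f"duplicate (bee_id, pollen_taxon) rows at {dup.index.tolist()}"
            )
        return self


def _check_columns(df: pd.DataFrame, required: Iterable[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"table {name!r} is missing columns {missing}")


def read_dataset(
    sites_path: str | Path,
    bees_path: str | Path,
    plants_path: str | Path,
    pollen_path: str | Path,
) -> Dataset:
    """Read and validate the four CSV tables (UTF-8, comma, header row)."""
    frames = {}
    for name, path, required in (
        ("sites", sites_path, SITE_COLUMNS),
        ("bees", bees_path, BEE_COLUMNS),
        ("plants", plants_path, PLANT_COLUMNS[:2]),
        ("pollen", pollen_path, POLLEN_COLUMNS),
    ):
        path = Path(path)
        if not path.exists():
            raise FormatError(f"input file for table {name!r} not found: {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
        _check_columns(df, required, name)
        frames[name] = df

    plants = frames["plants"]
    if "entomophilous" not in plants.columns:
        plants["entomophilous"] = True
    else:
        plants["entomophilous"] = plants["entomophilous"].map(_parse_bool)
    if "layer" not in plants.columns:
        plants["layer"] = ""
    if "abundance_code" not in plants.columns:
        plants["abundance_code"] = ""

    ds = Dataset(
        sites=frames["sites"], bees=frames["bees"], plants=plants, pollen=frames["pollen"]
    )
    ds.validate()
    logger.info(
        "read dataset: %d points, %d bees, %d plant rows, %d pollen rows",
        len(ds.sites), len(ds.bees), len(ds.plants), len(ds.pollen),
    )
    return ds


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().casefold()
    if text in ("true", "1", "yes", "t", "y"):
        return True
    if text in ("false", "0", "no", "f", "n", ""):
        return False
    raise FormatError(f"cannot parse boolean value {value!r} in 'entomophilous'")


def write_dataset(dataset: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the four tables as CSV; returns table name -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sites": out_dir / "sites.csv",
        "bees": out_dir / "bees.csv",
        "plants": out_dir / "plants.csv",
        "pollen": out_dir / "pollen.csv",
    }
    dataset.sites.to_csv(paths["sites"], index=False)
    dataset.bees.to_csv(paths["bees"], index=False)
    dataset.plants.to_csv(paths["plants"], index=False)
    dataset.pollen.to_csv(paths["pollen"], index=False)
    return paths


def harmonize_taxa(dataset: Dataset, genus_merges: Mapping[str, str]) -> Dataset:
    """Apply raw -> harmonized taxon renames to plant and pollen tables.

    Matching is case-insensitive after whitespace normalization.  The
    mapping must be closed (no target is itself remapped), so applying it
    twice equals applying it once.  Pollen taxa with no flora match after
    harmonization are recorded in ``absent_from_flora``.
    """
    lookup: dict[str, str] = {}
    for raw, target in genus_merges.items():
        key = normalize_taxon(raw)
        target = " ".join(str(target).split())
        if key in lookup and lookup[key] != target:
            raise ConfigurationError(
                f"conflicting merges for {raw!r}: {lookup[key]!r} vs {target!r}"
            )
        lookup[key] = target
    for target in lookup.values():
        tkey = normalize_taxon(target)
        if tkey in lookup and normalize_taxon(lookup[tkey]) != tkey:
            raise ConfigurationError(
                f"chained/cyclic merge: target {target!r} is itself remapped to "
                f"{lookup[tkey]!r}"
            )

    def rename(series: pd.Series) -> pd.Series:
        return series.map(lambda t: lookup.get(normalize_taxon(t), t))

    plants = dataset.plants.copy()
    plants["taxon"] = rename(plants["taxon"])
    plants = plants.drop_duplicates(subset=["point_id", "taxon", "layer"], ignore_index=True)
    pollen = dataset.pollen.copy()
    pollen["pollen_taxon"] = rename(pollen["pollen_taxon"])
    pollen = pollen.drop_duplicates(subset=["bee_id", "pollen_taxon"], ignore_index=True)

    flora_keys = {normalize_taxon(t) for t in plants["taxon"]}
    absent = frozenset(
        t for t in pollen["pollen_taxon"].unique() if normalize_taxon(t) not in flora_keys
    )
    if absent:
        logger.info("%d pollen taxa absent from flora: %s", len(absent), sorted(absent))
    return replace(
        dataset,
        plants=plants,
        pollen=pollen,
        taxon_map=dict(genus_merges),
        absent_from_flora=absent,
    )


def file_checksum(path: str | Path) -> str:
    """SHA-256 of a file, for run manifests."""
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()
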