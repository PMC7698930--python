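"""Synthetic survey datasets with known ground truth.

Habitat species pools are built from an explicit shared core plus
habitat-exclusive taxa, so the true shared/unique counts between any two
pooled habitat communities are known exactly.  Bee pollen loads are drawn
with probability proportional to (bee-species preference x local plant
availability), making resource-selection recovery testable.

One seed drives four documented sub-streams, spawned in a fixed order:
design (which habitats each landscape has), plants, bees, pollen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data import HABITATS, ConfigurationError, Dataset
from .diversity import BetaPartition, baselga_partition

logger = logging.getLogger("beeflora")

DEFAULT_POLLEN_RICHNESS = {0: 0.15, 1: 0.55, 2: 0.25, 3: 0.05}
_BB_CODES = ("r", "+", "1", "2", "3", "4", "5")


@dataclass
class SimulationConfig:
    """Knobs of the generator; all probabilities must lie in [0, 1]."""

    n_landscapes: int = 30
    habitat_missingness: Mapping[str, float] = field(
        default_factory=lambda: {h: 0.0 for h in HABITATS}
    )
    # exact per-habitat site counts override missingness when given
    exact_site_counts: Mapping[str, int] | None = None
    plant_pool_size: int = 60
    plant_pool_overlap: float = 0.5
    bee_pool_size: int = 25
    bee_pool_overlap: float = 0.5
    detection_prob: float = 0.5
    entomophilous_fraction: float = 1.0
    bee_abundance_mean: Mapping[str, float] = field(
        default_factory=lambda: {"hedgerow": 4.0, "forest_edge": 4.8, "grassland": 10.1}
    )
    # None => per-taxon uniform; otherwise bee-species x plant-taxon weights
    preference: pd.DataFrame | None = None
    pollen_richness_dist: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_POLLEN_RICHNESS)
    )
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        probs = [self.detection_prob, self.entomophilous_fraction,
                 *self.habitat_missingness.values(), *self.pollen_richness_dist.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigurationError("all probabilities must be in [0, 1]")
        if not (0.0 <= self.plant_pool_overlap <= 1.0 and 0.0 <= self.bee_pool_overlap <= 1.0):
            raise ConfigurationError("pool overlaps must be in [0, 1]")
        if self.plant_pool_size < 1 or self.bee_pool_size < 1:
            raise ConfigurationError("species pools must be non-empty")
        if self.n_landscapes < 1:
            raise ConfigurationError("need at least one landscape")
        total = sum(self.pollen_richness_dist.values())
        if not np.isclose(total, 1.0):
            raise ConfigurationError("pollen_richness_dist must sum to 1")
        if self.preference is not None:
            if (self.preference.to_numpy() < 0).any():
                raise ConfigurationError("preference weights must be non-negative")
            if not self.preference.to_numpy().sum() > 0:
                raise ConfigurationError("preference matrix is all zeros")
        return self


@dataclass
class GroundTruth:
    """What the generator knows that an analyst would have to estimate."""

    plant_pools: dict[str, frozenset[str]]
    bee_pools: dict[str, frozenset[str]]
    preference: pd.DataFrame
    expected_plant_beta: dict[tuple[str, str], BetaPartition]
    expected_bee_beta: dict[tuple[str, str], BetaPartition]
    seed: int

    def to_jsonable(self) -> dict:
        def beta_map(d):
            return {
                f"{h1}|{h2}": {"a": p.a, "b": p.b, "c": p.c, "beta_sor": p.beta_sor,
                               "beta_sim": p.beta_sim, "beta_sne": p.beta_sne}
                for (h1, h2), p in d.items()
            }
        return {
            "seed": self.seed,
            "plant_pools": {h: sorted(s) for h, s in self.plant_pools.items()},
            "bee_pools": {h: sorted(s) for h, s in self.bee_pools.items()},
            "preference": {
                "bee_species": list(self.preference.index),
                "plant_taxa": list(self.preference.columns),
                "weights": self.preference.to_numpy().tolist(),
            },
            "expected_plant_beta": beta_map(self.expected_plant_beta),
            "expected_bee_beta": beta_map(self.expected_bee_beta),
        }


def _build_pools(prefix: str, pool_size: int, overlap: float) -> dict[str, frozenset[str]]:
    """Shared core + habitat-exclusive taxa; true a/b/c are known exactly."""
    n_shared = int(round(overlap * pool_size))
    shared = [f"{prefix} shared{i:03d}" for i in range(n_shared)]
    pools = {}
    for h in HABITATS:
        exclusive = [
            f"{prefix} {h}{i:03d}" for i in range(pool_size - n_shared)
        ]
        pools[h] = frozenset(shared + exclusive)
    return pools


def _expected_beta(pools: dict[str, frozenset[str]]) -> dict[tuple[str, str], BetaPartition]:
    out = {}
    for i, h1 in enumerate(HABITATS):
        for h2 in HABITATS[i + 1:]:
            out[(h1, h2)] = baselga_partition(pools[h1], pools[h2])
    return out


def uniform_preference(
    bee_species: list[str], plant_taxa: list[str], boosts: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Unit-weight preference matrix, optionally boosting some plant taxa."""
    pref = pd.DataFrame(1.0, index=list(bee_species), columns=list(plant_taxa))
    for taxon, weight in (boosts or {}).items():
        if taxon not in pref.columns:
            raise ConfigurationError(f"boosted taxon {taxon!r} not in plant pool")
        pref[taxon] = float(weight)
    return pref


def generate_dataset(config: SimulationConfig) -> tuple[Dataset, GroundTruth]:
    """Draw a full synthetic dataset plus its ground truth."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    design_rng, plant_rng, bee_rng, pollen_rng = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    logger.info("simulate: seed=%d", config.seed)

    plant_pools = _build_pools("Plant", config.plant_pool_size, config.plant_pool_overlap)
    bee_pools = _build_pools("Bee", config.bee_pool_size, config.bee_pool_overlap)
    all_plants = sorted(frozenset().union(*plant_pools.values()))
    all_bees = sorted(frozenset().union(*bee_pools.values()))

    if config.preference is not None:
        preference = config.preference.reindex(
            index=all_bees, columns=all_plants, fill_value=1.0
        )
    else:
        preference = uniform_preference(all_bees, all_plants)

    # --- design: which (landscape, habitat) points exist ---------------
    sites = _draw_sites(config, design_rng)

    # entomophily is a fixed per-taxon attribute
    entomophilous = {
        t: bool(plant_rng.random() < config.entomophilous_fraction) for t in all_plants
    }

    # --- plants: pool taxa occur per point with detection_prob ---------
    plant_rows = []
    for _, site in sites.iterrows():
        pool = sorted(plant_pools[site["habitat"]])
        occurs = plant_rng.random(len(pool)) < config.detection_prob
        for taxon, present in zip(pool, occurs):
            if present:
                plant_rows.append({
                    "point_id": site["point_id"],
                    "taxon": taxon,
                    "layer": "herbaceous",
                    "abundance_code": _BB_CODES[int(plant_rng.integers(len(_BB_CODES)))],
                    "entomophilous": entomophilous[taxon],
                })
    plants = pd.DataFrame(
        plant_rows, columns=["point_id", "taxon", "layer", "abundance_code", "entomophilous"]
    )

    # --- bees: skewed species-abundance, weight fixed per species ------
    bee_rows = []
    # lognormal commonness is a species attribute, so two habitats sharing
    # their whole pool have identical sampling distributions (no spurious
    # habitat effect under full overlap)
    species_weight = {
        sp: bee_rng.lognormal(mean=0.0, sigma=1.2) for sp in all_bees
    }
    rank_weights = {}
    for h in HABITATS:
        pool = sorted(bee_pools[h])
        weights = np.array([species_weight[sp] for sp in pool])
        rank_weights[h] = weights / weights.sum()
    bee_counter = 0
    for _, site in sites.iterrows():
        h = site["habitat"]
        count = int(bee_rng.poisson(config.bee_abundance_mean[h]))
        pool = sorted(bee_pools[h])
        if count == 0:
            continue
        species = bee_rng.choice(pool, size=count, p=rank_weights[h])
        for sp in species:
            bee_counter += 1
            bee_rows.append({
                "bee_id": f"bee{bee_counter:05d}",
                "point_id": site["point_id"],
                "species": sp,
            })
    bees = pd.DataFrame(bee_rows, columns=["bee_id", "point_id", "species"])

    # --- pollen: per-bee load ~ preference x local availability --------
    richness_values = np.array(sorted(config.pollen_richness_dist), dtype=int)
    richness_probs = np.array(
        [config.pollen_richness_dist[k] for k in richness_values], dtype=float
    )
    plants_by_point = {
        p: sorted(g.loc[g["entomophilous"], "taxon"].unique())
        for p, g in plants.groupby("point_id")
    }
    pollen_rows = []
    for _, bee in bees.iterrows():
        k = int(pollen_rng.choice(richness_values, p=richness_probs))
        candidates = plants_by_point.get(bee["point_id"], [])
        k = min(k, len(candidates))
        if k == 0:
            continue
        weights = preference.loc[bee["species"], candidates].to_numpy(dtype=float)
        if weights.sum() <= 0:
            continue
        chosen = pollen_rng.choice(
            candidates, size=k, replace=False, p=weights / weights.sum()
        )
        for taxon in chosen:
            pollen_rows.append({"bee_id": bee["bee_id"], "pollen_taxon": taxon})
    pollen = pd.DataFrame(pollen_rows, columns=["bee_id", "pollen_taxon"])

    dataset = Dataset(sites=sites, bees=bees, plants=plants, pollen=pollen).validate()
    truth = GroundTruth(
        plant_pools=plant_pools,
        bee_pools=bee_pools,
        preference=preference,
        expected_plant_beta=_expected_beta(plant_pools),
        expected_bee_beta=_expected_beta(bee_pools),
        seed=config.seed,
    )
    logger.info(
        "simulated %d points, %d bees, %d plant rows, %d pollen rows",
        len(sites), len(bees), len(plants), len(pollen),
    )
    return dataset, truth


def _draw_sites(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for land in range(1, config.n_landscapes + 1):
        for h in HABITATS:
            rows.append({
                "point_id": f"L{land:02d}_{h}",
                "landscape_id": f"L{land:02d}",
                "habitat": h,
            })
    sites = pd.DataFrame(rows)
    if config.exact_site_counts is not None:
        keep = []
        for h in HABITATS:
            idx = sites.index[sites["habitat"] == h].to_numpy()
            want = int(config.exact_site_counts.get(h, len(idx)))
            if want > len(idx):
                raise ConfigurationError(
                    f"exact_site_counts[{h!r}]={want} exceeds n_landscapes"
                )
            keep.extend(rng.choice(idx, size=want, replace=False))
        sites = sites.loc[sorted(keep)].reset_index(drop=True)
    else:
        drop_mask = np.array([
            rng.random() < config.habitat_missingness.get(h, 0.0)
            for h in sites["habitat"]
        ])
        sites = sites.loc[~drop_mask].reset_index(drop=True)
    if sites.empty:
        raise ConfigurationError("site design is empty (missingness too high?)")
    return sites


def emulate_study_design(seed: int = 0) -> tuple[Dataset, GroundTruth]:
    """Preset mimicking the field design: 30/29/24 points by habitat,
    roughly 500 bees and 300 plant taxa, and pollen loads where most
    pollen-carrying bees hold 1-2 taxa and ~15% carry none."""
    config = SimulationConfig(
        n_landscapes=30,
        exact_site_counts={"hedgerow": 30, "grassland": 29, "forest_edge": 24},
        plant_pool_size=140,
        plant_pool_overlap=60 / 140,  # union ~300 taxa
        bee_pool_size=40,
        bee_pool_overlap=0.45,
        detection_prob=0.22,
        entomophilous_fraction=0.75,
        bee_abundance_mean={"hedgerow": 4.0, "forest_edge": 4.8, "grassland": 10.1},
        pollen_richness_dist=dict(DEFAULT_POLLEN_RICHNESS),
        seed=seed,
    )
    return generate_dataset(config)
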