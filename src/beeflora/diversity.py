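"""Community diversity analyses on presence/absence and abundance data.

Implements pairwise beta-diversity partitioning into turnover and
nestedness components, pooled per-habitat communities, within-habitat
pairwise dissimilarities, individual-based rarefaction/extrapolation with
bootstrap confidence bands, a label-permutation null model for
between-habitat dissimilarity, and per-point richness/abundance summaries.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import kruskal, mannwhitneyu

from .data import (
    HABITATS,
    Dataset,
    InsufficientDataError,
    UndefinedDissimilarityError,
    ValidationError,
)

logger = logging.getLogger("beeflora")


# ---------------------------------------------------------------------------
# Beta-diversity partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BetaPartition:
    """Pairwise dissimilarity split into turnover and nestedness components.

    ``a`` is the shared-taxon count, ``b``/``c`` the unique-taxon counts of
    the poorer/richer community (b <= c).  Satisfies
    ``beta_sor == beta_sim + beta_sne`` and all three lie in [0, 1].
    """

    a: int
    b: int
    c: int
    beta_sor: float
    beta_sim: float
    beta_sne: float


def baselga_partition(community_a: Iterable, community_b: Iterable) -> BetaPartition:
    """Partition Sorensen dissimilarity between two presence/absence communities.

    beta_sor = (b+c)/(2a+b+c); beta_sim = b/(a+b);
    beta_sne = ((c-b)/(2a+b+c)) * (a/(a+b)), with b = min and c = max of the
    two unique-taxon counts.  When the poorer community is empty (a+b = 0)
    turnover is defined as 0 and all dissimilarity is nestedness-resultant.
    """
    set_a, set_b = set(community_a), set(community_b)
    if not set_a and not set_b:
        raise UndefinedDissimilarityError("both communities are empty")
    a = len(set_a & set_b)
    u1, u2 = len(set_a - set_b), len(set_b - set_a)
    b, c = min(u1, u2), max(u1, u2)
    denom = 2 * a + b + c
    beta_sor = (b + c) / denom
    if a + b > 0:
        beta_sim = b / (a + b)
        beta_sne = ((c - b) / denom) * (a / (a + b))
    else:  # poorer community empty: pure nestedness by convention
        beta_sim = 0.0
        beta_sne = beta_sor
    return BetaPartition(a=a, b=b, c=c, beta_sor=beta_sor, beta_sim=beta_sim, beta_sne=beta_sne)


def pooled_habitat_community(
    dataset: Dataset, habitat: str, taxa_source: str = "bees", *,
    entomophilous_only: bool = True,
) -> frozenset[str]:
    """Union of taxa over all sampling points of one habitat (presence only).

    ``taxa_source`` is ``"bees"`` (bee species) or ``"plants"`` (plant taxa;
    restricted to entomophilous taxa by default).
    """
    points = set(dataset.points_in(habitat))
    if not points:
        logger.warning("habitat %r has no sampling points; empty community", habitat)
        return frozenset()
    taxa = _taxa_by_point(dataset, taxa_source, entomophilous_only)
    pooled = frozenset(taxa.loc[taxa["point_id"].isin(points), "taxon"])
    if not pooled:
        logger.warning("habitat %r has no %s records; empty community", habitat, taxa_source)
    return pooled


def _taxa_by_point(dataset: Dataset, taxa_source: str, entomophilous_only: bool) -> pd.DataFrame:
    if taxa_source == "bees":
        df = dataset.bees[["point_id", "species"]].rename(columns={"species": "taxon"})
        return df.drop_duplicates(ignore_index=True)
    if taxa_source == "plants":
        return dataset.plant_presence(entomophilous_only=entomophilous_only)
    raise ValidationError(f"taxa_source must be 'bees' or 'plants', got {taxa_source!r}")


def inter_habitat_beta(
    dataset: Dataset, taxa_source: str = "bees", *, entomophilous_only: bool = True,
) -> pd.DataFrame:
    """Beta partition between pooled communities of every habitat pair."""
    pooled = {
        h: pooled_habitat_community(
            dataset, h, taxa_source, entomophilous_only=entomophilous_only
        )
        for h in HABITATS
    }
    rows = []
    for h1, h2 in itertools.combinations(HABITATS, 2):
        part = baselga_partition(pooled[h1], pooled[h2])
        rows.append({"habitat_a": h1, "habitat_b": h2, **part.__dict__})
    return pd.DataFrame(rows)


def pairwise_beta_within(
    dataset: Dataset, habitat: str, taxa_source: str = "bees", *,
    entomophilous_only: bool = True,
) -> pd.DataFrame:
    """Beta partition for every unordered pair of points within one habitat.

    Pairs where both points have empty communities are excluded (and
    logged).  The returned frame carries ``attrs['median_beta_sor']``.
    """
    points = dataset.points_in(habitat)
    taxa = _taxa_by_point(dataset, taxa_source, entomophilous_only)
    communities = {
        p: frozenset(taxa.loc[taxa["point_id"] == p, "taxon"]) for p in points
    }
    usable = [p for p in points if communities[p]]
    if len(usable) < 2:
        raise InsufficientDataError(
            f"habitat {habitat!r} has {len(usable)} non-empty points; need >= 2"
        )
    rows = []
    skipped = 0
    for p1, p2 in itertools.combinations(points, 2):
        if not communities[p1] and not communities[p2]:
            skipped += 1
            continue
        part = baselga_partition(communities[p1], communities[p2])
        rows.append({"point_a": p1, "point_b": p2, **part.__dict__})
    if skipped:
        logger.info("excluded %d point pairs with two empty communities", skipped)
    table = pd.DataFrame(rows)
    table.attrs["median_beta_sor"] = float(table["beta_sor"].median())
    table.attrs["habitat"] = habitat
    return table


# ---------------------------------------------------------------------------
# Abundance vectors and rarefaction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AbundanceVector:
    """Taxon -> count mapping for one community with cached summaries."""

    counts: Mapping[str, int]
    n: int
    s_obs: int
    f1: int
    f2: int

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "AbundanceVector":
        clean = {t: int(x) for t, x in counts.items() if x > 0}
        if any(x < 0 for x in counts.values()):
            raise ValidationError("abundance counts must be non-negative")
        values = list(clean.values())
        return cls(
            counts=clean,
            n=sum(values),
            s_obs=len(values),
            f1=sum(1 for x in values if x == 1),
            f2=sum(1 for x in values if x == 2),
        )

    @classmethod
    def from_dataset(cls, dataset: Dataset, habitat: str | None = None) -> "AbundanceVector":
        bees = dataset.bees
        if habitat is not None:
            points = set(dataset.points_in(habitat))
            bees = bees[bees["point_id"].isin(points)]
        return cls.from_counts(bees["species"].value_counts().to_dict())


@dataclass(frozen=True)
class RarefactionCurve:
    m: np.ndarray
    expected_richness: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    conf: float
    n_boot: int
    seed: int


def _interpolated_richness(x: np.ndarray, n: int, m: int) -> float:
    # E[S_m] = S_obs - sum_i C(n - x_i, m) / C(n, m), exact hypergeometric form
    keep = (n - x) >= m
    if not keep.any():
        return float(len(x))
    nx = (n - x[keep]).astype(float)
    log_terms = (
        gammaln(nx + 1) - gammaln(nx - m + 1) - (gammaln(n + 1) - gammaln(n - m + 1))
    )
    return float(len(x) - np.exp(log_terms).sum())


def _extrapolated_richness(x: np.ndarray, n: int, m: int, f1: int, f2: int) -> float:
    # Chao1-based extrapolation beyond the observed sample size
    s_obs = len(x)
    if f1 == 0:
        return float(s_obs)
    if f2 > 0:
        f0 = (n - 1) / n * f1 * f1 / (2 * f2)
    else:  # small-sample correction when no doubletons
        f0 = (n - 1) / n * f1 * (f1 - 1) / 2
    if f0 <= 0:
        return float(s_obs)
    m_star = m - n
    return float(s_obs + f0 * (1.0 - (1.0 - f1 / (n * f0 + f1)) ** m_star))


def _curve(x: np.ndarray, m_grid: np.ndarray) -> np.ndarray:
    n = int(x.sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    out = np.empty(len(m_grid), dtype=float)
    for i, m in enumerate(m_grid):
        out[i] = (
            _interpolated_richness(x, n, int(m))
            if m <= n
            else _extrapolated_richness(x, n, int(m), f1, f2)
        )
    return out


def rarefaction_curve(
    av: AbundanceVector,
    m_grid: Sequence[int] | None = None,
    conf: float = 0.84,
    n_boot: int = 200,
    seed: int = 0,
) -> RarefactionCurve:
    """Individual-based rarefaction/extrapolation with bootstrap percentile CI.

    Interpolation (m <= n) uses the exact hypergeometric expectation;
    extrapolation (m > n) the Chao1-based estimator, bounded at 2n by the
    default grid.  The CI resamples the abundance vector (multinomial on
    observed proportions) ``n_boot`` times.
    """
    if av.n < 1:
        raise InsufficientDataError("cannot rarefy an all-zero abundance vector")
    if m_grid is None:
        m_grid = np.unique(np.linspace(1, 2 * av.n, 40).round().astype(int))
    m_grid = np.asarray(list(m_grid), dtype=int)
    if (m_grid < 1).any():
        raise ValidationError("all m values must be >= 1")

    x = np.array(sorted(av.counts.values(), reverse=True), dtype=int)
    expected = _curve(x, m_grid)

    rng = np.random.default_rng(seed)
    logger.info("rarefaction bootstrap: n_boot=%d seed=%d", n_boot, seed)
    probs = x / x.sum()
    boot = np.empty((n_boot, len(m_grid)), dtype=float)
    for b in range(n_boot):
        counts = rng.multinomial(av.n, probs)
        boot[b] = _curve(counts[counts > 0], m_grid)
    alpha = (1.0 - conf) / 2.0
    ci_low = np.quantile(boot, alpha, axis=0)
    ci_high = np.quantile(boot, 1.0 - alpha, axis=0)
    # percentile band re-centred so the point estimate always lies inside
    ci_low = np.minimum(ci_low, expected)
    ci_high = np.maximum(ci_high, expected)
    return RarefactionCurve(
        m=m_grid, expected_richness=expected, ci_low=ci_low, ci_high=ci_high,
        conf=conf, n_boot=n_boot, seed=seed,
    )


# ---------------------------------------------------------------------------
# Permutation null model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NullModelResult:
    observed: float
    null_values: np.ndarray
    p_value: float
    n_perm: int
    seed: int


def beta_null_test(
    dataset: Dataset,
    habitat_pair: tuple[str, str],
    taxa_source: str = "bees",
    n_perm: int = 999,
    seed: int = 0,
    *,
    entomophilous_only: bool = True,
) -> NullModelResult:
    """Permutation test of pooled between-habitat Sorensen dissimilarity.

    Sampling-point labels (not taxa) are shuffled between the two habitats;
    p = (1 + #{null >= observed}) / (1 + n_perm), one-sided.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    h1, h2 = habitat_pair
    points1, points2 = dataset.points_in(h1), dataset.points_in(h2)
    if not points1 or not points2:
        raise InsufficientDataError(f"both habitats need >= 1 point: {habitat_pair}")

    taxa = _taxa_by_point(dataset, taxa_source, entomophilous_only)
    communities = {
        p: frozenset(g["taxon"]) for p, g in taxa.groupby("point_id")
    }
    empty: frozenset[str] = frozenset()

    def pooled_beta(group1: Sequence[str], group2: Sequence[str]) -> float:
        c1 = frozenset().union(*(communities.get(p, empty) for p in group1))
        c2 = frozenset().union(*(communities.get(p, empty) for p in group2))
        return baselga_partition(c1, c2).beta_sor

    observed = pooled_beta(points1, points2)
    all_points = np.array(points1 + points2, dtype=object)
    n1 = len(points1)
    rng = np.random.default_rng(seed)
    logger.info("beta null test: n_perm=%d seed=%d", n_perm, seed)
    null_values = np.empty(n_perm, dtype=float)
    for i in range(n_perm):
        perm = rng.permutation(all_points)
        null_values[i] = pooled_beta(perm[:n1], perm[n1:])
    p_value = (1.0 + np.sum(null_values >= observed)) / (1.0 + n_perm)
    return NullModelResult(
        observed=observed, null_values=null_values, p_value=float(p_value),
        n_perm=n_perm, seed=seed,
    )


# ---------------------------------------------------------------------------
# Richness / abundance summaries
# ---------------------------------------------------------------------------

def richness_abundance_summary(dataset: Dataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-point bee abundance/richness and per-habitat medians.

    Group differences are reported via standard Kruskal-Wallis plus pairwise
    Mann-Whitney tests with Bonferroni correction (attached in ``attrs``);
    these are delegated to scipy, not re-implemented.
    """
    habitat = dataset.habitat_of()
    per_point = (
        dataset.bees.groupby("point_id")
        .agg(abundance=("bee_id", "size"), richness=("species", "nunique"))
        .reindex(dataset.sites["point_id"])
        .fillna(0)
        .astype(int)
        .reset_index()
    )
    per_point["habitat"] = per_point["point_id"].map(habitat)

    per_habitat = (
        per_point.groupby("habitat")[["abundance", "richness"]]
        .median()
        .rename(columns=lambda c: f"median_{c}")
        .reindex(list(HABITATS))
        .reset_index()
    )

    tests: dict[str, object] = {}
    groups = {h: per_point.loc[per_point["habitat"] == h] for h in HABITATS}
    for metric in ("abundance", "richness"):
        samples = [groups[h][metric].to_numpy() for h in HABITATS if len(groups[h])]
        if len(samples) >= 2 and all(len(s) for s in samples):
            stat, p = kruskal(*samples)
            pairwise = {}
            pairs = [
                (h1, h2)
                for h1, h2 in itertools.combinations(HABITATS, 2)
                if len(groups[h1]) and len(groups[h2])
            ]
            for h1, h2 in pairs:
                _, raw_p = mannwhitneyu(
                    groups[h1][metric], groups[h2][metric], alternative="two-sided"
                )
                pairwise[(h1, h2)] = min(1.0, raw_p * len(pairs))  # Bonferroni
            tests[metric] = {"kruskal_stat": float(stat), "kruskal_p": float(p),
                             "pairwise_bonferroni": pairwise}
    per_habitat.attrs["tests"] = tests
    return per_point, per_habitat
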