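"""diversity module: beta partition, pooling, rarefaction, null model."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beeflora.data import InsufficientDataError, UndefinedDissimilarityError
from beeflora.diversity import (
    AbundanceVector,
    baselga_partition,
    beta_null_test,
    pairwise_beta_within,
    pooled_habitat_community,
    rarefaction_curve,
    richness_abundance_summary,
)

from .conftest import make_dataset


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_partition(set_a: set, set_b: set) -> tuple[float, float, float]:
    """Set-algebra oracle: enumerate shared/unique taxa, plug into formulas."""
    a = len(set_a & set_b)
    u = sorted([len(set_a - set_b), len(set_b - set_a)])
    b, c = u
    sor = (b + c) / (2 * a + b + c)
    sim = b / (a + b) if a + b else 0.0
    sne = sor - sim
    return sor, sim, sne


def brute_force_rarefaction(individuals: list[str], m: int) -> float:
    """Mean richness over every size-m subsample (exhaustive enumeration)."""
    richness = [
        len(set(combo)) for combo in itertools.combinations(individuals, m)
    ]
    return sum(richness) / len(richness)


# ---------------------------------------------------------------------------
# Baselga partition
# ---------------------------------------------------------------------------

class TestBaselgaPartition:
    def test_identical_communities(self):
        part = baselga_partition(set("abcdefghij"), set("abcdefghij"))
        assert (part.a, part.b, part.c) == (10, 0, 0)
        assert part.beta_sor == part.beta_sim == part.beta_sne == 0.0

    def test_disjoint_communities(self):
        part = baselga_partition({f"x{i}" for i in range(5)},
                                 {f"y{i}" for i in range(7)})
        assert part.beta_sor == 1.0
        assert part.beta_sim == 1.0
        assert part.beta_sne == 0.0

    def test_hand_computed_example(self):
        # a=2, b=1, c=3: sor = 4/8, sim = 1/3, sne = (2/8)*(2/3) = 1/6
        part = baselga_partition({"s1", "s2", "u1"}, {"s1", "s2", "v1", "v2", "v3"})
        assert (part.a, part.b, part.c) == (2, 1, 3)
        assert part.beta_sor == pytest.approx(0.5, abs=1e-12)
        assert part.beta_sim == pytest.approx(1 / 3, abs=1e-5)
        assert part.beta_sne == pytest.approx(1 / 6, abs=1e-5)

    def test_symmetry(self):
        a = {"p", "q", "r"}
        b = {"q", "r", "s", "t"}
        assert baselga_partition(a, b) == baselga_partition(b, a)

    def test_both_empty_raises(self):
        with pytest.raises(UndefinedDissimilarityError):
            baselga_partition(set(), set())

    def test_one_empty_is_pure_nestedness(self):
        part = baselga_partition(set(), {"x", "y"})
        assert part.beta_sor == 1.0
        assert part.beta_sim == 0.0
        assert part.beta_sne == 1.0

    @given(
        st.sets(st.integers(0, 30), max_size=20),
        st.sets(st.integers(0, 30), max_size=20),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_oracle_and_invariants(self, set_a, set_b):
        if not set_a and not set_b:
            return
        part = baselga_partition(set_a, set_b)
        sor, sim, sne = oracle_partition(set_a, set_b)
        assert part.beta_sor == pytest.approx(sor, abs=1e-12)
        assert part.beta_sim == pytest.approx(sim, abs=1e-12)
        assert part.beta_sne == pytest.approx(sne, abs=1e-12)
        assert abs(part.beta_sor - (part.beta_sim + part.beta_sne)) < 1e-12
        assert 0.0 <= part.beta_sim <= part.beta_sor <= 1.0
        assert part.b <= part.c
        if len(set_a - set_b) == len(set_b - set_a):
            assert part.beta_sne == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# pooled communities and within-habitat pairwise beta
# ---------------------------------------------------------------------------

class TestPooledCommunity:
    def test_union_of_points(self):
        ds = make_dataset(
            sites=[("p1", "L1", "hedgerow"), ("p2", "L2", "hedgerow")],
            bees=[("b1", "p1", "x"), ("b2", "p1", "y"),
                  ("b3", "p2", "y"), ("b4", "p2", "z")],
            plants=[], pollen=[],
        )
        assert pooled_habitat_community(ds, "hedgerow", "bees") == {"x", "y", "z"}

    def test_habitat_without_records_is_empty_with_warning(self, caplog):
        ds = make_dataset(
            sites=[("p1", "L1", "hedgerow")], bees=[], plants=[], pollen=[]
        )
        with caplog.at_level("WARNING", logger="beeflora"):
            assert pooled_habitat_community(ds, "grassland", "bees") == frozenset()
        assert "no sampling points" in caplog.text

    def test_plants_source_uses_entomophilous_presence(self):
        ds = make_dataset(
            sites=[("p1", "L1", "grassland")],
            bees=[],
            plants=[("p1", "Rosa y", "shrub", "1", True),
                    ("p1", "Poa p", "herbaceous", "3", False)],
            pollen=[],
        )
        assert pooled_habitat_community(ds, "grassland", "plants") == {"Rosa y"}


class TestPairwiseBetaWithin:
    def _dataset(self, communities: dict[str, list[str]]):
        sites = [(p, "L1", "grassland") for p in communities]
        bees, k = [], 0
        for p, taxa in communities.items():
            for t in taxa:
                k += 1
                bees.append((f"b{k}", p, t))
        return make_dataset(sites=sites, bees=bees, plants=[], pollen=[])

    def test_identical_communities_all_zero(self):
        ds = self._dataset({"p1": ["x", "y"], "p2": ["x", "y"], "p3": ["x", "y"]})
        table = pairwise_beta_within(ds, "grassland")
        assert len(table) == 3
        assert (table["beta_sor"] == 0).all()
        assert table.attrs["median_beta_sor"] == 0.0

    def test_disjoint_communities_all_one(self):
        ds = self._dataset({"p1": ["x"], "p2": ["y"], "p3": ["z"]})
        table = pairwise_beta_within(ds, "grassland")
        assert (table["beta_sor"] == 1).all()
        assert table.attrs["median_beta_sor"] == 1.0

    def test_rotating_overlap_half(self):
        ds = self._dataset({"p1": ["x", "y"], "p2": ["y", "z"], "p3": ["x", "z"]})
        table = pairwise_beta_within(ds, "grassland")
        assert (table[["a", "b", "c"]] == 1).all().all()
        assert table["beta_sor"].tolist() == [0.5, 0.5, 0.5]
        assert table.attrs["median_beta_sor"] == 0.5

    def test_fewer_than_two_usable_points_raises(self):
        ds = self._dataset({"p1": ["x"], "p2": []})
        with pytest.raises(InsufficientDataError):
            pairwise_beta_within(ds, "grassland")


# ---------------------------------------------------------------------------
# rarefaction / extrapolation
# ---------------------------------------------------------------------------

class TestRarefaction:
    def test_full_sample_recovers_observed_richness(self):
        av = AbundanceVector.from_counts({"a": 5, "b": 3, "c": 1})
        curve = rarefaction_curve(av, m_grid=[av.n], n_boot=10, seed=0)
        assert curve.expected_richness[0] == pytest.approx(av.s_obs, abs=1e-9)

    def test_single_individual_is_one_species(self):
        av = AbundanceVector.from_counts({"a": 4, "b": 2, "c": 2, "d": 1})
        curve = rarefaction_curve(av, m_grid=[1], n_boot=10, seed=0)
        assert curve.expected_richness[0] == pytest.approx(1.0, abs=1e-9)

    def test_frozen_two_species_example(self):
        # x=(2,1), m=2: E = 2 - [C(1,2)/C(3,2) + C(2,2)/C(3,2)] = 5/3
        av = AbundanceVector.from_counts({"a": 2, "b": 1})
        curve = rarefaction_curve(av, m_grid=[2], n_boot=10, seed=0)
        assert curve.expected_richness[0] == pytest.approx(5 / 3, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        n_species = int(rng.integers(1, n + 1))
        assignment = rng.integers(0, n_species, size=n)
        counts = {f"s{i}": int((assignment == i).sum()) for i in range(n_species)}
        counts = {k: v for k, v in counts.items() if v > 0}
        av = AbundanceVector.from_counts(counts)
        individuals = [sp for sp, x in counts.items() for _ in range(x)]
        grid = list(range(1, av.n + 1))
        curve = rarefaction_curve(av, m_grid=grid, n_boot=5, seed=0)
        for m, expected in zip(grid, curve.expected_richness):
            assert expected == pytest.approx(
                brute_force_rarefaction(individuals, m), abs=1e-9
            )

    def test_nondecreasing_and_concave_interpolated(self):
        av = AbundanceVector.from_counts({"a": 9, "b": 5, "c": 3, "d": 2, "e": 1})
        grid = list(range(1, av.n + 1))
        curve = rarefaction_curve(av, m_grid=grid, n_boot=5, seed=0)
        diffs = np.diff(curve.expected_richness)
        assert (diffs >= -1e-12).all()
        assert (np.diff(diffs) <= 1e-12).all()

    def test_extrapolation_beyond_n_is_nondecreasing_and_bounded(self):
        av = AbundanceVector.from_counts({"a": 6, "b": 3, "c": 1, "d": 1})
        grid = [av.n, av.n + 3, 2 * av.n]
        curve = rarefaction_curve(av, m_grid=grid, n_boot=20, seed=1)
        assert curve.expected_richness[0] == pytest.approx(av.s_obs)
        assert (np.diff(curve.expected_richness) >= 0).all()
        # asymptote is the Chao1 estimate; with f2=0 the corrected form applies
        f0 = (av.n - 1) / av.n * av.f1 * (av.f1 - 1) / 2
        assert curve.expected_richness[-1] <= av.s_obs + f0 + 1e-9

    def test_no_singletons_means_flat_extrapolation(self):
        av = AbundanceVector.from_counts({"a": 4, "b": 4})
        curve = rarefaction_curve(av, m_grid=[8, 12, 16], n_boot=5, seed=0)
        assert np.allclose(curve.expected_richness, 2.0)

    def test_ci_contains_point_estimate(self):
        av = AbundanceVector.from_counts({"a": 12, "b": 6, "c": 3, "d": 1, "e": 1})
        curve = rarefaction_curve(av, n_boot=100, seed=3)
        assert (curve.ci_low <= curve.expected_richness + 1e-12).all()
        assert (curve.ci_high >= curve.expected_richness - 1e-12).all()

    def test_deterministic_under_seed(self):
        av = AbundanceVector.from_counts({"a": 5, "b": 4, "c": 1})
        c1 = rarefaction_curve(av, n_boot=50, seed=7)
        c2 = rarefaction_curve(av, n_boot=50, seed=7)
        assert np.array_equal(c1.ci_low, c2.ci_low)
        assert np.array_equal(c1.ci_high, c2.ci_high)

    def test_bad_inputs(self):
        av = AbundanceVector.from_counts({"a": 2})
        with pytest.raises(Exception):
            rarefaction_curve(av, m_grid=[0])
        with pytest.raises(InsufficientDataError):
            rarefaction_curve(AbundanceVector.from_counts({}), m_grid=[1])


# ---------------------------------------------------------------------------
# permutation null model
# ---------------------------------------------------------------------------

class TestBetaNullTest:
    def _two_habitat_dataset(self, pools: dict[str, list[str]], n_points=4):
        sites, bees, k = [], [], 0
        for h, taxa in pools.items():
            for i in range(n_points):
                p = f"{h}_{i}"
                sites.append((p, f"L{i}", h))
                for t in taxa:
                    k += 1
                    bees.append((f"b{k}", p, t))
        return make_dataset(sites=sites, bees=bees, plants=[], pollen=[])

    def test_identical_pools_give_p_one(self):
        ds = self._two_habitat_dataset(
            {"hedgerow": ["x", "y", "z"], "grassland": ["x", "y", "z"]}
        )
        res = beta_null_test(ds, ("hedgerow", "grassland"), n_perm=99, seed=0)
        assert res.observed == 0.0
        assert res.p_value == 1.0  # observed is the floor of the statistic

    def test_disjoint_pools_give_minimal_p(self):
        # 8 vs 8 points with fully disjoint large communities: the observed
        # beta_sor = 1 is only matched by permutations recreating the split
        pools = {"hedgerow": [f"h{i}" for i in range(15)],
                 "grassland": [f"g{i}" for i in range(15)]}
        ds = self._two_habitat_dataset(pools, n_points=8)
        res = beta_null_test(ds, ("hedgerow", "grassland"), n_perm=199, seed=5)
        assert res.observed == 1.0
        assert res.p_value == pytest.approx(1 / 200)

    def test_p_value_definition_add_one(self):
        ds = self._two_habitat_dataset(
            {"hedgerow": ["x", "y"], "grassland": ["y", "z"]}, n_points=3
        )
        res = beta_null_test(ds, ("hedgerow", "grassland"), n_perm=49, seed=1)
        expected = (1 + int((res.null_values >= res.observed).sum())) / 50
        assert res.p_value == pytest.approx(expected)
        assert 0 < res.p_value <= 1
        assert len(res.null_values) == 49

    def test_invalid_n_perm(self):
        ds = self._two_habitat_dataset({"hedgerow": ["x"], "grassland": ["y"]})
        with pytest.raises(Exception):
            beta_null_test(ds, ("hedgerow", "grassland"), n_perm=0)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

class TestRichnessAbundanceSummary:
    def test_counts_and_empty_point(self):
        ds = make_dataset(
            sites=[("p1", "L1", "grassland"), ("p2", "L2", "grassland")],
            bees=[("b1", "p1", "x"), ("b2", "p1", "x"), ("b3", "p1", "y")],
            plants=[], pollen=[],
        )
        per_point, per_habitat = richness_abundance_summary(ds)
        row = per_point.set_index("point_id")
        assert row.loc["p1", "abundance"] == 3
        assert row.loc["p1", "richness"] == 2
        assert row.loc["p2", "abundance"] == 0
        assert row.loc["p2", "richness"] == 0
        medians = per_habitat.set_index("habitat")
        assert medians.loc["grassland", "median_abundance"] == 1.5

    def test_group_tests_delegated_to_scipy(self):
        rng = np.random.default_rng(0)
        sites, bees, k = [], [], 0
        for h, mean in (("grassland", 8), ("hedgerow", 2), ("forest_edge", 2)):
            for i in range(8):
                p = f"{h}{i}"
                sites.append((p, f"L{i}", h))
                for _ in range(int(rng.poisson(mean)) + 1):
                    k += 1
                    bees.append((f"b{k}", p, f"sp{rng.integers(6)}"))
        ds = make_dataset(sites=sites, bees=bees, plants=[], pollen=[])
        _, per_habitat = richness_abundance_summary(ds)
        tests = per_habitat.attrs["tests"]
        assert set(tests) == {"abundance", "richness"}
        assert 0 <= tests["abundance"]["kruskal_p"] <= 1
        assert len(tests["abundance"]["pairwise_bonferroni"]) == 3
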