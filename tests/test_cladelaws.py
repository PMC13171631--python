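"""Clade-size distributions: Yule-Simon pmf/MLE, Willis fits, size tabulation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microcensus import (
    CladeSizeDistribution,
    fit_willis,
    fit_yule_simon,
    sizes_from_partitions,
    sizes_from_taxonomy_table,
    stratified_fits,
    yule_simon_pmf,
)
from microcensus.cladelaws import DegenerateDistributionError
from microcensus.red import CladePartition, compute_red, cut_at_red
from microcensus.synthetic import SimonProcessParams, simulate_simon_clades


class TestPmf:
    def test_closed_forms_at_rho_one(self):
        assert yule_simon_pmf(1, 1.0) == pytest.approx(0.5)
        assert yule_simon_pmf(2, 1.0) == pytest.approx(1 / 6)

    def test_matches_scipy_reference(self):
        sizes = np.arange(1, 200)
        for rho in (0.5, 1.5, 3.0):
            mine = yule_simon_pmf(sizes, rho)
            ref = stats.yulesimon.pmf(sizes, rho)
            assert mine == pytest.approx(ref, rel=1e-12)

    def test_normalizes_over_support(self):
        sizes = np.arange(1, 10**6 + 1)
        total = yule_simon_pmf(sizes, 1.5).sum()
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            yule_simon_pmf(0, 1.0)
        with pytest.raises(ValueError):
            yule_simon_pmf(1, 0.0)


def grid_search_rho(dist, lo=0.05, hi=10.0, step=1e-3):
    """Independent dense-grid oracle for the Yule-Simon MLE."""
    sizes = dist.sizes.astype(float)
    counts = np.array([dist.counts[int(s)] for s in dist.sizes], float)
    grid = np.arange(lo, hi, step)
    ll = [
        np.sum(counts * stats.yulesimon.logpmf(sizes, rho)) for rho in grid
    ]
    return grid[int(np.argmax(ll))]


class TestYuleSimonFit:
    def test_mle_matches_grid_oracle(self):
        fixtures = [
            CladeSizeDistribution({1: 50, 2: 20, 3: 8, 5: 3, 9: 1}),
            CladeSizeDistribution({1: 5, 2: 5, 3: 5}),
            CladeSizeDistribution.from_sizes(
                stats.yulesimon.rvs(2.0, size=2000, random_state=1)
            ),
        ]
        for dist in fixtures:
            fit = fit_yule_simon(dist)
            oracle = grid_search_rho(dist)
            assert abs(fit.rho - oracle) <= 1e-3 + 1e-9

    @pytest.mark.parametrize("rho", [0.75, 1.5, 3.0])
    def test_recovery_from_large_samples(self, rho):
        rng = np.random.default_rng(7)
        sample = stats.yulesimon.rvs(rho, size=100_000, random_state=rng)
        fit = fit_yule_simon(CladeSizeDistribution.from_sizes(sample))
        assert fit.rho == pytest.approx(rho, abs=0.05)
        assert fit.std_error > 0

    def test_all_singletons_degenerate(self):
        with pytest.raises(DegenerateDistributionError):
            fit_yule_simon(CladeSizeDistribution({1: 100}))

    def test_tail_heaviness_decreases_with_rho(self):
        rng = np.random.default_rng(3)
        q99 = []
        for rho in (0.75, 1.5, 3.0):
            sample = stats.yulesimon.rvs(rho, size=20_000, random_state=rng)
            q99.append(np.quantile(sample, 0.99))
        assert q99[0] > q99[1] > q99[2]


class TestWillis:
    def test_exact_log_linear_fixture(self):
        fit = fit_willis(CladeSizeDistribution({1: 8, 2: 4, 4: 2, 8: 1}))
        assert fit.omega == pytest.approx(1.0)
        assert fit.a == pytest.approx(8.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_flat_counts_omega_zero(self):
        fit = fit_willis(CladeSizeDistribution({1: 7, 2: 7, 4: 7}))
        assert fit.omega == pytest.approx(0.0)

    def test_too_few_sizes_rejected(self):
        with pytest.raises(ValueError):
            fit_willis(CladeSizeDistribution({1: 5, 2: 5}))

    @pytest.mark.parametrize("rho", [0.5, 1.0, 2.0])
    def test_omega_approximates_rho_plus_one(self, rho):
        """The binned log-log slope tracks the tail exponent rho + 1."""
        rng = np.random.default_rng(11)
        sample = stats.yulesimon.rvs(rho, size=100_000, random_state=rng)
        dist = CladeSizeDistribution.from_sizes(sample)
        fit = fit_willis(dist, binning="log2", s_min=2)
        assert fit.omega == pytest.approx(rho + 1.0, abs=0.3)


class TestSimonProcess:
    def test_always_innovate_all_singletons(self):
        dist = simulate_simon_clades(SimonProcessParams(100, 1.0, seed=0))
        assert dist.counts == {1: 100}

    def test_never_innovate_single_clade(self):
        dist = simulate_simon_clades(SimonProcessParams(50, 0.0, seed=0))
        assert dist.counts == {50: 1}

    def test_total_units_equals_steps(self):
        for seed in range(5):
            dist = simulate_simon_clades(SimonProcessParams(1000, 0.3, seed=seed))
            assert dist.total_units == 1000

    def test_histogram_matches_stationary_law(self):
        """Clade counts at p=0.5 agree with Yule-Simon(rho=2) on sizes 1-10."""
        n = 100_000
        dist = simulate_simon_clades(SimonProcessParams(n, 0.5, seed=123))
        n_clades = dist.n_clades
        for s in range(1, 11):
            observed = dist.counts.get(s, 0)
            p = yule_simon_pmf(s, 2.0)
            se = np.sqrt(n_clades * p * (1 - p))
            assert abs(observed - n_clades * p) < 3 * se + 1e-9, f"size {s}"

    def test_deterministic_under_seed(self):
        a = simulate_simon_clades(SimonProcessParams(5000, 0.4, seed=9))
        b = simulate_simon_clades(SimonProcessParams(5000, 0.4, seed=9))
        assert a.counts == b.counts

    def test_zero_steps_rejected(self):
        with pytest.raises(ValueError):
            SimonProcessParams(0, 0.5)


def partition(rank, tip_groups):
    clades = [
        {"clade_id": f"{rank}_{i}", "tips": frozenset(g), "provenance": None}
        for i, g in enumerate(tip_groups)
    ]
    return CladePartition(rank=rank, cutoff=0.5, clades=clades)


class TestSizesFromPartitions:
    def test_single_parent_counts_children(self):
        parent = partition("phylum", [{"a", "b", "c", "d"}])
        child = partition("genus", [{"a"}, {"b"}, {"c", "d"}])
        dist = sizes_from_partitions(parent, child)
        assert dist.counts == {3: 1}

    def test_tips_unit(self):
        parent = partition("genus", [{"a", "b"}, {"c", "d"}, {"e", "f"}])
        dist = sizes_from_partitions(parent, "tips")
        assert dist.counts == {2: 3}
        assert dist.total_units == 6

    def test_conservation_of_child_units(self):
        parent = partition("family", [{"a", "b", "c"}, {"d", "e"}])
        child = partition("genus", [{"a"}, {"b", "c"}, {"d"}, {"e"}])
        dist = sizes_from_partitions(parent, child)
        assert dist.total_units == len(child.clades)

    def test_non_nested_rejected(self):
        parent = partition("family", [{"a", "b"}, {"c", "d"}])
        child = partition("genus", [{"b", "c"}, {"a"}, {"d"}])
        with pytest.raises(ValueError, match="refine"):
            sizes_from_partitions(parent, child)

    def test_planted_tree_matches_label_counting(self):
        from microcensus import simulate_yule_tree

        sim = simulate_yule_tree(200, seed=21)
        red = compute_red(sim.tree)
        parts = {}
        for rank in ("family", "genus"):
            labels = dict(sim.labels[rank])
            from microcensus import calibrate_cutoffs

            cutoff = calibrate_cutoffs(red, labels, rank).cutoff
            parts[rank] = cut_at_red(red, cutoff, rank=rank)
        dist = sizes_from_partitions(parts["family"], parts["genus"])
        # oracle: count planted genus labels inside each planted family label
        tab = sim.labels.groupby("family")["genus"].nunique()
        expected = tab.value_counts().sort_index()
        assert dist.counts == {int(k): int(v) for k, v in expected.items()}


class TestSizesFromTaxonomy:
    def test_simple_counts(self):
        tax = pd.DataFrame(
            {
                "genus": ["g1", "g1", "g2", "g2", "g3", "g3"],
                "species": ["s1", "s2", "s3", "s4", "s5", "s6"],
            }
        )
        dist = sizes_from_taxonomy_table(tax, "genus", "species")
        assert dist.counts == {2: 3}

    def test_single_pair(self):
        tax = pd.DataFrame({"genus": ["g1"], "species": ["s1"]})
        assert sizes_from_taxonomy_table(tax, "genus", "species").counts == {1: 1}

    def test_placeholders_excluded_and_groupby_oracle(self):
        rng = np.random.default_rng(5)
        genera = rng.choice([f"g{i}" for i in range(30)] + [""], size=500)
        species = [f"s{i}" for i in range(500)]
        tax = pd.DataFrame({"genus": genera, "species": species})
        dist = sizes_from_taxonomy_table(tax, "genus", "species")
        oracle = (
            tax[tax["genus"] != ""].groupby("genus")["species"].nunique().value_counts()
        )
        assert dist.counts == {int(k): int(v) for k, v in oracle.items()}

    def test_missing_rank_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            sizes_from_taxonomy_table(pd.DataFrame({"genus": []}), "genus", "species")


class TestStratifiedFits:
    def test_single_stratum_equals_unstratified(self):
        dist = CladeSizeDistribution.from_sizes(
            stats.yulesimon.rvs(1.5, size=5000, random_state=2)
        )
        out = stratified_fits({"global": {"mk": dist}})
        assert out["rho"].iloc[0] == pytest.approx(fit_yule_simon(dist).rho)

    def test_identical_strata_identical_rho(self):
        dist = CladeSizeDistribution({1: 40, 2: 20, 3: 10, 6: 2})
        out = stratified_fits({"a": {"mk": dist}, "b": {"mk": dist}})
        assert out["rho"].nunique() == 1

    def test_innovation_rate_orders_rho(self):
        """Higher innovation probability -> weaker attachment -> higher rho."""
        strata = {}
        for name, p in [("low", 0.2), ("high", 0.6)]:
            strata[name] = {
                f"mk{s}": simulate_simon_clades(
                    SimonProcessParams(20_000, p, seed=s)
                )
                for s in range(3)
            }
        out = stratified_fits(strata).set_index("stratum")["rho"]
        assert out["low"] < out["high"]
        assert out["low"] == pytest.approx(1 / (1 - 0.2), rel=0.15)
        assert out["high"] == pytest.approx(1 / (1 - 0.6), rel=0.15)
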