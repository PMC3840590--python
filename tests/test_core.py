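"""Randomization engine: sampling, null building, empirical p-value."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mset import (
    Background,
    GeneSet,
    NullDistribution,
    build_null,
    count_matches,
    empirical_p,
    run_mset,
    sample_simulated_results,
)
from mset.core import simulate_match_counts
from mset.genelist_io import RankedRecord
from mset.oracle import HypergeomSpec, hypergeom_tail


def _records(symbols):
    return [
        RankedRecord(probe_id=f"p{i + 1}", symbol=s, rank=i + 1)
        for i, s in enumerate(symbols)
    ]


class TestCountMatches:
    def test_roster_preserves_order(self):
        gs = GeneSet.from_symbols(["FOXP2", "NPY"], name="t")
        n, roster = count_matches(["FOXP2", "NPY", "ACTB"], gs)
        assert (n, roster) == (2, ("FOXP2", "NPY"))

    def test_disjoint_gives_zero(self):
        gs = GeneSet.from_symbols(["X"], name="t")
        assert count_matches(["A", "B"], gs) == (0, ())

    def test_subset_gives_full_length(self):
        gs = GeneSet.from_symbols(["A", "B", "C", "D"], name="t")
        n, _ = count_matches(["A", "B", "C"], gs)
        assert n == 3


class TestSampling:
    def test_forced_outcome(self):
        bg = Background.from_symbols(["A", "A", "A", "B"])
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert set(sample_simulated_results(bg, 2, rng)) == {"A", "B"}

    def test_exhaustive_draw_returns_full_complement(self):
        bg = Background.from_symbols(["A", "B", "C", "D"])
        rng = np.random.default_rng(0)
        assert set(sample_simulated_results(bg, 4, rng)) == {"A", "B", "C", "D"}

    def test_result_unique_length_L_from_background(self):
        bg = Background.from_symbols(["A", "A", "B", "C", "C", "D", "E"])
        rng = np.random.default_rng(3)
        for _ in range(50):
            draw = sample_simulated_results(bg, 3, rng)
            assert len(draw) == len(set(draw)) == 3
            assert set(draw) <= set(bg.unique_genes)

    def test_L_larger_than_gene_complement_errors(self):
        bg = Background.from_symbols(["A", "A", "B"])
        with pytest.raises(ValueError):
            sample_simulated_results(bg, 3, np.random.default_rng(0))

    def test_first_draw_weighting(self):
        # gene A on 10 probes, 9 others on one each: P(A drawn first) = 10/19
        bg = Background.from_symbols(["A"] * 10 + list("BCDEFGHIJ"))
        gs = GeneSet.from_symbols(["A"], name="a")
        n_sims = 100_000
        counts = simulate_match_counts(bg, 1, gs, n_sims, seed=7)
        p_emp = counts.mean()
        p_true = 10 / 19
        se = np.sqrt(p_true * (1 - p_true) / n_sims)
        assert abs(p_emp - p_true) <= 3 * se

    def test_multiplicity_increases_inclusion_frequency(self):
        # same gene count, unequal probe counts -> monotone inclusion rates
        bg = Background.from_symbols(
            ["A"] * 6 + ["B"] * 3 + ["C"] * 1 + list("DEFGH")
        )
        n_sims = 40_000
        freqs = {}
        for g in "ABC":
            gs = GeneSet.from_symbols([g], name=g)
            freqs[g] = simulate_match_counts(bg, 3, gs, n_sims, seed=11).mean()
        assert freqs["A"] > freqs["B"] > freqs["C"]


class TestNull:
    def test_disjoint_target_point_mass_at_zero(self):
        bg = Background.from_symbols(["A", "B", "C", "D"])
        gs = GeneSet.from_symbols(["X"], name="t")
        null = build_null(bg, 2, gs, 500, seed=0)
        assert null.counts == {0: 500}

    def test_superset_target_point_mass_at_L(self):
        bg = Background.from_symbols(["A", "A", "B", "C"])
        gs = GeneSet.from_symbols(["A", "B", "C"], name="t")
        null = build_null(bg, 3, gs, 500, seed=0)
        assert null.counts == {3: 500}

    def test_mass_equals_n_sims(self):
        bg = Background.from_symbols(["A", "A", "B", "C", "D", "E"])
        gs = GeneSet.from_symbols(["A", "D"], name="t")
        null = build_null(bg, 3, gs, 1234, seed=5)
        assert sum(null.counts.values()) == null.n_sims == 1234

    def test_hypergeometric_mean_on_duplicate_free_background(self):
        N, K, L, n_sims = 10, 5, 4, 100_000
        bg = Background.from_symbols([f"G{i}" for i in range(N)])
        gs = GeneSet.from_symbols([f"G{i}" for i in range(K)], name="t")
        counts = simulate_match_counts(bg, L, gs, n_sims, seed=3)
        mean_true = L * K / N
        sd = counts.std(ddof=1) / np.sqrt(n_sims)
        assert abs(counts.mean() - mean_true) <= 3 * sd

    def test_invalid_histogram_rejected(self):
        with pytest.raises(ValueError):
            NullDistribution(counts={0: 3, 1: 2}, n_sims=4)


class TestEmpiricalP:
    def test_tail_proportion(self):
        null = NullDistribution(
            counts={0: 5000, 1: 3000, 2: 1500, 3: 500}, n_sims=10_000
        )
        assert empirical_p(null, 2) == pytest.approx(0.2)

    def test_observed_zero_is_one(self):
        null = NullDistribution(counts={0: 5, 2: 5}, n_sims=10)
        assert empirical_p(null, 0) == 1.0

    def test_observed_beyond_support_is_zero(self):
        null = NullDistribution(counts={0: 5, 2: 5}, n_sims=10)
        assert empirical_p(null, 3) == 0.0

    @given(
        st.dictionaries(
            st.integers(min_value=0, max_value=8),
            st.integers(min_value=1, max_value=100),
            min_size=1,
        )
    )
    def test_monotone_non_increasing_in_observed(self, counts):
        null = NullDistribution(counts=counts, n_sims=sum(counts.values()))
        ps = [empirical_p(null, k) for k in range(0, 11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert ps[0] == 1.0


class TestRunMset:
    def test_disjoint_target_p_one(self):
        records = _records(["A", None, "B", "C", "D"])
        gs = GeneSet.from_symbols(["X", "Y"], name="t")
        res = run_mset(records, gs, n_top=2, n_sims=200, seed=1)
        assert res.observed_matches == 0
        assert res.matched_genes == ()
        assert res.p_value == 1.0

    def test_bit_identical_for_same_seed(self):
        records = _records(["A", "B", None, "C", "A", "D", "E", "F"])
        gs = GeneSet.from_symbols(["B", "E"], name="t")
        r1 = run_mset(records, gs, n_top=3, n_sims=500, seed=42)
        r2 = run_mset(records, gs, n_top=3, n_sims=500, seed=42)
        assert r1 == r2
        assert r1.to_json() == r2.to_json()

    def test_empirical_p_tracks_hypergeometric_oracle(self):
        # duplicate-free background: the null is exactly hypergeometric
        N, K, L, n_sims = 40, 10, 8, 100_000
        symbols = [f"G{i:02d}" for i in range(N)]
        records = _records(symbols)
        gs = GeneSet.from_symbols(symbols[:K], name="t")
        res = run_mset(records, gs, n_top=L, n_sims=n_sims, seed=9)
        p_true = hypergeom_tail(
            HypergeomSpec(N=N, K=K, n=L, k=res.observed_matches)
        )
        se = np.sqrt(p_true * (1 - p_true) / n_sims)
        assert abs(res.p_value - p_true) <= 3 * se

    def test_result_records_run_parameters(self):
        records = _records(["A", "B", "C", None, "D"])
        gs = GeneSet.from_symbols(["A", "D"], name="db1")
        res = run_mset(records, gs, n_top=3, n_sims=300, seed=8,
                       dataset_name="ds1")
        assert (res.database_name, res.dataset_name) == ("db1", "ds1")
        assert (res.L, res.n_sims, res.seed, res.n_top) == (3, 300, 8, 3)
        assert res.background_n_targets == 4
        assert res.background_n_unique_genes == 4
        assert res.gene_set_size == 2
        assert res.observed_matches == len(res.matched_genes) == 1
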