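import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from mirpathnet import (
    CountMatrix,
    SimulationConfig,
    differential_expression,
    estimate_common_dispersion,
    exact_nb_pvalue,
    exact_test_feature,
    normalize_library_sizes,
    significant_features,
    simulate_counts,
)
from mirpathnet.diffexpr import bh_adjust, depth_adjusted_counts
from mirpathnet.types import FormatError
from oracles import bh_stepup_reference, conditional_nb_pvalue_by_convolution


def _matrix(counts, n_tumor):
    counts = pd.DataFrame(
        np.asarray(counts),
        index=[f"g{i}" for i in range(len(counts))],
        columns=[f"s{j}" for j in range(np.asarray(counts).shape[1])],
    )
    cond = pd.Series(
        ["tumor"] * n_tumor + ["control"] * (counts.shape[1] - n_tumor),
        index=counts.columns, dtype=object,
    )
    return CountMatrix(counts, cond)


class TestTMMNormalization:
    def test_identical_samples_get_equal_sizes(self, rng):
        col = rng.integers(0, 500, size=100)
        m = _matrix(np.column_stack([col, col, col, col]), 2)
        eff = normalize_library_sizes(m)
        assert np.allclose(eff, eff.iloc[0])

    def test_pure_depth_doubling(self, rng):
        col = rng.integers(1, 500, size=200)
        m = _matrix(np.column_stack([col, 2 * col, col, 2 * col]), 2)
        eff = normalize_library_sizes(m)
        assert eff["s1"] / eff["s0"] == pytest.approx(2.0, rel=1e-6)

    def test_factors_geometric_mean_one(self, rng):
        counts = rng.integers(0, 300, size=(300, 8))
        m = _matrix(counts, 4)
        eff = normalize_library_sizes(m)
        factors = eff.to_numpy() / m.counts.sum(axis=0).to_numpy()
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_sample_rejected(self):
        counts = np.array([[1, 0, 2, 1], [3, 0, 1, 2]])
        with pytest.raises(FormatError, match="all-zero"):
            normalize_library_sizes(_matrix(counts, 2))


class TestDispersionEstimate:
    def test_poisson_data_near_zero(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(100, size=(2000, 60))
        phi = estimate_common_dispersion(_matrix(counts, 30))
        assert 0 <= phi < 0.02

    def test_recovers_planted_dispersion(self):
        rng = np.random.default_rng(6)
        phi_true, mu = 0.2, 100.0
        r = 1 / phi_true
        counts = rng.negative_binomial(r, r / (r + mu), size=(2000, 100))
        phi = estimate_common_dispersion(_matrix(counts, 50))
        assert 0.1 <= phi <= 0.3

    def test_constant_counts_give_zero(self):
        phi = estimate_common_dispersion(_matrix(np.full((5, 6), 7), 3))
        assert phi == 0.0

    def test_requires_two_per_group(self):
        with pytest.raises(FormatError, match="2 samples"):
            estimate_common_dispersion(_matrix(np.ones((3, 3), dtype=int), 1))


class TestExactTest:
    def test_identical_groups_p_one(self):
        assert exact_nb_pvalue(5, 5, 2, 2, 0.1) == 1.0
        assert exact_nb_pvalue(0, 0, 3, 3, 0.0) == 1.0

    def test_poisson_limit_matches_binomial(self):
        # totals 10 vs 0, equal group sizes: conditional law is Binom(10, 1/2)
        assert exact_nb_pvalue(10, 0, 3, 3, 0.0) == pytest.approx(2 * 0.5**10, rel=1e-12)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError, match="phi"):
            exact_nb_pvalue(1, 2, 2, 2, -0.1)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    @pytest.mark.parametrize("sizes", [(2, 2), (3, 2)])
    def test_matches_convolution_oracle_small_totals(self, phi, sizes):
        n_a, n_b = sizes
        for s in range(1, 21):
            for a in range(s + 1):
                got = exact_nb_pvalue(a, s - a, n_a, n_b, phi)
                want = conditional_nb_pvalue_by_convolution(a, s - a, n_a, n_b, phi)
                assert got == pytest.approx(want, abs=1e-9), (phi, sizes, s, a)

    def test_effective_size_rescaling(self):
        # group B sequenced twice as deep; identical underlying expression
        p = exact_test_feature(
            np.array([10, 10]), np.array([20, 20]), 0.0,
            eff_a=np.array([1.0, 1.0]), eff_b=np.array([2.0, 2.0]),
        )
        assert p == 1.0


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.01]) == pytest.approx([0.01])

    def test_stepup_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.05] * 10) == pytest.approx([0.05] * 10)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50)
    def test_matches_references(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 50))
        ours = bh_adjust(p)
        assert np.allclose(ours, bh_stepup_reference(p), atol=1e-12)
        assert np.allclose(ours, multipletests(p, method="fdr_bh")[1], atol=1e-12)


class TestDifferentialExpression:
    def test_null_simulation_makes_no_calls(self):
        config = SimulationConfig(
            n_genes=500, n_mirnas=10, n_tumor=20, n_control=20,
            n_de_genes=0, n_de_mirnas=0, dispersion=0.1, seed=42, hub=None,
            n_target_genes=0,
        )
        mrna, _, _ = simulate_counts(config)
        de = differential_expression(mrna)
        assert len(significant_features(de)) == 0

    def test_recovers_planted_features(self):
        config = SimulationConfig(
            n_genes=500, n_mirnas=10, n_tumor=60, n_control=30,
            n_de_genes=50, n_de_mirnas=0, dispersion=0.1, seed=43, hub=None,
            n_target_genes=0,
        )
        mrna, _, truth = simulate_counts(config)
        called = set(significant_features(differential_expression(mrna)))
        sensitivity = len(called & set(truth.de_gene_ids)) / len(truth.de_gene_ids)
        assert sensitivity >= 0.8

    def test_boundary_log2fc_exactly_one_not_significant(self):
        # 40 vs 20 samples, means 200 vs ~99.8 give log2fc == 1.0 exactly only
        # in the constructed case below; strict ">" must exclude it
        rng = np.random.default_rng(0)
        base = rng.poisson(100, size=(50, 12))
        m = _matrix(base, 6)
        de = differential_expression(m, lfc_cut=10.0)  # nothing can pass strict cut
        assert (de["direction"] == "ns").all()
        de2 = differential_expression(m, lfc_cut=0.0, lfc_inclusive=True)
        # inclusive at 0 lets p decide: directions may appear; the rule itself
        # is exercised at pathway level, here we just check both code paths run
        assert set(de2["direction"]) <= {"up", "down", "ns"}

    def test_label_swap_flips_log2fc_and_keeps_p(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson([[50], [500], [20]] * np.ones((3, 8)), size=(3, 8)).astype(int)
        m = _matrix(counts, 4)
        swapped = CountMatrix(
            m.counts.copy(),
            m.condition.map({"tumor": "control", "control": "tumor"}),
        )
        de = differential_expression(m)
        de_swapped = differential_expression(swapped)
        assert np.allclose(de["log2fc"], -de_swapped["log2fc"], atol=1e-12)
        assert np.allclose(de["p_value"], de_swapped["p_value"], atol=1e-12)

    def test_pvalues_superuniform_under_null(self):
        config = SimulationConfig(
            n_genes=2000, n_mirnas=10, n_tumor=30, n_control=30,
            n_de_genes=0, n_de_mirnas=0, dispersion=0.0, seed=44, hub=None,
            n_target_genes=0,
        )
        mrna, _, _ = simulate_counts(config)
        p = differential_expression(mrna)["p_value"].to_numpy()
        for t in (0.01, 0.05, 0.1):
            se = np.sqrt(t * (1 - t) / len(p))
            assert (p <= t).mean() <= t + 3 * se


def test_depth_adjustment_removes_library_effect():
    rng = np.random.default_rng(9)
    base = rng.integers(50, 150, size=(400, 1))
    lib = np.array([0.5, 1.0, 2.0, 4.0, 0.5, 1.0, 2.0, 4.0])
    counts = rng.poisson(base * lib[None, :])
    m = _matrix(counts, 4)
    adj = depth_adjusted_counts(m)
    col_means = adj.mean(axis=0).to_numpy()
    assert col_means.max() / col_means.min() < 1.1
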