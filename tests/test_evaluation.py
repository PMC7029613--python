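import itertools

import numpy as np
import pandas as pd
import pytest

from ipco import (
    FeatureTable,
    TableRole,
    ValidationConfig,
    associate_with_metadata,
    bin_by_coverage,
    bootstrap_validate,
    feature_correlations,
    sample_correlations,
    spearman,
    spearman_with_pvalue,
)


def _ft(vals, prefix, role=TableRole.FUNCTIONAL, sample_prefix="s"):
    vals = np.asarray(vals, float)
    return FeatureTable(vals, [f"{prefix}{i}" for i in range(vals.shape[0])],
                        [f"{sample_prefix}{j}" for j in range(vals.shape[1])],
                        role)


class TestSpearman:
    def test_monotone_identity(self):
        assert spearman([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)

    def test_reversal(self):
        assert spearman([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_tied_data_matches_rank_then_pearson(self):
        x, y = [1, 1, 2, 3], [4, 5, 6, 7]
        # independent oracle: average ranks, then plain Pearson
        rx = np.array([1.5, 1.5, 3.0, 4.0])
        ry = np.array([1.0, 2.0, 3.0, 4.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_is_missing(self):
        assert np.isnan(spearman([1, 1, 1], [1, 2, 3]))

    def test_short_input_error(self):
        with pytest.raises(ValueError, match="3"):
            spearman([1, 2], [3, 4])

    def test_missing_pairs_removed(self):
        rho = spearman([1, 2, 3, np.nan], [1, 2, 3, 100])
        assert rho == pytest.approx(1.0)

    def test_exact_pvalue_matches_enumeration(self):
        x, y = [3, 1, 4, 1, 5], [2, 7, 1, 8, 2]
        rho, p = spearman_with_pvalue(x, y)
        # brute-force enumeration over all orderings of y
        from scipy.stats import rankdata
        rx, ry = rankdata(x), rankdata(y)
        rxc, ryc = rx - rx.mean(), ry - ry.mean()
        denom = np.sqrt((rxc @ rxc) * (ryc @ ryc))
        null = [abs((rxc @ ryc[list(perm)]) / denom)
                for perm in itertools.permutations(range(5))]
        expected = np.mean(np.asarray(null) >= abs(rho) - 1e-12)
        assert p == pytest.approx(expected)

    def test_large_n_pvalue_matches_t_approximation(self, rng):
        x = rng.standard_normal(30)
        y = x + rng.standard_normal(30)
        from scipy.stats import spearmanr
        rho, p = spearman_with_pvalue(x, y)
        ref = spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestDirectionalCorrelations:
    def test_self_comparison_all_one(self, rng):
        F = _ft(rng.random((6, 5)), "f")
        assert np.allclose(sample_correlations(F, F), 1.0)
        assert np.allclose(feature_correlations(F, F), 1.0)

    def test_monotone_transform_invariance(self, rng):
        F = _ft(rng.random((6, 5)), "f")
        G = FeatureTable(np.exp(2.5 * F.values), F.feature_ids, F.sample_ids,
                         TableRole.FUNCTIONAL)
        assert np.allclose(sample_correlations(F, G), 1.0)

    def test_independent_tables_near_zero(self):
        # feature-direction null: mean |rho| stays small
        rhos = []
        for s in range(25):
            g = np.random.default_rng(s)
            A = _ft(g.random((200, 10)), "f")
            B = _ft(g.random((200, 10)), "f")
            rhos.append(np.abs(sample_correlations(A, B)).mean())
        assert np.mean(rhos) <= 0.15

    def test_no_shared_samples_error(self, rng):
        A = _ft(rng.random((4, 3)), "f")
        B = _ft(rng.random((4, 3)), "f", sample_prefix="other")
        with pytest.raises(ValueError, match="sample"):
            sample_correlations(A, B)


class TestBootstrapValidate:
    def test_partition_property(self, small_dataset):
        R, L = small_dataset.functional_true, small_dataset.taxa_counts
        cfg = ValidationConfig(reference_fraction=0.5, n_iterations=1, seed=3)
        res = bootstrap_validate(R, L, L, R, cfg)
        row = res.per_iteration_sample_rho.iloc[0]
        n = len(small_dataset.taxa_counts.sample_ids)
        # query side = samples with a correlation; reference = the rest
        assert row.notna().sum() == n - round(0.5 * n)

    def test_bit_reproducible(self, small_dataset):
        R, L = small_dataset.functional_true, small_dataset.taxa_counts
        cfg = ValidationConfig(reference_fraction=0.5, n_iterations=3, seed=9)
        a = bootstrap_validate(R, L, L, R, cfg)
        b = bootstrap_validate(R, L, L, R, cfg)
        pd.testing.assert_frame_equal(a.per_iteration_feature_rho,
                                      b.per_iteration_feature_rho)
        pd.testing.assert_frame_equal(a.per_iteration_sample_rho,
                                      b.per_iteration_sample_rho)

    def test_correlations_bounded(self, small_dataset):
        R, L = small_dataset.functional_true, small_dataset.taxa_counts
        cfg = ValidationConfig(reference_fraction=0.5, n_iterations=2, seed=1)
        res = bootstrap_validate(R, L, L, R, cfg)
        v = res.per_iteration_feature_rho.to_numpy()
        assert np.nanmax(np.abs(v)) <= 1.0 + 1e-12

    def test_shuffle_kills_feature_signal_not_sample_signal(self, small_dataset):
        R, L = small_dataset.functional_true, small_dataset.taxa_counts
        base = bootstrap_validate(R, L, L, R, ValidationConfig(0.5, 10, seed=5))
        null = bootstrap_validate(
            R, L, L, R, ValidationConfig(0.5, 10, seed=5, shuffle_reference=True))
        assert base.mean_feature_rho.median() > 0.3
        assert abs(null.mean_feature_rho.median()) <= 0.15
        # functional redundancy keeps sample-wise correlation high even
        # under the shuffled reference
        assert null.mean_sample_rho.median() > 0.3

    def test_too_small_side_error(self, small_dataset):
        R, L = small_dataset.functional_true, small_dataset.taxa_counts
        with pytest.raises(ValueError, match="< 3"):
            bootstrap_validate(R, L, L, R, ValidationConfig(0.95, 1, seed=0))


class TestBinByCoverage:
    def test_fixed_scheme_example(self):
        cov = _ft(np.array([[0.005], [0.05], [0.5]]), "p", TableRole.COVERAGE)
        bins = bin_by_coverage(cov, scheme="fixed", low_cut=0.01, high_cut=0.1)
        assert [bins.assignment[f] for f in cov.feature_ids] == \
            ["low", "medium", "high"]
        assert bins.counts == {"low": 1, "medium": 1, "high": 1}

    def test_degenerate_quantiles_single_bin(self):
        cov = _ft(np.full((5, 3), 0.7), "p", TableRole.COVERAGE)
        bins = bin_by_coverage(cov, scheme="quantile")
        assert len(set(bins.assignment.values())) == 1

    def test_quantile_counts(self):
        g = np.random.default_rng(0)
        cov = _ft(g.random((1000, 1)), "p", TableRole.COVERAGE)
        bins = bin_by_coverage(cov, scheme="quantile", q_low=0.25, q_high=0.5)
        # multinomial sampling error around (250, 250, 500)
        assert abs(bins.counts["low"] - 250) < 60
        assert abs(bins.counts["medium"] - 250) < 60
        assert abs(bins.counts["high"] - 500) < 60
        assert sum(bins.counts.values()) == 1000

    def test_empty_table_error(self):
        with pytest.raises(ValueError, match="empty"):
            bin_by_coverage(FeatureTable(np.empty((0, 0)), [], [],
                                         TableRole.COVERAGE))

    def test_bad_cuts_error(self):
        cov = _ft(np.array([[0.5]]), "p", TableRole.COVERAGE)
        with pytest.raises(ValueError, match="low_cut"):
            bin_by_coverage(cov, scheme="fixed", low_cut=0.5, high_cut=0.1)


class TestAssociate:
    def test_self_association_rho_one(self, rng):
        F = _ft(rng.random((3, 8)), "f")
        M = FeatureTable(F.values[:1].copy(), ["m0"], F.sample_ids,
                         TableRole.METABOLITE)
        df = associate_with_metadata(F, M)
        hit = df[(df.function_id == "f0") & (df.metabolite_id == "m0")]
        assert hit.rho.iloc[0] == pytest.approx(1.0)

    def test_bh_step_up_by_hand(self):
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03])

    def test_adjustment_monotone_and_bounded(self, rng):
        F = _ft(rng.random((5, 12)), "f")
        M = _ft(rng.random((4, 12)), "m", TableRole.METABOLITE)
        df = associate_with_metadata(F, M).dropna(subset=["p_value"])
        assert (df.p_adjusted >= df.p_value - 1e-12).all()
        s = df.sort_values("p_value")
        assert s.p_adjusted.is_monotonic_increasing

    def test_log_transform_is_rank_neutral(self, rng):
        F = _ft(rng.random((4, 10)), "f")
        M = _ft(rng.random((3, 10)), "m", TableRole.METABOLITE)
        a = associate_with_metadata(F, M, log_metabolites=True)
        b = associate_with_metadata(F, M, log_metabolites=False)
        np.testing.assert_allclose(a.rho, b.rho, atol=1e-12)

    def test_direction_is_sign_of_rho(self, rng):
        F = _ft(rng.random((4, 10)), "f")
        M = _ft(rng.random((3, 10)), "m", TableRole.METABOLITE)
        df = associate_with_metadata(F, M).dropna(subset=["rho"])
        assert (df.direction == np.sign(df.rho)).all()

    def test_too_few_shared_samples_error(self, rng):
        F = _ft(rng.random((3, 4)), "f")
        M = _ft(rng.random((2, 4)), "m", TableRole.METABOLITE,
                sample_prefix="other")
        with pytest.raises(ValueError, match="shared"):
            associate_with_metadata(F, M)
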