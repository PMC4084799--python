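"""Paired/moderated tests, pi0, q-values and directional enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from exoninclusion.difftest import (
    ModerationParams,
    bin_direction,
    compute_qvalues,
    direction_enrichment,
    estimate_pi0,
    expression_level_contrast,
    fit_moderation,
    moderated_t_tests,
    paired_t_tests,
    run_tests,
)
from exoninclusion.inclusion import apply_detection_filters, compute_inclusion

from .conftest import make_bundle, make_design


def table_from_diffs(diffs: np.ndarray) -> pd.DataFrame:
    """Build an inclusion-like matrix whose pair differences equal diffs."""
    m, n = diffs.shape
    design = make_design(n)
    values = np.zeros((m, 2 * n))
    values[:, 0::2] = diffs  # cases T_i; controls stay 0
    cols = [s for i in range(1, n + 1) for s in (f"T{i}", f"C{i}")]
    return (pd.DataFrame(values,
                         index=[f"ps{i}" for i in range(m)], columns=cols),
            design)


class TestPairedT:
    def test_zero_mean_gives_t_zero_p_one(self):
        values, design = table_from_diffs(np.array([[1., -1., 1., -1.]]))
        out = paired_t_tests(values, design)
        assert out["t"].iloc[0] == pytest.approx(0.0)
        assert out["p_plain"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_example(self):
        diffs = np.array([[2.1, 1.3, 0.8, 1.8]])
        values, design = table_from_diffs(diffs)
        out = paired_t_tests(values, design)
        # independent oracle
        t_ref, p_ref = stats.ttest_1samp(diffs[0], 0.0)
        assert out["t"].iloc[0] == pytest.approx(t_ref, abs=1e-12)
        assert out["p_plain"].iloc[0] == pytest.approx(p_ref, abs=1e-12)
        assert out["t"].iloc[0] == pytest.approx(5.25, abs=0.01)
        assert out["p_plain"].iloc[0] == pytest.approx(0.013, abs=0.001)
        assert out["df"].iloc[0] == 3

    def test_zero_variance_flagged_and_undefined(self):
        values, design = table_from_diffs(np.array([[1., 1., 1., 1.]]))
        out = paired_t_tests(values, design)
        assert bool(out["zero_variance"].iloc[0])
        assert np.isnan(out["t"].iloc[0])

    def test_single_pair_rejected(self):
        values, design = table_from_diffs(np.array([[1., 2.]]))
        design = design[design["pair"] == "P1"]
        with pytest.raises(ValueError, match="at least 2 pairs"):
            paired_t_tests(values[["T1", "C1"]], design)

    def test_mirror_symmetry_of_two_sided_p(self, default_dataset):
        """Global case/control swap leaves every two-sided p unchanged."""
        bundle, _ = default_dataset
        filtered, _ = apply_detection_filters(bundle)
        incl = compute_inclusion(filtered)
        out = paired_t_tests(incl, bundle.design)
        mirrored = bundle.design.copy()
        mirrored["status"] = mirrored["status"].map(
            {"case": "control", "control": "case"})
        out_m = paired_t_tests(incl, mirrored)
        np.testing.assert_allclose(out["p_plain"], out_m["p_plain"],
                                   atol=1e-12)
        np.testing.assert_allclose(out["t"], -out_m["t"], atol=1e-12)


class TestModeration:
    def test_posterior_variance_arithmetic(self):
        # d0=4, s0^2=1, d=3, s^2=2 -> posterior (4*1+3*2)/7 = 10/7
        table = pd.DataFrame(
            {"mean_diff": [1.0], "s2": [2.0], "n_pairs": [4], "df": [3],
             "t": [1.0], "p_plain": [0.5]})
        out = moderated_t_tests(table, ModerationParams(d0=4, s02=1.0, d=3))
        assert out["s2_post"].iloc[0] == pytest.approx(10 / 7)

    def test_d0_zero_limit_equals_plain_t(self, default_dataset):
        bundle, _ = default_dataset
        filtered, _ = apply_detection_filters(bundle)
        incl = compute_inclusion(filtered)
        table = paired_t_tests(incl, bundle.design)
        out = moderated_t_tests(
            table, ModerationParams(d0=0.0, s02=1.0, d=3.0))
        ok = ~table["zero_variance"]
        np.testing.assert_allclose(out.loc[ok, "t_mod"],
                                   table.loc[ok, "t"], atol=1e-9)
        np.testing.assert_allclose(out.loc[ok, "p_mod"],
                                   table.loc[ok, "p_plain"], atol=1e-9)

    def test_p_mod_matches_t_distribution_oracle(self, default_dataset):
        bundle, _ = default_dataset
        filtered, _ = apply_detection_filters(bundle)
        incl = compute_inclusion(filtered)
        table = paired_t_tests(incl, bundle.design)
        params = ModerationParams(d0=4.0, s02=0.1, d=3.0)
        out = moderated_t_tests(table, params)
        # independent survival-function recomputation at df = d0 + d
        expected = 2.0 * stats.t.sf(np.abs(out["t_mod"]),
                                    df=params.d0 + params.d)
        np.testing.assert_allclose(out["p_mod"], expected, atol=1e-12)

    def test_infinite_d0_uses_normal_reference(self, default_dataset):
        # constant-noise simulated data has no excess variance spread, so
        # the fitted prior is degenerate (d0 infinite) and p comes from
        # the normal limit of the t distribution
        bundle, _ = default_dataset
        filtered, _ = apply_detection_filters(bundle)
        incl = compute_inclusion(filtered)
        table, params = run_tests(incl, bundle.design)
        assert np.isinf(params.d0)
        expected = 2.0 * stats.norm.sf(np.abs(table["t_mod"]))
        np.testing.assert_allclose(table["p_mod"], expected, atol=1e-12)

    def test_moderated_and_plain_signs_agree(self, default_dataset):
        bundle, _ = default_dataset
        filtered, _ = apply_detection_filters(bundle)
        incl = compute_inclusion(filtered)
        table, _ = run_tests(incl, bundle.design)
        ok = ~table["zero_variance"] & (table["t"] != 0)
        assert (np.sign(table.loc[ok, "t_mod"])
                == np.sign(table.loc[ok, "t"])).all()

    def test_hyperparameter_recovery(self):
        # simulation oracle: s2 ~ s0^2 (chi2_d/d)/(chi2_d0/d0)
        rng = np.random.default_rng(42)
        d0, s02, d, m = 4.0, 1.0, 3.0, 10_000
        s2 = s02 * (rng.chisquare(d, m) / d) / (rng.chisquare(d0, m) / d0)
        params = fit_moderation(s2, d)
        assert params.d0 == pytest.approx(d0, abs=1.5)
        assert params.s02 == pytest.approx(s02, rel=0.15)

    def test_constant_variances_give_infinite_d0(self):
        d = 3.0
        params = fit_moderation(np.full(500, 2.0), d=d)
        assert np.isinf(params.d0)
        # closed-form moment match: s0^2 = s2 * exp(log(d/2) - digamma(d/2))
        from scipy.special import digamma
        expected = 2.0 * np.exp(np.log(d / 2) - digamma(d / 2))
        assert params.s02 == pytest.approx(expected, rel=1e-9)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(43)
        s2 = rng.chisquare(3, 2000) / 3
        a = fit_moderation(s2, d=3.0)
        b = fit_moderation(2 * s2, d=3.0)
        assert b.d0 == pytest.approx(a.d0, rel=1e-9)
        assert b.s02 == pytest.approx(2 * a.s02, rel=1e-9)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError, match="all variances are zero"):
            fit_moderation(np.zeros(200), d=3.0)


class TestPi0:
    def test_raw_trajectory_arithmetic(self):
        # m = 100 with 40 p-values above 0.5 -> raw pi0(0.5) = 0.8
        p = np.concatenate([np.linspace(0.001, 0.4, 60),
                            np.linspace(0.51, 0.99, 40)])
        est = estimate_pi0(p)
        lam_idx = est.lambda_grid.index(0.5)
        assert est.raw_pi0[lam_idx] == pytest.approx(
            40 / (100 * 0.5), abs=1e-12)

    def test_ideal_uniform_estimates_near_one(self):
        m = 10_000
        p = (np.arange(1, m + 1) - 0.5) / m
        est = estimate_pi0(p)
        assert 0.98 <= est.pi0 <= 1.0

    def test_all_small_p_clipped_near_zero(self):
        p = np.random.default_rng(0).uniform(0, 0.04, 500)
        with np.errstate(all="ignore"):
            est = estimate_pi0(p)
        assert est.pi0 <= 0.05
        assert all(r == 0 for r, lam in
                   zip(est.raw_pi0, est.lambda_grid) if lam >= 0.05)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="lie in"):
            estimate_pi0(np.array([0.1, 1.2] * 100))
        with pytest.raises(ValueError, match="grid"):
            estimate_pi0(np.random.default_rng(1).random(200),
                         lambda_grid=(0.2, 0.5))

    def test_null_pvalue_histogram_uniform_and_pi0_high(self):
        """pi0_true = 1: uniform p histogram (chi2, 20 bins, alpha=0.01,
        <=1 failure in 20 seeds); pi0 >= 0.9 at the calibrated size
        (m >= 10,000 tests)."""
        from exoninclusion.simulate import SimulationParams, generate_dataset

        def null_pvalues(n_genes, seed):
            bundle, _ = generate_dataset(SimulationParams(
                n_genes=n_genes, pi0_true=1.0, seed=seed))
            filtered, _ = apply_detection_filters(bundle)
            incl = compute_inclusion(filtered)
            table = paired_t_tests(incl, bundle.design)
            return table.loc[~table["zero_variance"], "p_plain"].to_numpy()

        failures = 0
        for seed in range(20):
            p = null_pvalues(150, seed)
            counts, _ = np.histogram(p, bins=20, range=(0, 1))
            if stats.chisquare(counts).pvalue < 0.01:
                failures += 1
        assert failures <= 1
        for seed in range(2):
            p = null_pvalues(1430, seed)
            assert len(p) >= 8000
            assert estimate_pi0(p).pi0 >= 0.9


class TestQValues:
    def test_hand_step_up_example(self):
        q = compute_qvalues(np.array([0.01, 0.02, 0.03, 0.04]), pi0=1.0)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_pi0_scaling(self):
        q = compute_qvalues(np.array([0.01, 0.02, 0.03, 0.04]), pi0=0.5)
        np.testing.assert_allclose(q, [0.02, 0.02, 0.02, 0.02])

    def test_equals_bh_when_pi0_is_one(self):
        p = np.random.default_rng(3).random(1000)
        q = compute_qvalues(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh, atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2,
                 max_size=60),
        st.floats(min_value=0.01, max_value=1.0),
    )
    def test_monotone_in_p_and_bounded(self, pvals, pi0):
        p = np.array(pvals)
        q = compute_qvalues(p, pi0)
        assert ((q >= 0) & (q <= 1)).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestDirectionEnrichment:
    def make_table(self, t_values, p_values):
        return pd.DataFrame({"t_mod": t_values, "p_mod": p_values})

    def test_all_positive_closed_form(self):
        table = self.make_table([1.0] * 10, [0.1] * 10)
        res = direction_enrichment(table, 0.2)
        assert res["p_binomial"] == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_balanced_is_null(self):
        table = self.make_table([1.0] * 5 + [-1.0] * 5, [0.1] * 10)
        res = direction_enrichment(table, 0.2)
        assert res["p_binomial"] == pytest.approx(1.0)

    def test_no_probesets_below_threshold_undefined(self):
        table = self.make_table([1.0, -1.0], [0.5, 0.9])
        res = direction_enrichment(table, 0.2)
        assert not res["defined"]
        assert np.isnan(res["p_binomial"])

    def test_zero_t_excluded_from_counts(self):
        table = self.make_table([1.0, 0.0, -1.0], [0.1, 0.1, 0.1])
        res = direction_enrichment(table, 0.2)
        assert res["n_pos"] + res["n_neg"] == 2

    def test_bins_partition_and_count_all(self):
        rng = np.random.default_rng(5)
        table = self.make_table(rng.normal(size=400), rng.random(400))
        bins = bin_direction(table)
        assert len(bins) == 20
        assert (bins["n_pos"] + bins["n_neg"] + bins["n_zero"]).sum() == 400
        np.testing.assert_allclose(bins["bin_right"] - bins["bin_left"],
                                   0.05)


class TestExpressionLevelContrast:
    def test_unaffected_control_ratio_is_one(self, default_dataset):
        bundle, _ = default_dataset
        filtered, _ = apply_detection_filters(bundle)
        incl = compute_inclusion(filtered)
        table, _ = run_tests(incl, bundle.design)
        out = expression_level_contrast(bundle, table)
        control = out.set_index("group").loc["Unaffected"]
        assert control["mean_ratio"] == pytest.approx(1.0)

    def test_planted_low_baseline_gives_ratio_below_one(self):
        # one affected probeset per gene: baseline 2 log2 units low, with a
        # +1 case shift (Up); 20 probesets per gene keep the metaprobeset
        # contamination of the null probesets' inclusion negligible
        rng = np.random.default_rng(12)
        genes, per_gene = 60, 20
        m = genes * per_gene
        meta_of = [f"g{i % genes}" for i in range(m)]
        values = rng.normal(8, 0.1, size=(m, 8))
        affected = np.arange(genes)  # first probeset of each gene
        values[affected] -= 2.0        # low baseline
        values[affected, 0::2] += 1.0  # higher inclusion in cases
        bundle = make_bundle(values, meta_of)
        filtered, _ = apply_detection_filters(bundle)
        incl = compute_inclusion(filtered)
        table, _ = run_tests(incl, bundle.design)
        out = expression_level_contrast(bundle, table, alpha=0.01)
        up = out.set_index("group").loc["Up"]
        assert up["n_metaprobesets"] > 20
        assert up["mean_ratio"] < 1.0

    def test_single_probeset_metaprobesets_skipped(self):
        rng = np.random.default_rng(13)
        values = rng.normal(8, 0.1, size=(3, 8))
        bundle = make_bundle(values, ["g1", "g2", "g3"])
        # force Up labels for all three probesets: their metaprobesets
        # have no unaffected sibling, so every gene is skipped
        table = pd.DataFrame(
            {"p_mod": [0.001] * 3, "t_mod": [3.0] * 3,
             "p_plain": [0.001] * 3, "t": [3.0] * 3},
            index=bundle.probesets.index)
        out = expression_level_contrast(bundle, table)
        up = out.set_index("group").loc["Up"]
        assert up["n_metaprobesets"] == 0
        assert up["n_skipped_no_unaffected"] == 3

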