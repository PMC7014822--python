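"""Synthetic study generator: determinism, analytic truth, fixtures."""

import numpy as np
import pandas as pd
import pytest

from tgxpod import apical, fixtures, synth


class TestApicalSimulation:
    def test_same_seed_is_byte_identical(self, study_design):
        curve = synth.TrueCurve("exponential", {"a": 3.0, "b": 1e-3}, noise_cv=0.2)
        df1, _ = synth.simulate_apical_series(study_design, curve)
        df2, _ = synth.simulate_apical_series(study_design, curve)
        pd.testing.assert_frame_equal(df1, df2)

    def test_flat_curve_has_no_bmd_and_flat_means(self, study_design):
        curve = synth.TrueCurve("flat", {"a": 5.0}, noise_cv=0.1)
        df, bmd = synth.simulate_apical_series(study_design, curve)
        assert np.isnan(bmd)
        gm = df.groupby("dose")["value"].mean()
        assert np.all(np.abs(gm / 5.0 - 1) < 0.2)

    def test_exponential_true_bmd_is_analytic(self):
        curve = synth.TrueCurve("exponential", {"a": 1.0, "b": np.log(1.1) / 100})
        assert curve.true_bmd(0.10) == pytest.approx(100.0, rel=1e-12)

    def test_hill_true_bmd_is_analytic(self):
        curve = synth.TrueCurve("hill", {"a": 1.0, "b": 900.0, "c": 2.0, "d": 1.0})
        # x/(900+x) = 0.1  ->  x = 100
        assert curve.true_bmd(0.10) == pytest.approx(100.0, rel=1e-12)

    def test_invalid_curves_rejected(self):
        with pytest.raises(ValueError):
            synth.TrueCurve("exponential", {"a": -1.0, "b": 1.0})
        with pytest.raises(ValueError):
            synth.TrueCurve("flat", {"a": 1.0}, noise_cv=-0.1)

    def test_noise_free_truth_recovered_by_apical_fit(self, study_design):
        """Analytic BMD of a generating curve matches the fitted BMD on
        noise-free data to well under 0.1% (truth-consistency invariant)."""
        curve = synth.TrueCurve(
            "exponential", {"a": 3.0, "b": 2e-3, "c": 3.0}, noise_cv=0.0)
        df, true_bmd = synth.simulate_apical_series(study_design, curve)
        fit = apical.fit_continuous(df[["series", "dose", "value"]],
                                    family="exponential", submodel="E4")
        res = apical._bmd_from_params(fit.submodel, fit.direction,
                                      fit.b[fit.prepared.series[0]],
                                      fit.c, fit.d, 0.10)
        assert res == pytest.approx(true_bmd, rel=1e-3)


class TestExpressionSimulation:
    def test_null_simulation_has_no_responsive_genes(self, study_design):
        matrix, truth = synth.simulate_expression_study(
            study_design, n_genes=150, responsive_fraction=0.0)
        assert truth["responsive"].sum() == 0
        deg = synth.make_deg_table(matrix)
        # per-dose mean log-ratios center on zero
        assert abs(deg.groupby("dose")["log2fc"].mean()).max() < 0.1

    def test_noise_free_single_gene_hits_its_fold_change(self):
        design = synth.StudyDesign(seed=5)
        law = synth.EffectLaw(fc_log2_min=1.0, fc_log2_max=1.0)
        disp = synth.DispersionSpec(sd_min=1e-6, sd_max=1e-6)
        matrix, truth = synth.simulate_expression_study(
            design, n_genes=1, responsive_fraction=1.0, effect_law=law,
            dispersion=disp, poisson_counts=False)
        deg = synth.make_deg_table(matrix)
        top = deg[deg["dose"] == 1500.0]["log2fc"].iloc[0]
        assert top == pytest.approx(truth["true_top_log2fc"].iloc[0], abs=1e-4)
        assert abs(abs(top) - 1.0) < 1e-3

    def test_truth_rows_match_matrix_rows(self, small_expression_study):
        matrix, truth = small_expression_study
        assert list(truth["gene"]) == matrix.genes
        assert (truth.loc[~truth["responsive"], "true_top_log2fc"] == 0).all()

    def test_bad_fractions_rejected(self, study_design):
        with pytest.raises(ValueError):
            synth.simulate_expression_study(study_design, 10, responsive_fraction=1.5)
        with pytest.raises(ValueError):
            synth.simulate_expression_study(study_design, 0)


class TestDegTableStandIn:
    def test_constant_gene_has_zero_fold_change(self):
        design = synth.StudyDesign(seed=1)
        x = design.sample_doses
        from tgxpod.genebmd import GeneDoseMatrix
        log2 = np.vstack([np.full(x.size, 8.0),
                          8.0 + 0.001 * np.arange(x.size)])
        matrix = GeneDoseMatrix(genes=["flat", "other"], doses=x, log2=log2)
        deg = synth.make_deg_table(matrix)
        assert (deg.loc[deg["gene"] == "flat", "log2fc"] == 0).all()

    def test_noise_free_fourfold_gene(self):
        design = synth.StudyDesign(seed=1)
        x = design.sample_doses
        from tgxpod.genebmd import GeneDoseMatrix
        row = np.where(x == 1500.0, 10.0, 8.0)
        jitter = np.random.default_rng(0).normal(0, 1e-9, x.size)
        matrix = GeneDoseMatrix(genes=["g4", "ref"], doses=x,
                                log2=np.vstack([row, 8.0 + jitter]))
        deg = synth.make_deg_table(matrix)
        top = deg[(deg["gene"] == "g4") & (deg["dose"] == 1500.0)]
        assert top["log2fc"].iloc[0] == pytest.approx(2.0, abs=1e-9)
        assert top["fc"].iloc[0] == pytest.approx(4.0, abs=1e-6)

    def test_false_discovery_proportion_controlled_under_null(self):
        """BH at q <= 0.05 keeps the realized false-discovery proportion
        near or below nominal over >= 100 null simulations."""
        fdp = []
        for seed in range(100):
            design = synth.StudyDesign(seed=seed)
            matrix, _ = synth.simulate_expression_study(
                design, n_genes=120, responsive_fraction=0.0,
                poisson_counts=False)
            deg = synth.make_deg_table(matrix)
            n_disc = int((deg["fdr"] <= 0.05).sum())
            fdp.append(1.0 if n_disc > 0 else 0.0)
        # every discovery is false under the null; the chance of any
        # discovery per dose-level family is <= 0.05, so across 5 doses
        # the per-study hit rate stays small
        assert np.mean(fdp) <= 0.25


class TestPaperFixtures:
    def test_ki67_printed_cells(self):
        t = fixtures.ki67_table()
        row = t[(t.series == "females_d29") & (t.dose == 1500)].iloc[0]
        assert (row["mean"], row["dispersion"], row["n"]) == (5.69, 0.95, 6)
        row = t[(t.series == "males_d29") & (t.dose == 1500)].iloc[0]
        assert (row["mean"], row["dispersion"]) == (10.31, 13.35)

    def test_alt_printed_cells(self):
        t = fixtures.clinical_chemistry_table("alt")
        row = t[(t.experiment == "B") & (t.series == "males_d29") & (t.dose == 0)].iloc[0]
        assert (row["mean"], row["dispersion"]) == (44.00, 2.41)

    def test_deg_count_printed_cells(self):
        t = fixtures.deg_count_table()
        sub = t[(t.series == "females_d29") & (t.direction == "up")]
        assert list(sub.sort_values("dose")["count"]) == [0, 52, 109, 352, 1202]

    def test_se_interpretation_scales_sd(self):
        sd = fixtures.ki67_table("sd")
        se = fixtures.ki67_table("se")
        assert np.allclose(se["sd"], sd["dispersion"] * np.sqrt(sd["n"]))

    def test_outlier_adjustment_matches_direct_computation(self, rng):
        x = rng.normal(10, 2, 6)
        n, m, s = len(x), x.mean(), x.std(ddof=1)
        n2, m2, s2 = fixtures.adjust_group_for_outlier(n, m, s, x[-1])
        assert n2 == 5
        assert m2 == pytest.approx(x[:-1].mean(), rel=1e-12)
        assert s2 == pytest.approx(x[:-1].std(ddof=1), rel=1e-9)

    def test_outlier_adjusted_series_entry(self):
        df = fixtures.ki67_covariate_series()
        row = df[(df.series == "males_d29") & (df.dose == 1500)].iloc[0]
        assert row["n"] == 5
        assert row["mean"] == pytest.approx((6 * 10.31 - 37.5) / 5, rel=1e-12)
        assert "females_d8" not in set(df["series"])
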