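"""Per-gene dose-response models, hierarchical selection, BMD, filters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tgxpod import genebmd
from tgxpod.genebmd import BMR_SD_UNITS, GeneDoseMatrix

DOSES = np.repeat([0.0, 300.0, 500.0, 750.0, 1000.0, 1500.0], 4)


class TestPrefilter:
    def _matrix(self, raw):
        raw = np.asarray(raw, float)
        genes = [f"g{i}" for i in range(raw.shape[0])]
        return GeneDoseMatrix(genes=genes, doses=DOSES,
                              log2=np.log2(raw + 1), raw=raw)

    def test_single_zero_excludes_gene(self, rng):
        raw = rng.poisson(50, (3, DOSES.size)) + 1.0
        raw[1, 7] = 0.0
        assert genebmd.prefilter_genes(self._matrix(raw)) == ["g0", "g2"]

    def test_all_positive_matrix_is_identity(self, rng):
        raw = rng.poisson(50, (4, DOSES.size)) + 1.0
        m = self._matrix(raw)
        assert genebmd.prefilter_genes(m) == m.genes

    def test_counted_exclusions_on_crafted_fixture(self, rng):
        raw = rng.poisson(30, (10, DOSES.size)) + 1.0
        for i in (2, 5, 9):
            raw[i, rng.integers(0, DOSES.size)] = 0.0
        assert len(genebmd.prefilter_genes(self._matrix(raw))) == 7

    def test_missing_raw_layer_is_an_error(self, rng):
        m = GeneDoseMatrix(genes=["g"], doses=DOSES,
                           log2=rng.normal(8, 1, (1, DOSES.size)))
        with pytest.raises(ValueError):
            genebmd.prefilter_genes(m)


class TestModelFits:
    def test_exactly_linear_data(self):
        y = 1.0 + 0.002 * DOSES
        fits = genebmd.fit_gene_models(y, DOSES)
        assert fits["linear"].sse == pytest.approx(0.0, abs=1e-18)
        assert fits["poly2"].aic >= fits["linear"].aic - 1e-6

    def test_noise_free_hill_recovery(self):
        y = 5.0 + 2.0 * DOSES / (750.0 + DOSES)
        fit = genebmd.fit_gene_models(y, DOSES)["hill"]
        assert fit.params["v"] == pytest.approx(2.0, rel=1e-3)
        assert fit.params["k"] == pytest.approx(750.0, rel=1e-2)
        assert fit.params["nH"] == pytest.approx(1.0, rel=1e-2)

    def test_constant_gene_flagged(self):
        fits = genebmd.fit_gene_models(np.full(DOSES.size, 3.0), DOSES)
        assert "constant" in fits["linear"].flags

    def test_nonfinite_values_rejected(self):
        y = np.full(DOSES.size, 1.0)
        y[0] = np.nan
        with pytest.raises(ValueError):
            genebmd.fit_gene_models(y, DOSES)

    def test_poly3_needs_five_doses(self):
        x4 = np.repeat([0.0, 300.0, 750.0, 1500.0], 4)
        fits = genebmd.fit_gene_models(np.ones(x4.size) + 0.001 * x4, x4)
        assert "poly3" not in fits

    def test_gof_p_uniform_under_true_model(self):
        """Goodness-of-fit p for the generating (linear) model is uniform
        over repeated noise realizations (KS check over 200 seeds)."""
        rng = np.random.default_rng(99)
        ps = []
        for _ in range(200):
            y = 1.0 + 0.001 * DOSES + rng.normal(0, 0.3, DOSES.size)
            ps.append(genebmd.fit_gene_models(y, DOSES, ("linear",))["linear"].fit_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestModelSelection:
    def test_linear_wins_on_linear_data(self, rng):
        y = 1.0 + 0.002 * DOSES + rng.normal(0, 0.05, DOSES.size)
        fits = genebmd.fit_gene_models(y, DOSES,
                                       ("linear", "poly2", "poly3"))
        best = genebmd.select_best_model(fits, 300.0)
        assert best.model == "linear"

    def test_hill_demoted_when_k_below_design_support(self):
        # k = 50 when the lowest positive dose is 300: flag + demote
        y = 5.0 + 2.0 * DOSES / (50.0 + DOSES)
        fits = genebmd.fit_gene_models(y, DOSES)
        best = genebmd.select_best_model(fits, 300.0)
        assert best.model != "hill"
        assert "hill_k_below_third_lowest_dose" in fits["hill"].flags

    def test_identical_aic_tie_broken_by_parameter_count(self):
        a = genebmd.GeneFit("poly2", {}, 1.0, 24, 3, -10.0, 28.0, 0.5)
        b = genebmd.GeneFit("linear", {}, 1.0, 24, 2, -10.0, 28.0, 0.5)
        best = genebmd.select_best_model({"linear": b, "poly2": a}, 300.0)
        assert best.model == "linear"


class TestGeneBmd:
    def test_linear_closed_form_to_machine_precision(self):
        fit = genebmd.fit_gene_models(1.0 + 0.002 * DOSES
                                      + np.random.default_rng(3).normal(0, 0.1, DOSES.size),
                                      DOSES, ("linear",))["linear"]
        bmd, sign, delta = genebmd.compute_gene_bmd(fit)
        assert bmd == BMR_SD_UNITS * fit.residual_sd / abs(fit.params["b1"])
        assert sign == 1

    def test_hill_algebraic_inversion(self):
        fit = genebmd.GeneFit("hill", {"b0": 0.0, "v": 2.0, "k": 750.0, "nH": 1.0},
                              0.0, 24, 4, 0.0, 0.0, 1.0)
        bmd, sign, delta = genebmd.compute_gene_bmd(fit, sigma=0.2)
        q = BMR_SD_UNITS * 0.2 / 2.0
        assert bmd == pytest.approx(750.0 * q / (1 - q), rel=1e-12)
        assert bmd == pytest.approx(116.95, abs=0.01)

    def test_bmd_vanishes_with_sigma(self):
        fit = genebmd.GeneFit("linear", {"b0": 1.0, "b1": 0.001},
                              0.0, 24, 2, 0.0, 0.0, 1.0)
        bmds = [genebmd.compute_gene_bmd(fit, sigma=s)[0]
                for s in (0.1, 0.01, 0.001)]
        assert bmds[0] > bmds[1] > bmds[2]
        assert bmds[2] < 2.0

    def test_curve_never_attaining_bmr_is_undefined(self):
        fit = genebmd.GeneFit("hill", {"b0": 0.0, "v": 0.1, "k": 750.0, "nH": 1.0},
                              0.0, 24, 4, 0.0, 0.0, 1.0)
        bmd, _, _ = genebmd.compute_gene_bmd(fit, sigma=1.0)
        assert np.isnan(bmd)

    def test_profile_bounds_bracket_the_estimate(self, rng):
        y = 1.0 + 0.0015 * DOSES + rng.normal(0, 0.25, DOSES.size)
        fit = genebmd.fit_gene_models(y, DOSES, ("linear",))["linear"]
        bmd, sign, delta = genebmd.compute_gene_bmd(fit)
        lo, hi, flags = genebmd.gene_bmd_bounds(fit, DOSES, y, bmd, delta, sign)
        assert lo <= bmd <= hi


class TestFilterCascade:
    def _records(self):
        mk = dict(model="linear", direction=1)
        return pd.DataFrame([
            # one record failing each rule, plus two clean survivors
            dict(gene="low_p", bmd=400, bmdl=200, bmdu=800, fit_p=0.05,
                 max_fc=2.0, **mk),
            dict(gene="wide", bmd=400, bmdl=10, bmdu=400, fit_p=0.5,
                 max_fc=2.0, **mk),                       # ratio == 40
            dict(gene="high_bmd", bmd=1600, bmdl=900, bmdu=2000, fit_p=0.5,
                 max_fc=2.0, **mk),
            dict(gene="small_fc", bmd=400, bmdl=200, bmdu=800, fit_p=0.5,
                 max_fc=1.4, **mk),
            dict(gene="ok1", bmd=400, bmdl=200, bmdu=800, fit_p=0.11,
                 max_fc=2.0, **mk),
            dict(gene="ok2", bmd=500, bmdl=300, bmdu=900, fit_p=0.8,
                 max_fc=1.5, **mk),
        ])

    def test_exactly_two_constructed_survivors(self):
        out = genebmd.apply_bmd_filters(self._records(), highest_dose=1500.0)
        assert set(out.loc[out["survives"], "gene"]) == {"ok1", "ok2"}

    def test_ratio_exactly_40_is_excluded(self):
        out = genebmd.apply_bmd_filters(self._records(), 1500.0)
        assert not out.loc[out["gene"] == "wide", "survives"].iloc[0]

    def test_boundary_record_survives(self):
        rec = pd.DataFrame([dict(gene="edge", model="linear", bmd=400,
                                 bmdl=300, bmdu=600, fit_p=0.11, max_fc=2.0,
                                 direction=1)])
        assert genebmd.apply_bmd_filters(rec, 1500.0)["survives"].iloc[0]

    def test_missing_fold_change_is_an_error(self):
        rec = self._records()
        rec.loc[0, "max_fc"] = np.nan
        with pytest.raises(ValueError):
            genebmd.apply_bmd_filters(rec, 1500.0)

    def test_cascade_is_a_pure_conjunction(self):
        out = genebmd.apply_bmd_filters(self._records(), 1500.0)
        rules = out[["pass_fit_p", "pass_ratio", "pass_range", "pass_fc"]]
        assert (out["survives"] == rules.all(axis=1)).all()


class TestEndToEndRecovery:
    def test_recovered_bmd_tracks_truth(self, small_expression_study,
                                        small_deg_table):
        """Responsive survivors' bmd_t rank-correlates with the generating
        BMD; non-responsive genes are overwhelmingly filtered out."""
        matrix, truth = small_expression_study
        from tgxpod.qc import _linear_fc
        deg = small_deg_table
        max_fc = _linear_fc(deg).abs().groupby(deg["gene"]).max()
        table = genebmd.gene_bmd_table(matrix, max_fc)
        surv = table[table["survives"]].set_index("gene")
        tr = truth.set_index("gene")
        resp = tr.loc[surv.index, "responsive"]
        assert resp.mean() > 0.9  # survivors are almost all truly responsive
        both = surv.join(tr[["true_bmd"]]).dropna(subset=["true_bmd"])
        rho = stats.spearmanr(both["bmd"], both["true_bmd"]).statistic
        assert rho >= 0.8
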