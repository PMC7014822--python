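"""Apical BMD modeling: fits, covariates, profile bounds, invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tgxpod import apical, synth


def _individual(series_specs, doses=(0, 100, 300, 1000), n=6, seed=0, cv=0.0):
    """Noise-free (or noisy) individual data from a*exp(b*x) per series."""
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))
    rows = []
    for label, (a, b) in series_specs.items():
        for x in doses:
            mu = a * np.exp(b * x)
            noise = np.exp(rng.normal(0, sigma, n)) if cv > 0 else np.ones(n)
            rows += [(label, float(x), mu * z) for z in noise]
    return pd.DataFrame(rows, columns=["series", "dose", "value"])


class TestFitting:
    def test_noise_free_exponential_selfconsistency(self):
        df = _individual({"s": (2.5, 0.002)})
        fit = apical.fit_continuous(df, family="exponential", submodel="E2")
        assert fit.a["s"] == pytest.approx(2.5, rel=1e-5)
        assert fit.b["s"] == pytest.approx(0.002, rel=1e-4)
        assert fit.sigma["s"] < 1e-5

    def test_background_covariate_improves_aic(self):
        df = _individual({"lo": (1.0, 0.002), "hi": (4.0, 0.002)},
                         seed=3, cv=0.05)
        with_cov = apical.fit_continuous(df, family="exponential",
                                         covariate_on=("a",), submodel="E2")
        without = apical.fit_continuous(df, family="exponential",
                                        covariate_on=(), submodel="E2")
        assert with_cov.a["lo"] != with_cov.a["hi"]
        assert len(set(with_cov.b.values())) == 1  # shared potency
        assert with_cov.aic < without.aic

    def test_summary_fit_matches_individual_fit(self):
        df = _individual({"s": (2.0, 0.0015)}, n=8, seed=5, cv=0.2)
        summary = (df.groupby(["series", "dose"])["value"]
                   .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
                   .reset_index())
        fi = apical.fit_continuous(df, family="exponential", submodel="E2")
        fs = apical.fit_continuous(summary, family="exponential", submodel="E2")
        assert fs.a["s"] == pytest.approx(fi.a["s"], rel=5e-3)
        assert fs.b["s"] == pytest.approx(fi.b["s"], rel=5e-3)

    def test_constant_response_rejected(self):
        df = pd.DataFrame({"series": "s", "dose": [0, 0, 100, 100, 300, 300],
                           "value": 2.0})
        with pytest.raises(ValueError):
            apical.fit_continuous(df)

    def test_summary_without_sd_rejected(self):
        df = pd.DataFrame({"series": "s", "dose": [0, 100, 300],
                           "n": 6, "mean": [2.0, 2.5, 3.0], "sd": np.nan})
        with pytest.raises(ValueError):
            apical.prepare_series(df)


class TestBmdInversion:
    def test_exponential_closed_form(self):
        # y = a*exp(bx), b = ln(1.1)/100  ->  BMD(10%) = 100 exactly
        b = np.log(1.1) / 100
        bmd = apical._bmd_from_params("E2", 1, b, None, 1.0, 0.10)
        assert bmd == pytest.approx(100.0, rel=1e-12)

    def test_hill_closed_form(self):
        # a=1, c=2, d=1, b=900: x/(900+x) = 0.1 -> x = 100
        bmd = apical._bmd_from_params("H4", 1, 900.0, 2.0, 1.0, 0.10)
        assert bmd == pytest.approx(100.0, rel=1e-12)

    def test_bmr_monotonicity(self):
        for bmr_lo, bmr_hi in [(0.05, 0.10), (0.10, 0.20)]:
            lo = apical._bmd_from_params("E4", 1, 0.002, 2.0, 1.0, bmr_lo)
            hi = apical._bmd_from_params("E4", 1, 0.002, 2.0, 1.0, bmr_hi)
            assert lo < hi

    def test_unattained_bmr_flagged(self):
        df = _individual({"s": (1.0, 0.00005)}, seed=2, cv=0.02)
        fit = apical.fit_continuous(df, family="hill", submodel="H4")
        if fit.c is not None and abs(fit.c - 1) <= 0.10:
            res = apical.compute_bmd(fit)
            assert "bmr_not_attained" in res.flags


class TestProfileBounds:
    @pytest.fixture(scope="class")
    def noisy_fit(self):
        df = _individual({"s": (2.0, 0.002)}, doses=(0, 100, 300, 1000),
                         n=5, seed=9, cv=0.25)
        fit = apical.fit_continuous(df, family="exponential", submodel="E2")
        return df, fit

    def test_bound_ordering(self, noisy_fit):
        _, fit = noisy_fit
        res = apical.compute_bmd(fit)
        assert res.bmdl <= res.bmd <= res.bmdu

    def test_profile_matches_grid_search_oracle(self, noisy_fit):
        """Profile BMDL/BMDU agree within 1% with a brute-force scan of the
        (a, b) box: the extreme BMD = ln(1.1)/b over parameters whose
        deviance stays inside the chi-square threshold."""
        df, fit = noisy_fit
        res = apical.compute_bmd(fit)
        prep = fit.prepared
        thresh = stats.chi2.ppf(0.90, 1)

        def nll(la, lb):
            mu = la + prep.dose * np.exp(lb)
            return apical._nll_from_mu(prep, mu, False)

        nll0 = -fit.loglik
        s = prep.series[0]
        la_grid = np.log(fit.a[s]) + np.linspace(-0.15, 0.15, 160)
        lb_grid = np.log(fit.b[s]) + np.linspace(-1.2, 1.2, 500)
        bmds = []
        for la in la_grid:
            for lb in lb_grid:
                if 2 * (nll(la, lb) - nll0) <= thresh:
                    bmds.append(np.log(1.1) / np.exp(lb))
        assert res.bmdl == pytest.approx(min(bmds), rel=0.01)
        assert res.bmdu == pytest.approx(max(bmds), rel=0.01)

    def test_dose_scale_equivariance(self):
        base = _individual({"s": (2.0, 0.002)}, n=5, seed=13, cv=0.2)
        scaled = base.assign(dose=base["dose"] * 3.0)
        r1 = apical.compute_bmd(apical.fit_continuous(base, submodel="E2"))
        r2 = apical.compute_bmd(apical.fit_continuous(scaled, submodel="E2"))
        assert r2.bmd == pytest.approx(3 * r1.bmd, rel=1e-3)
        assert r2.bmdl == pytest.approx(3 * r1.bmdl, rel=5e-3)
        assert r2.bmdu == pytest.approx(3 * r1.bmdu, rel=5e-3)


class TestPodSelection:
    def test_min_max_combination(self):
        r1 = apical.BmdResult("exponential", "E4", "relative_change", 0.1,
                              300.0, 200.0, 450.0)
        r2 = apical.BmdResult("hill", "H4", "relative_change", 0.1,
                              350.0, 250.0, 500.0)
        pod = apical.select_pod([r1, r2])
        assert pod.bmdl == 200.0 and pod.bmdu == 500.0
        assert pod.ratio == pytest.approx(2.5)

    def test_single_family_passes_through(self):
        r = apical.BmdResult("hill", "H4", "relative_change", 0.1,
                             300.0, 200.0, 450.0)
        pod = apical.select_pod([r])
        assert (pod.bmdl, pod.bmdu) == (200.0, 450.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            apical.select_pod([])


class TestRecovery:
    def test_bmd_recovery_and_bmdl_coverage(self):
        """Across >= 50 simulated studies at the study-like design (6 doses,
        n = 6, CV 25%), the median recovered BMD is within 20% of truth and
        the one-sided BMDL covers truth at about its nominal 95% rate."""
        curve = synth.TrueCurve("exponential",
                                {"a": 3.0, "b": 2.5e-3, "c": 2.5}, noise_cv=0.25)
        true_bmd = curve.true_bmd(0.10)
        recovered, covered = [], 0
        n_sims = 50
        for seed in range(n_sims):
            design = synth.StudyDesign(seed=seed)
            df, _ = synth.simulate_apical_series(design, curve)
            fit = apical.fit_continuous(df[["series", "dose", "value"]],
                                        family="exponential", submodel="E4")
            res = apical.compute_bmd(fit)
            recovered.append(res.bmd)
            covered += res.bmdl <= true_bmd
        assert np.median(recovered) == pytest.approx(true_bmd, rel=0.20)
        # nominal 95% one-sided coverage; binomial(50, .95) >= 43 w.p. ~.99
        assert covered >= 43
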