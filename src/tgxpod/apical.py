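"""Continuous-endpoint benchmark-dose modeling with covariates.

Implements the exponential and Hill model families in the EFSA/PROAST
parameterization for a positive continuous endpoint assumed lognormal:

    exponential:  y(x) = a * [c - (c - 1) * exp(-b * x**d)]
    Hill:         y(x) = a * [1 + (c - 1) * x**d / (b**d + x**d)]

with the reduced forms nested inside each family (see ``SUBMODELS``), a
categorical covariate ("study": sex x time-point) on the background ``a``
and optionally on the potency ``b`` and the residual variance, and the
benchmark dose defined by a relative change in the median response:

    |y(BMD) / y(0)| - 1 = CES            (CES = BMR, default 10%)

Fitting maximizes the normal likelihood of log responses with constant
log-scale variance per covariate level; group summaries (n, mean, SD on the
natural scale) are converted to log-scale sufficient statistics via the
lognormal moment relations, so individual-animal and summary layouts share
one likelihood.  BMDL/BMDU are profile-likelihood bounds at the chi-square
threshold for a two-sided 90% interval (one-sided 95% per bound), obtained
by re-expressing ``b`` as a function of the BMD and profiling the remaining
parameters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PreparedSeries",
    "ContinuousFit",
    "BmdResult",
    "PodSummary",
    "prepare_series",
    "fit_continuous",
    "fit_family_best",
    "compute_bmd",
    "select_pod",
    "apical_pod",
]

# Sub-model registry: (family, has_c, has_d).  Names follow the PROAST
# numbering: model 2 = a*exp(b x), 3 adds shape d, 4 adds fold-range c,
# 5 is the full four-parameter form; Hill 4/5 are the analogous forms.
SUBMODELS: dict[str, tuple[str, bool, bool]] = {
    "E2": ("exponential", False, False),
    "E3": ("exponential", False, True),
    "E4": ("exponential", True, False),
    "E5": ("exponential", True, True),
    "H4": ("hill", True, False),
    "H5": ("hill", True, True),
}

FAMILY_SUBMODELS = {
    "exponential": ("E2", "E3", "E4", "E5"),
    "hill": ("H4", "H5"),
}

_LOG_D_MAX = np.log(8.0)  # shape parameter bounded in [1, 8]
_SIGMA2_FLOOR = 1e-12


@dataclass
class PreparedSeries:
    """Log-scale sufficient statistics of a dose-response series set."""

    series: list[str]            # covariate level labels
    series_idx: np.ndarray       # group -> series index
    dose: np.ndarray             # group dose
    n: np.ndarray                # group size
    logmean: np.ndarray          # mean of log responses per group
    log_ss: np.ndarray           # within-group sum of squares of log responses

    @property
    def max_dose(self) -> float:
        return float(self.dose.max())

    @property
    def n_total(self) -> int:
        return int(self.n.sum())


def prepare_series(data: pd.DataFrame) -> PreparedSeries:
    """Reduce an apical table to per-group log-scale sufficient statistics.

    Accepts the individual layout (columns series, dose, value) or the
    summary layout (series, dose, n, mean, sd).  Natural-scale summaries
    are mapped to log scale with the lognormal relations
    ``logvar = log(1 + cv^2)``, ``logmean = log(mean) - logvar/2``.
    """
    cols = set(data.columns)
    if {"series", "dose", "value"} <= cols:
        if (data["value"] <= 0).any():
            raise ValueError("responses must be > 0 (lognormal support)")
        rows = []
        for (s, x), grp in data.groupby(["series", "dose"], sort=True):
            lv = np.log(grp["value"].to_numpy(dtype=float))
            rows.append((s, float(x), lv.size, lv.mean(), ((lv - lv.mean()) ** 2).sum()))
    elif {"series", "dose", "n", "mean", "sd"} <= cols:
        if (data["mean"] <= 0).any():
            raise ValueError("group means must be > 0 (lognormal support)")
        if (data["sd"] <= 0).any() or data["sd"].isna().any():
            raise ValueError("summary layout requires positive sd for every group")
        if data["n"].isna().any():
            raise ValueError("summary layout requires n for every group")
        rows = []
        for r in data.itertuples():
            cv2 = (r.sd / r.mean) ** 2
            logvar = np.log1p(cv2)
            m = np.log(r.mean) - logvar / 2
            rows.append((r.series, float(r.dose), int(r.n), m, (int(r.n) - 1) * logvar))
    else:
        raise ValueError(
            "need columns (series, dose, value) or (series, dose, n, mean, sd)"
        )
    df = pd.DataFrame(rows, columns=["series", "dose", "n", "logmean", "log_ss"])
    labels = sorted(df["series"].unique())
    for s in labels:
        sub = df[df["series"] == s]
        if 0.0 not in sub["dose"].to_numpy():
            raise ValueError(f"series {s!r} has no dose-0 control group")
        if sub["dose"].nunique() < 3:
            raise ValueError(f"series {s!r} has fewer than 3 distinct doses")
    return PreparedSeries(
        series=labels,
        series_idx=df["series"].map({s: i for i, s in enumerate(labels)}).to_numpy(),
        dose=df["dose"].to_numpy(dtype=float),
        n=df["n"].to_numpy(dtype=float),
        logmean=df["logmean"].to_numpy(dtype=float),
        log_ss=df["log_ss"].to_numpy(dtype=float),
    )


@dataclass
class ContinuousFit:
    family: str
    submodel: str
    direction: int                      # +1 increasing, -1 decreasing
    a: dict[str, float]
    b: dict[str, float]                 # per covariate level (shared -> equal)
    c: float | None
    d: float
    sigma: dict[str, float]             # residual log-scale SD per level
    loglik: float
    aic: float
    n_params: int
    covariate_on: frozenset
    prepared: PreparedSeries = field(repr=False)
    converged: bool = True

    def mean(self, x, series: str | None = None):
        """Fitted median response on the natural scale."""
        s = series if series is not None else self.prepared.series[0]
        a = self.a[s]
        b = self.b[s]
        g = _shape(self.submodel, self.direction, np.asarray(x, dtype=float), b, self.c, self.d)
        return a * g


def _shape(submodel: str, direction: int, x, b: float, c: float | None, d: float):
    """y/a for a sub-model; uniform in direction via gamma = |c - 1|."""
    family, has_c, _ = SUBMODELS[submodel]
    xd = np.power(x, d)
    if family == "exponential" and not has_c:
        return np.exp(np.clip(direction * b * xd, -700.0, 700.0))
    if family == "exponential":
        gamma = abs(c - 1.0)
        return 1.0 + direction * gamma * (1.0 - np.exp(-b * xd))
    gamma = abs(c - 1.0)
    return 1.0 + direction * gamma * xd / (b**d + xd)


def _nll_from_mu(prep: PreparedSeries, mu: np.ndarray, var_by_series: bool) -> float:
    """Profile the residual variance(s) analytically and return -loglik."""
    resid = prep.log_ss + prep.n * (prep.logmean - mu) ** 2
    if var_by_series:
        nll = 0.0
        for i in range(len(prep.series)):
            m = prep.series_idx == i
            n_s = prep.n[m].sum()
            s2 = max(resid[m].sum() / n_s, _SIGMA2_FLOOR)
            nll += 0.5 * n_s * (np.log(2 * np.pi * s2) + 1.0)
        return nll
    n_t = prep.n.sum()
    s2 = max(resid.sum() / n_t, _SIGMA2_FLOOR)
    return 0.5 * n_t * (np.log(2 * np.pi * s2) + 1.0)


def _sigma_hat(prep: PreparedSeries, mu: np.ndarray, var_by_series: bool) -> dict[str, float]:
    resid = prep.log_ss + prep.n * (prep.logmean - mu) ** 2
    out = {}
    if var_by_series:
        for i, s in enumerate(prep.series):
            m = prep.series_idx == i
            out[s] = float(np.sqrt(max(resid[m].sum() / prep.n[m].sum(), _SIGMA2_FLOOR)))
    else:
        s2 = max(resid.sum() / prep.n.sum(), _SIGMA2_FLOOR)
        out = {s: float(np.sqrt(s2)) for s in prep.series}
    return out


class _Model:
    """Unconstrained-parameter wrapper around one sub-model.

    Free vector layout: [log a per series] + [log b per b-level] +
    [t_c if has_c] + [t_d if has_d], with c = 1 + direction*exp(t_c)
    (bounded so c stays positive on the decreasing side) and
    d = 1 + (exp(t_d) clipped to [1, 8] via bounds).
    """

    def __init__(self, submodel: str, prep: PreparedSeries, direction: int,
                 covariate_on: frozenset):
        self.submodel = submodel
        self.family, self.has_c, self.has_d = SUBMODELS[submodel]
        self.prep = prep
        self.direction = direction
        self.cov = covariate_on
        self.n_series = len(prep.series)
        self.n_b = self.n_series if "b" in covariate_on else 1
        self.var_by_series = "var" in covariate_on and self.n_series > 1
        self.n_a = self.n_series if "a" in covariate_on else 1

    # ---- packing -------------------------------------------------------
    def unpack(self, theta: np.ndarray):
        i = 0
        la = theta[i:i + self.n_a]; i += self.n_a
        lb = theta[i:i + self.n_b]; i += self.n_b
        c = None
        if self.has_c:
            gamma = np.exp(theta[i]); i += 1
            c = 1.0 + self.direction * gamma
        d = np.exp(theta[i]) if self.has_d else 1.0
        return la, lb, c, d

    def bounds(self):
        bb = [(-30.0, 30.0)] * self.n_a + [(-30.0, 30.0)] * self.n_b
        if self.has_c:
            # keep c > 0 when decreasing
            hi = np.log(0.999) if self.direction < 0 else 20.0
            bb.append((-10.0, hi))
        if self.has_d:
            bb.append((0.0, _LOG_D_MAX))
        return bb

    @property
    def n_free_mean(self) -> int:
        return self.n_a + self.n_b + int(self.has_c) + int(self.has_d)

    @property
    def n_params(self) -> int:
        n_var = self.n_series if self.var_by_series else 1
        return self.n_free_mean + n_var

    # ---- likelihood ----------------------------------------------------
    def mu(self, la, lb, c, d) -> np.ndarray:
        a_g = la[self.prep.series_idx] if self.n_a > 1 else np.full(len(self.prep.dose), la[0])
        b_g = np.exp(lb[self.prep.series_idx] if self.n_b > 1 else np.full(len(self.prep.dose), lb[0]))
        g = np.empty_like(self.prep.dose)
        for bval in np.unique(b_g):
            m = b_g == bval
            g[m] = _shape(self.submodel, self.direction, self.prep.dose[m], bval, c, d)
        return a_g + np.log(g)

    def nll(self, theta: np.ndarray) -> float:
        la, lb, c, d = self.unpack(theta)
        mu = self.mu(la, lb, c, d)
        if not np.all(np.isfinite(mu)):
            return 1e10
        return _nll_from_mu(self.prep, mu, self.var_by_series)

    # ---- starting values ----------------------------------------------
    def starts(self) -> list[np.ndarray]:
        prep = self.prep
        a0 = []
        for i in range(self.n_series):
            m = (prep.series_idx == i) & (prep.dose == 0)
            a0.append(float(np.average(prep.logmean[m], weights=prep.n[m])))
        if self.n_a == 1:
            a0 = [float(np.mean(a0))]
        xmax = prep.max_dose
        if self.family == "hill":
            b_grid = xmax * np.array([0.05, 0.2, 0.5, 1.0, 3.0])
        elif self.has_c:
            b_grid = np.array([0.3, 1.0, 3.0, 10.0]) / xmax
        else:
            # a*exp(b x): b ~ log(fold)/xmax
            b_grid = np.array([0.03, 0.1, 0.3, 1.0]) / xmax
        out = []
        c_grid = [np.log(0.5)] if self.has_c else [None]
        if self.has_c and self.direction > 0:
            c_grid = [np.log(0.5), np.log(2.0)]
        for b0, tc in itertools.product(b_grid, c_grid):
            th = list(a0) + [np.log(b0)] * self.n_b
            if self.has_c:
                th.append(tc)
            if self.has_d:
                th.append(np.log(1.5))
            out.append(np.array(th))
        return out


def _minimize(fun, x0, bounds):
    res = optimize.minimize(fun, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10})
    return res


def _infer_direction(prep: PreparedSeries) -> int:
    """Sign of the pooled top-vs-control log response change."""
    delta = 0.0
    for i in range(len(prep.series)):
        m = prep.series_idx == i
        d = prep.dose[m]
        lm = prep.logmean[m]
        delta += lm[np.argmax(d)] - lm[np.argmin(d)]
    return 1 if delta >= 0 else -1


def fit_continuous(
    data: pd.DataFrame | PreparedSeries,
    family: str = "exponential",
    covariate_on: frozenset | set | tuple = ("a", "var"),
    submodel: str | None = None,
    direction: int | None = None,
) -> ContinuousFit:
    """Maximum-likelihood fit of one sub-model (or the AIC-best of a family).

    With ``submodel=None`` every nested form of ``family`` is fit and the
    lowest-AIC one returned (ties: fewer parameters, then smaller b).
    """
    prep = data if isinstance(data, PreparedSeries) else prepare_series(data)
    if np.allclose(prep.logmean, prep.logmean[0]) and np.allclose(prep.log_ss, 0):
        raise ValueError("all-constant response: potency is not estimable")
    cov = frozenset(covariate_on) if len(prep.series) > 1 else frozenset()
    if direction is None:
        direction = _infer_direction(prep)
    names = [submodel] if submodel else list(FAMILY_SUBMODELS[family])
    fits = []
    for name in names:
        model = _Model(name, prep, direction, cov)
        best = None
        for x0 in model.starts():
            res = _minimize(model.nll, x0, model.bounds())
            if best is None or res.fun < best.fun - 1e-9:
                best = res
        la, lb, c, d = model.unpack(best.x)
        mu = model.mu(la, lb, c, d)
        sigma = _sigma_hat(prep, mu, model.var_by_series)
        ll = -best.fun
        k = model.n_params
        a_map = {s: float(np.exp(la[i] if model.n_a > 1 else la[0]))
                 for i, s in enumerate(prep.series)}
        b_map = {s: float(np.exp(lb[i] if model.n_b > 1 else lb[0]))
                 for i, s in enumerate(prep.series)}
        fits.append(ContinuousFit(
            family=family, submodel=name, direction=direction,
            a=a_map, b=b_map, c=(float(c) if c is not None else None),
            d=float(d), sigma=sigma, loglik=float(ll), aic=float(2 * k - 2 * ll),
            n_params=k, covariate_on=cov, prepared=prep,
            converged=bool(best.success or best.fun < 1e9),
        ))
    fits.sort(key=lambda f: (round(f.aic, 6), f.n_params, min(f.b.values())))
    return fits[0]


def fit_family_best(data, family, covariate_on=("a", "var")) -> ContinuousFit:
    return fit_continuous(data, family=family, covariate_on=covariate_on)


# --------------------------------------------------------------------------
# BMD and profile-likelihood bounds
# --------------------------------------------------------------------------

@dataclass
class BmdResult:
    family: str
    submodel: str
    bmr_type: str
    bmr_value: float
    bmd: float
    bmdl: float
    bmdu: float
    confidence: float = 0.90
    flags: list[str] = field(default_factory=list)
    series: str | None = None  # set when the potency carries the covariate

    def __post_init__(self):
        if np.isfinite(self.bmd) and not (self.bmdl <= self.bmd * (1 + 1e-9) and
                                          self.bmd <= self.bmdu * (1 + 1e-9)):
            self.flags.append("bound_ordering")


def _bmd_from_params(submodel: str, direction: int, b: float, c: float | None,
                     d: float, bmr: float) -> float:
    """Dose at which |y/y(0) - 1| = bmr, or nan when the curve never gets there."""
    family, has_c, _ = SUBMODELS[submodel]
    if family == "exponential" and not has_c:
        tau = abs(np.log1p(direction * bmr))
        return (tau / b) ** (1.0 / d)
    gamma = abs(c - 1.0)
    if gamma <= bmr:
        return np.nan
    q = bmr / gamma
    if family == "exponential":
        return (-np.log1p(-q) / b) ** (1.0 / d)
    return b * (q / (1.0 - q)) ** (1.0 / d)


def _b_from_bmd(submodel: str, direction: int, bmd: float, c: float | None,
                d: float, bmr: float) -> float:
    """Inverse of :func:`_bmd_from_params` in b, used for profiling."""
    family, has_c, _ = SUBMODELS[submodel]
    if family == "exponential" and not has_c:
        tau = abs(np.log1p(direction * bmr))
        return tau / bmd**d
    gamma = abs(c - 1.0)
    if gamma <= bmr:
        return np.nan
    q = bmr / gamma
    if family == "exponential":
        return -np.log1p(-q) / bmd**d
    return bmd * ((1.0 - q) / q) ** (1.0 / d)


class _ProfileModel:
    """Sub-model with b of one covariate level tied to a candidate BMD."""

    def __init__(self, model: _Model, bmr: float, level: int = 0):
        self.m = model
        self.bmr = bmr
        self.level = level  # which b entry is substituted

    def split(self, theta):
        # theta excludes the profiled lb entry
        m = self.m
        i = 0
        la = theta[i:i + m.n_a]; i += m.n_a
        lb_other = theta[i:i + m.n_b - 1]; i += m.n_b - 1
        c = None
        if m.has_c:
            gamma = np.exp(theta[i]); i += 1
            c = 1.0 + m.direction * gamma
        d = np.exp(theta[i]) if m.has_d else 1.0
        return la, lb_other, c, d

    def nll(self, theta, bmd):
        m = self.m
        la, lb_other, c, d = self.split(theta)
        if m.has_c and abs(c - 1.0) <= self.bmr * (1 + 1e-9):
            return 1e10
        b = _b_from_bmd(m.submodel, m.direction, bmd, c, d, self.bmr)
        if not np.isfinite(b) or b <= 0:
            return 1e10
        lb = np.insert(lb_other, self.level, np.log(b))
        mu = m.mu(la, lb, c, d)
        if not np.all(np.isfinite(mu)):
            return 1e10
        return _nll_from_mu(m.prep, mu, m.var_by_series)

    def bounds(self):
        m = self.m
        bb = [(-30.0, 30.0)] * m.n_a + [(-30.0, 30.0)] * (m.n_b - 1)
        if m.has_c:
            lo = np.log(self.bmr * (1 + 1e-6))
            hi = np.log(0.999) if m.direction < 0 else 20.0
            bb.append((lo, hi))
        if m.has_d:
            bb.append((0.0, _LOG_D_MAX))
        return bb


def _profile_bounds(fit: ContinuousFit, bmr: float, confidence: float,
                    level_label: str) -> tuple[float, float, list[str]]:
    prep = fit.prepared
    model = _Model(fit.submodel, prep, fit.direction, fit.covariate_on)
    level = prep.series.index(level_label) if model.n_b > 1 else 0
    prof = _ProfileModel(model, bmr, level)
    bounds = prof.bounds()
    thresh = stats.chi2.ppf(confidence, 1)

    # theta at the MLE, with the profiled lb removed
    la0 = np.log([fit.a[s] for s in (prep.series if model.n_a > 1 else prep.series[:1])])
    lb_all = np.log([fit.b[s] for s in (prep.series if model.n_b > 1 else prep.series[:1])])
    theta0 = list(la0) + list(np.delete(lb_all, level))
    if model.has_c:
        theta0.append(np.log(max(abs(fit.c - 1.0), bmr * (1 + 1e-5))))
    if model.has_d:
        theta0.append(np.log(np.clip(fit.d, 1.0, 8.0)))
    theta0 = np.array(theta0)

    cache = {"theta": theta0.copy()}

    def deviance(bmd: float) -> float:
        best = None
        for x0 in (cache["theta"], theta0):
            res = _minimize(lambda th: prof.nll(th, bmd), x0, bounds)
            if best is None or res.fun < best.fun:
                best = res
        cache["theta"] = best.x
        return 2.0 * (best.fun + fit.loglik)  # 2*(nll_prof - nll_min)

    bmd_hat = _bmd_from_params(fit.submodel, fit.direction, fit.b[level_label],
                               fit.c, fit.d, bmr)
    flags: list[str] = []
    dev_hat = deviance(bmd_hat)
    offset = max(dev_hat, 0.0)  # numeric slack at the MLE

    def search(side: int) -> float:
        # side -1: lower bound; +1: upper bound
        cache["theta"] = theta0.copy()
        factor = 0.7 if side < 0 else 1.0 / 0.7
        limit = bmd_hat * 1e-4 if side < 0 else prep.max_dose * 100.0
        prev = bmd_hat
        cur = bmd_hat * factor
        while True:
            dev = deviance(cur)
            if dev - offset > thresh:
                break
            prev = cur
            cur *= factor
            if (side < 0 and cur < limit) or (side > 0 and cur > limit):
                flags.append("unbounded_lower" if side < 0 else "unbounded_upper")
                return 0.0 if side < 0 else np.inf
        lo, hi = (cur, prev) if side < 0 else (prev, cur)
        root = optimize.brentq(lambda x: deviance(x) - offset - thresh, lo, hi,
                               xtol=max(bmd_hat * 1e-6, 1e-10), rtol=1e-8)
        return float(root)

    bmdl = search(-1)
    bmdu = search(+1)
    return bmdl, bmdu, flags


def compute_bmd(fit: ContinuousFit, bmr: float = 0.10,
                confidence: float = 0.90, series: str | None = None) -> "BmdResult":
    """Benchmark dose and profile-likelihood BMDL/BMDU for a fitted model.

    When the potency ``b`` carries the covariate the BMD differs per level
    and ``series`` selects which level to invert; otherwise the single
    shared BMD is returned.
    """
    if not fit.converged:
        raise ValueError("cannot compute a BMD from a non-converged fit")
    level = series or fit.prepared.series[0]
    bmd = _bmd_from_params(fit.submodel, fit.direction, fit.b[level],
                           fit.c, fit.d, bmr)
    flags: list[str] = []
    if not np.isfinite(bmd):
        return BmdResult(fit.family, fit.submodel, "relative_change", bmr,
                         np.nan, np.nan, np.nan, confidence,
                         ["bmr_not_attained"])
    if bmd > fit.prepared.max_dose:
        flags.append("bmd_above_max_dose")
    bmdl, bmdu, pflags = _profile_bounds(fit, bmr, confidence, level)
    res = BmdResult(fit.family, fit.submodel, "relative_change", bmr,
                    float(bmd), float(bmdl), float(bmdu), confidence,
                    flags + pflags)
    res.series = level if "b" in fit.covariate_on else None
    return res


@dataclass
class PodSummary:
    bmdl: float
    bmdu: float
    ratio: float
    per_family: dict[str, BmdResult]
    results: list[BmdResult] = field(default_factory=list)

    @property
    def interval(self) -> tuple[float, float]:
        return (self.bmdl, self.bmdu)


def select_pod(results: list[BmdResult]) -> PodSummary:
    """Combine family results: reported BMDL = min, BMDU = max over families."""
    usable = [r for r in results if np.isfinite(r.bmd)]
    if not usable:
        raise ValueError("no converged family result")
    bmdl = min(r.bmdl for r in usable)
    bmdu = max(r.bmdu for r in usable)
    return PodSummary(bmdl=float(bmdl), bmdu=float(bmdu),
                      ratio=float(bmdu / bmdl) if bmdl > 0 else np.inf,
                      per_family={r.family: r for r in usable},
                      results=usable)


def family_bmds(prep: PreparedSeries, family: str, bmr: float = 0.10,
                covariate_on=("a", "var"), potency_aic_gate: float = 2.0,
                confidence: float = 0.90) -> list[BmdResult]:
    """AIC-best fit of one family with covariate-structure selection.

    The covariate always sits on the background (and residual variance by
    default); it is additionally placed on the potency ``b`` when doing so
    improves AIC by more than ``potency_aic_gate``.  With a per-level
    potency the benchmark dose differs per covariate level, so one
    :class:`BmdResult` per level is returned; otherwise a single result.
    """
    base = fit_continuous(prep, family=family, covariate_on=covariate_on)
    fit = base
    if len(prep.series) > 1 and "b" not in covariate_on:
        withb = fit_continuous(prep, family=family,
                               covariate_on=frozenset(covariate_on) | {"b"})
        if withb.aic < base.aic - potency_aic_gate:
            fit = withb
    if "b" in fit.covariate_on:
        return [compute_bmd(fit, bmr=bmr, confidence=confidence, series=s)
                for s in prep.series]
    return [compute_bmd(fit, bmr=bmr, confidence=confidence)]


def apical_pod(data, bmr: float = 0.10, covariate_on=("a", "var"),
               families=("exponential", "hill"),
               potency_aic_gate: float = 2.0) -> PodSummary:
    """End-to-end apical POD.

    Per family: AIC-selected sub-model and covariate structure, benchmark
    dose(s) with profile bounds.  Reported BMDL/BMDU are the minimum and
    maximum over families (and covariate levels when the potency carries
    the covariate).
    """
    prep = data if isinstance(data, PreparedSeries) else prepare_series(data)
    results = []
    for fam in families:
        results.extend(family_bmds(prep, fam, bmr=bmr, covariate_on=covariate_on,
                                   potency_aic_gate=potency_aic_gate))
    return select_pod(results)
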