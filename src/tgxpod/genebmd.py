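"""Per-gene dose-response modeling and transcriptomic benchmark doses.

Each gene's (log2) expression is fit against dose with a battery of
least-squares models — linear, quadratic and cubic polynomials, power,
Hill and two-parameter exponential — under normal errors with constant
variance.  The best model is chosen hierarchically: within the nested
linear/polynomial chain the simplest model not rejected by a likelihood-
ratio test (alpha = 0.05) is retained, the chain winner then competes
with the power, Hill and exponential forms on AIC, and a Hill fit whose
half-maximal dose falls below one third of the lowest positive dose is
demoted as unsupported by the design.

The transcriptomic benchmark dose bmd_t solves |y(x) - y(0)| = 1.349 * sigma
where sigma is the model residual SD (1.349 SD corresponds to a 10% change
for a typical control coefficient of variation); BMDL_t/BMDU_t are
profile-likelihood bounds (95% one-sided each).  A four-rule conjunction
then removes unreliable fits: goodness-of-fit p <= 0.1, BMDU/BMDL >= 40,
BMD above the highest tested dose, or maximum observed |fold change| < 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GeneDoseMatrix",
    "GeneFit",
    "GeneBmdRecord",
    "BMR_SD_UNITS",
    "prefilter_genes",
    "fit_gene_models",
    "select_best_model",
    "compute_gene_bmd",
    "gene_bmd_bounds",
    "apply_bmd_filters",
    "gene_bmd_table",
]

#: Benchmark response in residual-SD units (equivalent to a 10% change
#: relative to control expression at a typical control CV).
BMR_SD_UNITS = 1.349

MODEL_ORDER = ("linear", "poly2", "poly3", "power", "hill", "exp2")
_PROFILE_CHI2 = stats.chi2.ppf(0.90, 1)  # one-sided 95% per bound


@dataclass
class GeneDoseMatrix:
    """Normalized expression (genes x samples) with its dose design."""

    genes: list[str]
    doses: np.ndarray              # per sample
    log2: np.ndarray               # genes x samples, log2 normalized
    raw: np.ndarray | None = None  # optional raw counts, same shape
    meta: pd.DataFrame | None = None

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.log2 = np.asarray(self.log2, dtype=float)
        if self.log2.shape != (len(self.genes), self.doses.size):
            raise ValueError("log2 matrix shape does not match genes x samples")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene ids must be unique")
        for d in np.unique(self.doses):
            if (self.doses == d).sum() < 2:
                raise ValueError(f"dose {d} has fewer than 2 replicates")

    def row(self, gene: str) -> np.ndarray:
        return self.log2[self.genes.index(gene)]


def prefilter_genes(matrix: GeneDoseMatrix) -> list[str]:
    """Genes with a strictly positive raw count in every sample.

    Requires the raw-count layer; refusing to fall back on log values keeps
    the filter meaningful (normalized values are positive by construction).
    """
    if matrix.raw is None:
        raise ValueError("prefilter requires the raw-count layer")
    keep = (matrix.raw > 0).all(axis=1)
    return [g for g, k in zip(matrix.genes, keep) if k]


# --------------------------------------------------------------------------
# model fitting
# --------------------------------------------------------------------------

@dataclass
class GeneFit:
    model: str
    params: dict[str, float]
    sse: float
    n: int
    n_params: int                  # mean-function parameters
    loglik: float
    aic: float
    fit_p: float                   # F-test vs saturated group-means model
    converged: bool = True
    flags: list[str] = field(default_factory=list)

    @property
    def residual_sd(self) -> float:
        dof = max(self.n - self.n_params, 1)
        return float(np.sqrt(self.sse / dof))

    def predict(self, x) -> np.ndarray:
        return _predict(self.model, self.params, np.asarray(x, dtype=float))


def _predict(model: str, p: dict[str, float], x: np.ndarray) -> np.ndarray:
    if model == "linear":
        return p["b0"] + p["b1"] * x
    if model == "poly2":
        return p["b0"] + p["b1"] * x + p["b2"] * x**2
    if model == "poly3":
        return p["b0"] + p["b1"] * x + p["b2"] * x**2 + p["b3"] * x**3
    if model == "power":
        return p["b0"] + p["b1"] * x ** p["delta"]
    if model == "hill":
        xn = x ** p["nH"]
        return p["b0"] + p["v"] * xn / (p["k"] ** p["nH"] + xn)
    if model == "exp2":
        return p["alpha"] * np.exp(p["beta"] * x)
    raise KeyError(model)


def _loglik(sse: float, n: int) -> float:
    s2 = max(sse / n, 1e-300)
    return -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)


def _gof_p(sse_model: float, k_model: int, x: np.ndarray, y: np.ndarray) -> float:
    """F-test of the model against the saturated group-means fit."""
    sse_full = 0.0
    n_groups = 0
    for d in np.unique(x):
        yy = y[x == d]
        sse_full += ((yy - yy.mean()) ** 2).sum()
        n_groups += 1
    df1 = n_groups - k_model
    df2 = y.size - n_groups
    if df1 <= 0 or df2 <= 0:
        return np.nan
    num = max(sse_model - sse_full, 0.0) / df1
    den = sse_full / df2
    if den == 0:
        return 1.0 if num == 0 else 0.0
    return float(stats.f.sf(num / den, df1, df2))


def _ls_linear(x: np.ndarray, y: np.ndarray, degree: int) -> tuple[dict, float]:
    design = np.vander(x, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    sse = float(((y - design @ coef) ** 2).sum())
    names = ["b0", "b1", "b2", "b3"][: degree + 1]
    return dict(zip(names, coef)), sse


def _fit_power(x: np.ndarray, y: np.ndarray) -> tuple[dict, float, bool]:
    def inner(delta: float) -> tuple[float, np.ndarray]:
        design = np.column_stack([np.ones_like(x), x**delta])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        return float(((y - design @ coef) ** 2).sum()), coef

    res = optimize.minimize_scalar(lambda t: inner(np.exp(t))[0],
                                   bounds=(0.0, np.log(8.0)), method="bounded",
                                   options={"xatol": 1e-10})
    delta = float(np.exp(res.x))
    sse, coef = inner(delta)
    return {"b0": float(coef[0]), "b1": float(coef[1]), "delta": delta}, sse, True


def _fit_hill(x: np.ndarray, y: np.ndarray) -> tuple[dict, float, bool]:
    xmax = x.max()
    pos = x[x > 0]
    lo = np.log(pos.min() / 30.0)

    def inner(theta) -> tuple[float, np.ndarray]:
        k, n = np.exp(theta)
        f = x**n / (k**n + x**n)
        design = np.column_stack([np.ones_like(x), f])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        return float(((y - design @ coef) ** 2).sum()), coef

    best = None
    for k0, n0 in ((0.5 * xmax, 1.0), (0.1 * xmax, 3.0), (2.0 * xmax, 1.0)):
        res = optimize.minimize(lambda t: inner(t)[0],
                                np.log([k0, n0]), method="L-BFGS-B",
                                bounds=[(lo, np.log(xmax * 100)),
                                        (np.log(0.1), np.log(15.0))],
                                options={"maxiter": 80})
        if best is None or res.fun < best.fun:
            best = res
    k, n = np.exp(best.x)
    sse, coef = inner(best.x)
    return ({"b0": float(coef[0]), "v": float(coef[1]), "k": float(k),
             "nH": float(n)}, sse, bool(best.success or np.isfinite(best.fun)))


def _fit_exp2(x: np.ndarray, y: np.ndarray) -> tuple[dict, float, bool]:
    sign = 1.0 if y.mean() >= 0 else -1.0
    z = sign * y
    if (z <= 0).any():
        return {}, np.inf, False
    # start from a log-linear regression, refine with Gauss-Newton
    beta0 = np.polyfit(x, np.log(z), 1)
    p0 = np.array([np.exp(beta0[1]), beta0[0]])

    def resid(p):
        return p[0] * np.exp(np.clip(p[1] * x, -300, 300)) - z

    res = optimize.least_squares(resid, p0, method="lm", xtol=1e-12, ftol=1e-12)
    alpha, beta = res.x
    if alpha <= 0:
        return {}, np.inf, False
    sse = float((res.fun**2).sum())
    return {"alpha": float(sign * alpha), "beta": float(beta)}, sse, True


_N_PARAMS = {"linear": 2, "poly2": 3, "poly3": 4, "power": 3, "hill": 4, "exp2": 2}


def fit_gene_models(y, doses, models: tuple[str, ...] = MODEL_ORDER) -> dict[str, GeneFit]:
    """Least-squares fit of every candidate model to one gene.

    The cubic polynomial needs at least 5 distinct doses and is silently
    dropped from the candidate set otherwise; a constant gene yields a flat
    linear fit flagged ``constant``.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite expression values")
    n_doses = np.unique(x).size
    if n_doses < 4:
        raise ValueError("need >= 4 distinct doses for gene dose-response fits")
    out: dict[str, GeneFit] = {}
    constant = np.allclose(y, y[0])
    for model in models:
        if model == "poly3" and n_doses < 5:
            continue
        try:
            if model in ("linear", "poly2", "poly3"):
                degree = {"linear": 1, "poly2": 2, "poly3": 3}[model]
                params, sse = _ls_linear(x, y, degree)
                ok = True
            elif model == "power":
                params, sse, ok = _fit_power(x, y)
            elif model == "hill":
                params, sse, ok = _fit_hill(x, y)
            else:
                params, sse, ok = _fit_exp2(x, y)
        except (np.linalg.LinAlgError, ValueError):
            ok = False
        if not ok or not np.isfinite(sse):
            continue
        k = _N_PARAMS[model]
        ll = _loglik(sse, y.size)
        fit = GeneFit(model=model, params=params, sse=sse, n=y.size,
                      n_params=k, loglik=ll, aic=2 * (k + 1) - 2 * ll,
                      fit_p=_gof_p(sse, k, x, y))
        if constant:
            fit.flags.append("constant")
        out[model] = fit
    if not out:
        raise ValueError("no candidate model converged")
    return out


def select_best_model(candidates: dict[str, GeneFit],
                      lowest_positive_dose: float,
                      alpha: float = 0.05) -> GeneFit:
    """Hierarchical best-model choice (see module docstring)."""
    chain = [candidates[m] for m in ("linear", "poly2", "poly3") if m in candidates]
    winner = None
    if chain:
        winner = chain[0]
        for nxt in chain[1:]:
            dk = nxt.n_params - winner.n_params
            lr = 2.0 * (nxt.loglik - winner.loglik)
            if stats.chi2.sf(max(lr, 0.0), dk) < alpha:
                winner = nxt
            else:
                break
    pool = [winner] if winner is not None else []
    pool += [candidates[m] for m in ("power", "hill", "exp2") if m in candidates]
    if not pool:
        pool = list(candidates.values())
    pool.sort(key=lambda f: (round(f.aic, 9), f.n_params, MODEL_ORDER.index(f.model)))
    best = pool[0]
    if best.model == "hill" and best.params["k"] < lowest_positive_dose / 3.0:
        best.flags.append("hill_k_below_third_lowest_dose")
        rest = [f for f in pool if f.model != "hill"]
        if rest:
            best = rest[0]
    return best


# --------------------------------------------------------------------------
# benchmark dose and profile bounds
# --------------------------------------------------------------------------

def _bmd_closed(fit: GeneFit, delta: float, xmax: float) -> tuple[float, int]:
    """Smallest positive dose with |y(x) - y(0)| = delta; (nan, 0) if never."""
    p = fit.params
    m = fit.model
    if m == "linear":
        if p["b1"] == 0:
            return np.nan, 0
        return delta / abs(p["b1"]), int(np.sign(p["b1"]))
    if m == "power":
        if p["b1"] == 0:
            return np.nan, 0
        return (delta / abs(p["b1"])) ** (1.0 / p["delta"]), int(np.sign(p["b1"]))
    if m == "hill":
        v = p["v"]
        if v == 0 or delta >= abs(v):
            return np.nan, 0
        q = delta / abs(v)
        return p["k"] * (q / (1 - q)) ** (1.0 / p["nH"]), int(np.sign(v))
    if m == "exp2":
        a, b = p["alpha"], p["beta"]
        if b == 0 or a == 0:
            return np.nan, 0
        s = int(np.sign(a * b))  # direction of change
        arg = 1.0 + s * delta / a if a > 0 else 1.0 + s * delta / a
        # exp(b x) = 1 + s*delta/alpha
        val = 1.0 + s * delta / a
        if val <= 0:
            return np.nan, 0
        return float(np.log(val) / b), s
    # polynomials: smallest positive real root of f(x) - f(0) = +/- delta
    coeffs = [p.get("b3", 0.0), p.get("b2", 0.0), p["b1"]]
    best = np.inf
    sign = 0
    for s in (+1, -1):
        roots = np.roots(coeffs + [-s * delta])
        for r in roots:
            if abs(r.imag) < 1e-8 * max(1.0, abs(r.real)) and r.real > 0:
                if r.real < best:
                    best = float(r.real)
                    sign = s
    return (best, sign) if np.isfinite(best) else (np.nan, 0)


def compute_gene_bmd(fit: GeneFit, bmr_sd: float = BMR_SD_UNITS,
                     sigma: float | None = None,
                     xmax: float | None = None) -> tuple[float, int, float]:
    """bmd_t, direction and the effect-size target delta = bmr_sd * sigma."""
    s = fit.residual_sd if sigma is None else sigma
    delta = bmr_sd * s
    bmd, sign = _bmd_closed(fit, delta, xmax or np.inf)
    return bmd, sign, delta


def _profile_nll(model: str, x, y, bmd: float, delta: float, sign: int,
                 theta_hint=None):
    """min -loglik subject to y(bmd) - y(0) = sign*delta."""
    n = y.size
    t = sign * delta

    def from_sse(sse):
        return -_loglik(sse, n)

    if model == "linear":
        b1 = t / bmd
        r = y - b1 * x
        return from_sse(((r - r.mean()) ** 2).sum()), None
    if model == "poly2":
        # b1 = t/B - b2*B ; regress y - (t/B)x on [1, x^2 - B x]
        z = y - (t / bmd) * x
        design = np.column_stack([np.ones_like(x), x**2 - bmd * x])
        coef, *_ = np.linalg.lstsq(design, z, rcond=None)
        return from_sse(((z - design @ coef) ** 2).sum()), None
    if model == "poly3":
        z = y - (t / bmd) * x
        design = np.column_stack([np.ones_like(x), x**2 - bmd * x, x**3 - bmd**2 * x])
        coef, *_ = np.linalg.lstsq(design, z, rcond=None)
        return from_sse(((z - design @ coef) ** 2).sum()), None
    if model == "power":
        def sse_of(ldelta):
            d = np.exp(ldelta)
            f = t * (x / bmd) ** d
            r = y - f
            return ((r - r.mean()) ** 2).sum()
        res = optimize.minimize_scalar(sse_of, bounds=(0.0, np.log(8.0)),
                                       method="bounded", options={"xatol": 1e-9})
        return from_sse(res.fun), res.x
    if model == "hill":
        pos = x[x > 0]
        bounds = [(np.log(pos.min() / 30.0), np.log(x.max() * 100)),
                  (np.log(0.1), np.log(15.0))]

        def sse_of(theta):
            k, nh = np.exp(theta)
            fb = bmd**nh / (k**nh + bmd**nh)
            if fb <= 0:
                return 1e10
            f = t / fb * x**nh / (k**nh + x**nh)
            r = y - f
            return ((r - r.mean()) ** 2).sum()

        starts = [np.log([0.5 * x.max(), 1.0]), np.log([0.1 * x.max(), 3.0])]
        if theta_hint is not None:
            starts.insert(0, theta_hint)
        best = None
        for s0 in starts:
            res = optimize.minimize(sse_of, s0, method="L-BFGS-B", bounds=bounds,
                                    options={"maxiter": 80})
            if best is None or res.fun < best.fun:
                best = res
        return from_sse(best.fun), best.x
    if model == "exp2":
        def sse_of(beta):
            eb = np.exp(np.clip(beta * bmd, -300, 300)) - 1.0
            if abs(eb) < 1e-12:
                return 1e10
            alpha = t / eb
            r = y - alpha * np.exp(np.clip(beta * x, -300, 300))
            return (r**2).sum()
        span = max(1.0 / x.max(), 1e-6)
        res = optimize.minimize_scalar(sse_of, bounds=(-5 * span, 5 * span),
                                       method="bounded", options={"xatol": 1e-12})
        return from_sse(res.fun), res.x
    raise KeyError(model)


def gene_bmd_bounds(fit: GeneFit, x, y, bmd: float, delta: float, sign: int,
                    max_factor: float = 1e4) -> tuple[float, float, list[str]]:
    """Profile-likelihood BMDL_t / BMDU_t at 95% one-sided each.

    The effect-size target delta is held at its MLE value while the curve
    parameters are re-optimized under the constraint that the response
    change at the candidate dose equals delta.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nll_hat = -fit.loglik
    flags: list[str] = []
    hint = None

    def deviance(b):
        nonlocal hint
        nll, hint_new = _profile_nll(fit.model, x, y, b, delta, sign, hint)
        if hint_new is not None:
            hint = hint_new
        return 2.0 * (nll - nll_hat)

    dev0 = deviance(bmd)
    offset = max(dev0, 0.0)

    def search(side):
        factor = 0.7 if side < 0 else 1.0 / 0.7
        limit_lo = bmd / max_factor
        limit_hi = bmd * max_factor
        prev, cur = bmd, bmd * factor
        while True:
            if deviance(cur) - offset > _PROFILE_CHI2:
                break
            prev = cur
            cur *= factor
            if cur < limit_lo:
                flags.append("unbounded_lower")
                return 0.0
            if cur > limit_hi:
                flags.append("unbounded_upper")
                return np.inf
        lo, hi = (cur, prev) if side < 0 else (prev, cur)
        f = lambda b: deviance(b) - offset - _PROFILE_CHI2
        try:
            return float(optimize.brentq(f, lo, hi, xtol=max(bmd * 1e-6, 1e-12)))
        except ValueError:
            # profile can be locally rough for the nonlinear models; fall
            # back to bisection keeping the inside/outside classification
            inner, outer = (hi, lo) if side < 0 else (lo, hi)
            for _ in range(50):
                mid = np.sqrt(inner * outer)
                if f(mid) > 0:
                    outer = mid
                else:
                    inner = mid
            return float(np.sqrt(inner * outer))

    return search(-1), search(+1), flags


# --------------------------------------------------------------------------
# record assembly and the filter cascade
# --------------------------------------------------------------------------

@dataclass
class GeneBmdRecord:
    gene: str
    model: str
    bmd: float
    bmdl: float
    bmdu: float
    fit_p: float
    max_fc: float
    direction: int
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def survives(self) -> bool:
        return all(self.flags.values()) if self.flags else False


def apply_bmd_filters(records: list[GeneBmdRecord] | pd.DataFrame,
                      highest_dose: float,
                      fit_p_min: float = 0.1,
                      ratio_max: float = 40.0,
                      fc_min: float = 1.5) -> pd.DataFrame:
    """Evaluate the four-rule conjunction and return the annotated table.

    A record survives iff fit p > ``fit_p_min`` AND BMDU/BMDL < ``ratio_max``
    AND bmd <= ``highest_dose`` AND max |fold change| >= ``fc_min``.  The
    rules are a pure conjunction, hence order-independent; each failure is
    recorded per gene.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([{
            "gene": r.gene, "model": r.model, "bmd": r.bmd, "bmdl": r.bmdl,
            "bmdu": r.bmdu, "fit_p": r.fit_p, "max_fc": r.max_fc,
            "direction": r.direction,
        } for r in records])
    if df["max_fc"].isna().any():
        missing = df.loc[df["max_fc"].isna(), "gene"].tolist()
        raise ValueError(f"missing fold-change linkage for genes: {missing[:5]}")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = df["bmdu"] / df["bmdl"]
    df["pass_fit_p"] = df["fit_p"] > fit_p_min
    df["pass_ratio"] = ratio < ratio_max
    df["pass_range"] = df["bmd"] <= highest_dose
    df["pass_fc"] = df["max_fc"].abs() >= fc_min
    df["survives"] = (df["pass_fit_p"] & df["pass_ratio"]
                      & df["pass_range"] & df["pass_fc"]).fillna(False)
    return df


def gene_bmd_table(matrix: GeneDoseMatrix, max_fc: dict[str, float] | pd.Series,
                   genes: list[str] | None = None,
                   bmr_sd: float = BMR_SD_UNITS,
                   fit_p_min: float = 0.1, ratio_max: float = 40.0,
                   fc_min: float = 1.5,
                   compute_bounds: str = "survivors") -> pd.DataFrame:
    """Fit, select and filter every gene; return the per-gene record table.

    ``max_fc`` maps gene id -> maximum observed |linear fold change| across
    doses (from the companion DE table).  Profile bounds are expensive, so
    with ``compute_bounds='survivors'`` they are evaluated only for genes
    already passing the three cheap rules; the ratio rule is then applied.
    (The cascade is a conjunction, so the outcome is order-independent.)
    """
    if genes is None:
        genes = matrix.genes if matrix.raw is None else prefilter_genes(matrix)
    x = matrix.doses
    xmax = float(x.max())
    lowest_pos = float(x[x > 0].min())
    mfc = pd.Series(max_fc)
    rows = []
    for g in genes:
        y = matrix.row(g)
        try:
            fits = fit_gene_models(y, x)
        except ValueError:
            continue
        best = select_best_model(fits, lowest_pos)
        bmd, sign, delta = compute_gene_bmd(best, bmr_sd)
        rows.append({
            "gene": g, "model": best.model, "bmd": bmd, "bmdl": np.nan,
            "bmdu": np.nan, "fit_p": best.fit_p,
            "max_fc": float(mfc.get(g, np.nan)), "direction": sign,
            "_best": best, "_delta": delta,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    cheap = ((df["fit_p"] > fit_p_min) & (df["bmd"] <= xmax)
             & (df["max_fc"].abs() >= fc_min)).fillna(False)
    need = df.index if compute_bounds == "all" else df.index[cheap]
    if compute_bounds != "none":
        for i in need:
            r = df.loc[i]
            if not np.isfinite(r["bmd"]):
                continue
            lo, hi, _ = gene_bmd_bounds(r["_best"], x, matrix.row(r["gene"]),
                                        r["bmd"], r["_delta"], int(r["direction"]))
            df.loc[i, ["bmdl", "bmdu"]] = [lo, hi]
    df = df.drop(columns=["_best", "_delta"])
    return apply_bmd_filters(df, xmax, fit_p_min, ratio_max, fc_min)
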