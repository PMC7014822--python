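"""DEG-count point of departure: the D1 / D1* estimator.

The number of genes differentially expressed by at least K-fold
(|fold change| >= K and FDR <= 0.05) at each dose is fit with a
fixed-plateau Hill curve

    Count(dose) = C / (1 + (d50 / dose)**n),        C = 1000 by default,

by iteratively re-weighted least squares with inverse-variance weights
under a Poisson error model (variance = mean).  The dose D1 at which the
fitted curve predicts a single differentially expressed gene,

    D1 = d50 * (C - 1)**(-1/n),

plays the role of a benchmark dose; its lower one-tailed 95% confidence
bound D1* (the BMDL analog) is the 5th percentile of D1 over parametric
bootstrap replicates: counts are redrawn Poisson about the fitted curve
and refit with the weights frozen at the inverse of the originally fitted
responses.

The control dose is excluded from fitting (the model is undefined at dose
zero, where the DEG count is identically zero by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DegCountCurve",
    "HillCountFit",
    "D1Result",
    "count_degs_by_threshold",
    "fit_hill_count",
    "compute_d1",
    "bootstrap_d1star",
    "d1_analysis",
]

WEIGHT_FLOOR = 1e-6  # variance floor so zero predicted counts stay usable


@dataclass
class DegCountCurve:
    """DEG counts per positive dose at one fold-change threshold K."""

    k: float
    doses: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.k < 1:
            raise ValueError("fold-change threshold K must be >= 1")
        if np.any(self.doses <= 0) or np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing and > 0")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


def count_degs_by_threshold(
    deg_table: pd.DataFrame, k_values=(2, 3, 5, 10), fdr_thresh: float = 0.05,
) -> dict[float, DegCountCurve]:
    """Per-dose counts of genes with |FC| >= K and FDR <= ``fdr_thresh``.

    Counts are nested: at each dose the count is non-increasing in K.
    """
    from .qc import _linear_fc

    fc = _linear_fc(deg_table).abs()
    fdr = pd.to_numeric(deg_table["fdr"])
    doses = np.sort(pd.to_numeric(deg_table["dose"]).unique())
    doses = doses[doses > 0]
    out = {}
    for k in k_values:
        if k < 1:
            raise ValueError("K must be >= 1")
        counts = [int(((pd.to_numeric(deg_table["dose"]) == d)
                       & (fc >= k) & (fdr <= fdr_thresh)).sum()) for d in doses]
        out[float(k)] = DegCountCurve(float(k), doses, np.array(counts, float))
    return out


@dataclass
class HillCountFit:
    plateau: float
    d50: float
    n: float
    converged: bool
    iterations: int
    weights: np.ndarray = field(repr=False)
    doses: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)

    def predict(self, dose) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        return self.plateau / (1.0 + (self.d50 / dose) ** self.n)


def _hill_count(dose: np.ndarray, d50: float, n: float, c: float) -> np.ndarray:
    return c / (1.0 + (d50 / dose) ** n)


def _wls_step(dose, counts, w, theta0, c, max_iter=60, tol=1e-10):
    """Gauss-Newton (with Levenberg damping) weighted LS in log parameters."""
    theta = np.asarray(theta0, dtype=float).copy()
    lx = np.log(dose)
    sw = np.sqrt(w)
    lam = 1e-8
    for _ in range(max_iter):
        l50, ln_n = theta
        n = np.exp(ln_n)
        z = n * (l50 - lx)
        f = c / (1.0 + np.exp(np.clip(z, -500, 500)))
        dfdz = -f * (1.0 - f / c)
        jac = np.column_stack([dfdz * n, dfdz * z])  # d/d l50, d/d ln_n
        r = counts - f
        a = (jac * sw[:, None]).T @ (jac * sw[:, None])
        g = (jac * w[:, None]).T @ r
        step = np.linalg.solve(a + lam * np.eye(2), g)
        new = theta + step
        # damped acceptance on the objective
        def obj(th):
            ff = c / (1.0 + np.exp(np.clip(np.exp(th[1]) * (th[0] - lx), -500, 500)))
            return float((w * (counts - ff) ** 2).sum())
        if obj(new) <= obj(theta) + 1e-12:
            lam = max(lam / 3, 1e-12)
        else:
            lam *= 10
            continue
        delta = np.max(np.abs(new - theta) / np.maximum(np.abs(theta), 1.0))
        theta = new
        if delta < tol:
            break
    return theta


def fit_hill_count(
    curve: DegCountCurve, plateau: float = 1000.0,
    tol: float = 1e-8, max_iter: int = 100,
) -> HillCountFit:
    """IRLS fit of the fixed-plateau Hill count curve.

    Alternates a Poisson-weighted least-squares fit (weights = inverse of
    the current predicted counts, floored at a small epsilon) with a weight
    update, until the relative parameter change drops below ``tol``.
    """
    dose, counts = curve.doses, curve.counts
    if (counts > 0).sum() < 2:
        raise ValueError("need at least 2 doses with a positive count")
    if np.allclose(counts, plateau):
        raise ValueError("all counts at the plateau: d50 is unidentifiable")
    if np.all(counts == 0):
        raise ValueError("all counts are zero")
    # starting values: d50 at the dose where counts cross plateau/2
    frac = np.clip(counts / plateau, 1e-6, 1 - 1e-6)
    # logit(frac) = n*(log dose - log d50): regress
    lg = np.log(frac / (1 - frac))
    slope, inter = np.polyfit(np.log(dose), lg, 1)
    n0 = float(np.clip(slope, 0.2, 20.0))
    d50_0 = float(np.exp(-inter / max(slope, 1e-6)))
    d50_0 = float(np.clip(d50_0, dose.min() / 100, dose.max() * 100))
    theta = np.array([np.log(d50_0), np.log(n0)])
    w = 1.0 / np.maximum(_hill_count(dose, np.exp(theta[0]), np.exp(theta[1]),
                                     plateau), WEIGHT_FLOOR)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new = _wls_step(dose, counts, w, theta, plateau)
        w = 1.0 / np.maximum(_hill_count(dose, np.exp(new[0]), np.exp(new[1]),
                                         plateau), WEIGHT_FLOOR)
        delta = np.max(np.abs(new - theta) / np.maximum(np.abs(theta), 1.0))
        theta = new
        if delta < tol:
            converged = True
            break
    return HillCountFit(plateau=plateau, d50=float(np.exp(theta[0])),
                        n=float(np.exp(theta[1])), converged=converged,
                        iterations=it, weights=w, doses=dose, counts=counts)


def compute_d1(fit: HillCountFit) -> float:
    """Dose at which the fitted curve predicts a single DEG (closed form)."""
    if fit.plateau <= 1:
        raise ValueError("plateau must exceed 1 for D1 to exist")
    return float(fit.d50 * (fit.plateau - 1.0) ** (-1.0 / fit.n))


def _batched_wls(dose, counts_mat, w, theta0, c, max_iter=80, tol=1e-9):
    """Vectorized Gauss-Newton over many bootstrap replicates at once.

    ``counts_mat`` is (R, D); weights are shared (frozen).  Returns the
    (R, 2) log-parameter array and a per-replicate convergence mask.
    """
    r_n, d_n = counts_mat.shape
    theta = np.tile(np.asarray(theta0, float), (r_n, 1))
    lx = np.log(dose)[None, :]
    w2 = w[None, :]
    lam = np.full(r_n, 1e-8)
    active = np.ones(r_n, dtype=bool)
    last_step = np.full(r_n, np.inf)

    def objective(th):
        z = np.exp(th[:, 1:2]) * (th[:, 0:1] - lx)
        f = c / (1.0 + np.exp(np.clip(z, -500, 500)))
        return ((counts_mat - f) ** 2 * w2).sum(axis=1)

    obj = objective(theta)
    for _ in range(max_iter):
        if not active.any():
            break
        th = theta
        n = np.exp(th[:, 1:2])
        z = n * (th[:, 0:1] - lx)
        f = c / (1.0 + np.exp(np.clip(z, -500, 500)))
        dfdz = -f * (1.0 - f / c)
        j1 = dfdz * n          # d f / d l50
        j2 = dfdz * z          # d f / d ln n
        r = counts_mat - f
        a11 = (w2 * j1 * j1).sum(axis=1)
        a12 = (w2 * j1 * j2).sum(axis=1)
        a22 = (w2 * j2 * j2).sum(axis=1)
        g1 = (w2 * j1 * r).sum(axis=1)
        g2 = (w2 * j2 * r).sum(axis=1)
        a11l = a11 + lam
        a22l = a22 + lam
        det = a11l * a22l - a12 * a12
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        s1 = (a22l * g1 - a12 * g2) / det
        s2 = (a11l * g2 - a12 * g1) / det
        cand = theta + np.column_stack([s1, s2]) * active[:, None]
        cand_obj = objective(cand)
        accept = active & (cand_obj <= obj + 1e-12)
        theta = np.where(accept[:, None], cand, theta)
        step = np.max(np.abs(np.column_stack([s1, s2])), axis=1) / \
            np.maximum(np.max(np.abs(theta), axis=1), 1.0)
        last_step = np.where(accept, step, last_step)
        obj = np.where(accept, cand_obj, obj)
        lam = np.where(accept, np.maximum(lam / 3, 1e-12), lam * 10)
        active = active & ~(accept & (step < tol)) & (lam < 1e12)
    ok = (last_step < 1e-4) & np.all(np.isfinite(theta), axis=1)
    return theta, ok


@dataclass
class D1Result:
    k: float
    fit: HillCountFit
    d1: float
    d1_star: float
    n_boot: int
    seed: int | None


def bootstrap_d1star(
    fit: HillCountFit, curve: DegCountCurve | None = None,
    n_sim: int = 10000, seed: int | None = None,
    refit_weights: str = "frozen", max_fail_fraction: float = 0.05,
) -> float:
    """Parametric-bootstrap lower one-tailed 95% bound on D1.

    Counts at each dose are redrawn Poisson about the fitted responses and
    refit; with ``refit_weights='frozen'`` (the default) the weights stay
    fixed at the inverse of the originally fitted responses rather than
    being re-iterated, and ``'irls'`` re-runs the full IRLS per replicate
    as a sensitivity option.  D1* is the 5th percentile of the sorted
    bootstrap D1 sample.  Replicates that fail to converge are redrawn (up
    to twice the requested number); more than ``max_fail_fraction``
    permanent failures is an error.
    """
    if not fit.converged:
        raise ValueError("bootstrap requires a converged fit")
    rng = np.random.default_rng(seed)
    mu = fit.predict(fit.doses)
    w = 1.0 / np.maximum(mu, WEIGHT_FLOOR)
    theta0 = np.array([np.log(fit.d50), np.log(fit.n)])
    c = fit.plateau

    collected = np.empty(0)
    drawn = 0
    cap = 2 * n_sim
    while collected.size < n_sim and drawn < cap:
        todo = min(n_sim - collected.size, cap - drawn)
        counts = rng.poisson(mu, size=(todo, mu.size)).astype(float)
        drawn += todo
        # replicates with <2 informative doses cannot constrain 2 params
        usable = (counts > 0).sum(axis=1) >= 2
        counts = counts[usable]
        if counts.size == 0:
            continue
        if refit_weights == "frozen":
            theta, ok = _batched_wls(fit.doses, counts, w, theta0, c)
        else:
            theta = np.empty((counts.shape[0], 2))
            ok = np.zeros(counts.shape[0], dtype=bool)
            for i, row in enumerate(counts):
                try:
                    f = fit_hill_count(DegCountCurve(1.0, fit.doses, row),
                                       plateau=c)
                    theta[i] = [np.log(f.d50), np.log(f.n)]
                    ok[i] = f.converged
                except ValueError:
                    ok[i] = False
        d50_b = np.exp(theta[ok, 0])
        n_b = np.exp(theta[ok, 1])
        d1_b = d50_b * (c - 1.0) ** (-1.0 / n_b)
        collected = np.concatenate([collected, d1_b[np.isfinite(d1_b)]])
    if collected.size < n_sim * (1 - max_fail_fraction):
        raise RuntimeError(
            f"bootstrap convergence failure: {collected.size}/{n_sim} usable "
            f"replicates after {drawn} draws")
    sample = np.sort(collected[:n_sim])
    return float(np.percentile(sample, 5.0, method="linear"))


def d1_analysis(deg_table: pd.DataFrame, k_values=(2, 3, 5, 10),
                plateau: float = 1000.0, n_sim: int = 10000,
                seed: int | None = None) -> list[D1Result]:
    """Count DEGs per K, fit the count curve, invert to D1 and bootstrap D1*."""
    curves = count_degs_by_threshold(deg_table, k_values)
    out = []
    for k, curve in curves.items():
        fit = fit_hill_count(curve, plateau=plateau)
        d1 = compute_d1(fit)
        star = bootstrap_d1star(fit, curve, n_sim=n_sim, seed=seed)
        out.append(D1Result(k=k, fit=fit, d1=d1, d1_star=star,
                            n_boot=n_sim, seed=seed))
    return out
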