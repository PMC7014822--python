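"""Synthetic dose-response study generator with known ground truth.

Emulates the design of a 28-day repeated-dose rat study: doses
{0, 300, 500, 750, 1000, 1500} mg/kg/day, six animals per group, an apical
endpoint following a known exponential or Hill curve with multiplicative
lognormal noise, and a transcriptome in which a configurable fraction of
genes follows monotone Hill-shaped dose-response curves on the log2 scale.
Every generated object carries its analytic truth (true benchmark dose,
true top-dose fold change), so parameter recovery by the downstream
modeling stages can be measured exactly.

The differential-expression stand-in (:func:`make_deg_table`) is a Welch
t-test on log2 values with Benjamini-Hochberg correction within each dose.
It is deliberately simple — it is NOT a reimplementation of a count-based
DE method such as DESeq2 and makes no claim of equivalence; it exists so
the pipeline closes the loop on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genebmd import BMR_SD_UNITS, GeneDoseMatrix

__all__ = [
    "StudyDesign",
    "TrueCurve",
    "EffectLaw",
    "simulate_apical_series",
    "simulate_expression_study",
    "make_deg_table",
]

DEFAULT_DOSES = (0.0, 300.0, 500.0, 750.0, 1000.0, 1500.0)


@dataclass
class StudyDesign:
    """Dose design of one simulated study."""

    doses: tuple[float, ...] = DEFAULT_DOSES
    n_per_group: int = 6
    series: tuple[str, ...] = ("males_d29",)
    seed: int = 0

    def __post_init__(self):
        d = np.asarray(self.doses, dtype=float)
        if d[0] != 0:
            raise ValueError("first dose must be the control (0)")
        if not np.all(np.diff(d) > 0):
            raise ValueError("doses must be strictly increasing")
        if self.n_per_group < 2:
            raise ValueError("need at least 2 animals per group")
        if not self.series:
            raise ValueError("at least one series label is required")

    @property
    def sample_doses(self) -> np.ndarray:
        return np.repeat(np.asarray(self.doses, dtype=float), self.n_per_group)


@dataclass
class TrueCurve:
    """A generating dose-response curve for an apical endpoint.

    ``family`` is one of {"exponential", "hill", "flat"} with parameters in
    the same convention the fitting side uses: exponential
    y = a*[c - (c-1)*exp(-b*x**d)] (omit c for y = a*exp(b*x**d)); Hill
    y = a*[1 + (c-1)*x**d / (b**d + x**d)].  ``noise_cv`` is the
    multiplicative lognormal coefficient of variation; the noise has unit
    median so the curve is the median (geometric-mean) response, matching
    the lognormal likelihood used for fitting.
    """

    family: str
    params: dict[str, float] = field(default_factory=dict)
    noise_cv: float = 0.25

    def __post_init__(self):
        if self.family not in ("exponential", "hill", "flat"):
            raise ValueError(f"unknown curve family {self.family!r}")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.family != "flat" or self.params:
            if self.params.get("a", 1.0) <= 0:
                raise ValueError("background a must be > 0")

    def mean(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p = self.params
        a = p.get("a", 1.0)
        if self.family == "flat":
            return np.full_like(x, a)
        d = p.get("d", 1.0)
        b = p["b"]
        if self.family == "exponential":
            if "c" not in p:
                return a * np.exp(b * x**d)
            c = p["c"]
            return a * (c - (c - 1.0) * np.exp(-b * x**d))
        c = p["c"]
        return a * (1.0 + (c - 1.0) * x**d / (b**d + x**d))

    def true_bmd(self, bmr: float = 0.10) -> float:
        """Analytic dose at a relative-change benchmark response.

        Undefined (nan) for flat curves or curves whose fold range never
        reaches the benchmark response.
        """
        p = self.params
        if self.family == "flat":
            return np.nan
        d = p.get("d", 1.0)
        b = p["b"]
        if self.family == "exponential" and "c" not in p:
            tau = np.log1p(bmr) if b > 0 else np.log1p(-bmr)
            return float((tau / b) ** (1.0 / d))
        c = p["c"]
        gamma = abs(c - 1.0)
        if gamma <= bmr:
            return np.nan
        q = bmr / gamma
        if self.family == "exponential":
            return float((-np.log1p(-q) / b) ** (1.0 / d))
        return float(b * (q / (1.0 - q)) ** (1.0 / d))


def simulate_apical_series(
    design: StudyDesign, curve: TrueCurve, bmr: float = 0.10,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, float]:
    """Individual-animal records from a known curve, plus its analytic BMD.

    Response = curve median at dose x unit-median lognormal noise with the
    requested CV.  Deterministic for a fixed design seed.
    """
    rng = rng or np.random.default_rng(design.seed)
    sigma = np.sqrt(np.log1p(curve.noise_cv**2))
    rows = []
    for s in design.series:
        for dose in design.doses:
            mu = float(curve.mean(dose))
            noise = np.exp(rng.normal(0.0, sigma, design.n_per_group)) if sigma > 0 \
                else np.ones(design.n_per_group)
            for j, v in enumerate(mu * noise):
                rows.append((s, dose, f"{s}_{dose:g}_{j + 1}", v))
    df = pd.DataFrame(rows, columns=["series", "dose", "subject", "value"])
    return df, curve.true_bmd(bmr)


@dataclass
class EffectLaw:
    """Distribution of (true BMD, top-dose effect, direction) for responsive genes.

    True BMDs are log-uniform on [bmd_min, bmd_max]; the top-dose |log2
    fold change| is uniform on [fc_log2_min, fc_log2_max] (defaults span
    ~1.3- to 5-fold, matching the modest fold changes of a weakly acting
    compound); direction is up with probability ``p_up``.  Hill exponents
    of the generating curves are uniform on [n_min, n_max].
    """

    bmd_min: float = 100.0
    bmd_max: float = 1200.0
    fc_log2_min: float = 0.38   # 1.3-fold
    fc_log2_max: float = 2.32   # 5-fold
    p_up: float = 0.5
    n_min: float = 1.0
    n_max: float = 4.0

    def __post_init__(self):
        if self.bmd_min <= 0 or self.bmd_max <= self.bmd_min:
            raise ValueError("effect law requires 0 < bmd_min < bmd_max")


@dataclass
class DispersionSpec:
    """Per-gene noise on the log2 scale (additive Gaussian)."""

    sd_min: float = 0.15
    sd_max: float = 0.40


def simulate_expression_study(
    design: StudyDesign,
    n_genes: int = 2000,
    responsive_fraction: float = 0.10,
    effect_law: EffectLaw | None = None,
    dispersion: DispersionSpec | None = None,
    baseline_log2: tuple[float, float] = (4.0, 12.0),
    poisson_counts: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[GeneDoseMatrix, pd.DataFrame]:
    """Expression matrix with a known responsive subset, plus its truth table.

    Responsive genes follow Delta_log2(x) = v * x^n / (k^n + x^n) with the
    half-maximal dose chosen so that the analytic benchmark dose — the dose
    at which |Delta_log2| equals 1.349 x the gene's own noise SD, i.e. the
    quantity the transcriptomic BMD stage estimates — equals the BMD drawn
    from the effect law.  Non-responsive genes are dose-flat.  Raw counts
    are an optional Poisson layer around 2**log2 (the truth stays analytic
    on the log2 scale).
    """
    if not (0 <= responsive_fraction <= 1):
        raise ValueError("responsive_fraction must be in [0, 1]")
    if n_genes < 1:
        raise ValueError("need at least one gene")
    law = effect_law or EffectLaw()
    disp = dispersion or DispersionSpec()
    rng = rng or np.random.default_rng(design.seed)
    x = design.sample_doses
    xmax = x.max()

    n_resp = int(round(n_genes * responsive_fraction))
    responsive = np.zeros(n_genes, dtype=bool)
    responsive[:n_resp] = True

    base = rng.uniform(*baseline_log2, n_genes)
    sd = rng.uniform(disp.sd_min, disp.sd_max, n_genes)
    direction = np.where(rng.random(n_genes) < law.p_up, 1.0, -1.0)
    top_fc = rng.uniform(law.fc_log2_min, law.fc_log2_max, n_genes)
    nh = rng.uniform(law.n_min, law.n_max, n_genes)
    tgt_bmd = np.exp(rng.uniform(np.log(law.bmd_min), np.log(law.bmd_max), n_genes))
    if np.any(tgt_bmd <= 0):
        raise ValueError("effect law produced a non-positive true BMD")

    genes = [f"gene{i + 1:05d}" for i in range(n_genes)]
    mean_log2 = np.tile(base[:, None], (1, x.size))
    true_bmd = np.full(n_genes, np.nan)
    true_top = np.zeros(n_genes)

    delta = BMR_SD_UNITS * sd  # the benchmark change each gene must show
    for i in np.flatnonzero(responsive):
        # choose amplitude and k so that the top-dose |log2FC| is top_fc
        # and |Delta(bmd)| = delta: with q = delta/|v|,
        # bmd = k * (q/(1-q))**(1/n) once v is fixed by the top constraint.
        n = nh[i]
        # Two constraints fix (|v|, k): the top-dose effect
        # |v|*X/(K+X) = top_fc with X = xmax^n, K = k^n, and the benchmark
        # change |v|*u/(K+u) = delta with u = bmd^n.  Dividing them gives
        # rr = delta/top_fc = u(K+X) / (X(K+u)), hence
        # K = uX(1-rr)/(rr*X - u), valid when u/X < rr < 1; outside that
        # range the requested BMD is unreachable for the drawn effect size
        # and rr is clamped to the feasible interval (the realized true_bmd
        # below stays analytic either way).
        X = xmax**n
        u = tgt_bmd[i] ** n
        rr = delta[i] / top_fc[i]
        if rr <= u / X or rr >= 1.0:
            rr = float(np.clip(rr, u / X * (1 + 1e-9), 1 - 1e-9))
        K = u * X * (1.0 - rr) / (rr * X - u)
        if K <= 0 or not np.isfinite(K):
            K = X  # degenerate fall-back: k = xmax
        k = K ** (1.0 / n)
        v = direction[i] * top_fc[i] * (K + X) / X
        mean_log2[i] = base[i] + v * x**n / (K + x**n)
        true_top[i] = v * X / (K + X)
        q = delta[i] / abs(v)
        true_bmd[i] = k * (q / (1 - q)) ** (1.0 / n) if q < 1 else np.nan

    log2 = mean_log2 + rng.normal(0.0, sd[:, None], mean_log2.shape)
    raw = rng.poisson(2.0**log2).astype(float) if poisson_counts else None
    meta = pd.DataFrame({
        "sample": [f"s{j + 1:02d}" for j in range(x.size)],
        "dose": x,
        "replicate": np.tile(np.arange(1, design.n_per_group + 1), len(design.doses)),
        "series": design.series[0],
    })
    matrix = GeneDoseMatrix(genes=genes, doses=x, log2=log2, raw=raw, meta=meta)
    truth = pd.DataFrame({
        "gene": genes,
        "responsive": responsive,
        "direction": np.where(responsive, np.sign(true_top).astype(int), 0),
        "true_bmd": np.where(responsive, true_bmd, np.nan),
        "true_top_log2fc": np.where(responsive, true_top, 0.0),
        "noise_sd": sd,
    })
    return matrix, truth


def make_deg_table(matrix: GeneDoseMatrix, dataset: str = "synthetic") -> pd.DataFrame:
    """Stand-in differential-expression table (Welch t + BH per dose).

    Columns: gene, dataset, dose, log2fc, fc, pvalue, fdr.  log2fc is the
    difference of mean log2 expression vs the control group; p-values come
    from Welch's t-test on log2 values; FDR is Benjamini-Hochberg within
    each dose.  Not equivalent to a count-model DE test.
    """
    doses = np.unique(matrix.doses)
    if doses.size < 2:
        raise ValueError("need at least one non-control dose")
    ctrl = matrix.log2[:, matrix.doses == 0]
    if ctrl.shape[1] < 2:
        raise ValueError("need >= 2 control replicates")
    frames = []
    for d in doses[doses > 0]:
        trt = matrix.log2[:, matrix.doses == d]
        l2fc = trt.mean(axis=1) - ctrl.mean(axis=1)
        t = stats.ttest_ind(trt, ctrl, axis=1, equal_var=False)
        p = np.where(np.isfinite(t.pvalue), t.pvalue, 1.0)
        fdr = multipletests(p, method="fdr_bh")[1]
        sign = np.where(l2fc >= 0, 1.0, -1.0)
        frames.append(pd.DataFrame({
            "gene": matrix.genes, "dataset": dataset, "dose": d,
            "log2fc": l2fc, "fc": sign * 2.0 ** np.abs(l2fc),
            "pvalue": p, "fdr": fdr,
        }))
    return pd.concat(frames, ignore_index=True)
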