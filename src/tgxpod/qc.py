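"""Small gate statistics and DEG bookkeeping.

These are the tests that drive analysis decisions — whether an animal is
dropped before dose-response modeling (Grubbs), whether an endpoint series
is excluded for unequal variance (Bartlett) — plus fold-change/FDR
thresholding of differential-expression tables, cross-dataset DEG overlap,
and the fold-change magnitude summary.

Grubbs and Bartlett are implemented from their textbook formulas because
they gate modeling decisions and must be auditable; routine omnibus tests
(ANOVA/Dunnett, Shapiro-Wilk, Levene) are deliberately left to standard
libraries and are not wrapped here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DegSets",
    "deg_filter",
    "overlap_analysis",
    "grubbs_test",
    "bartlett_test",
    "fc_distribution",
]

#: Expected columns of a tidy DE table (one row per gene per dose).
DEG_TABLE_COLUMNS = ("gene", "dose", "fc", "fdr")


@dataclass
class DegSets:
    """Per-dose up/down DEG identifier sets for one dataset."""

    dataset: str
    up: dict[float, set[str]] = field(default_factory=dict)
    down: dict[float, set[str]] = field(default_factory=dict)

    @property
    def union(self) -> set[str]:
        out: set[str] = set()
        for d in self.up.values():
            out |= d
        for d in self.down.values():
            out |= d
        return out

    def at(self, dose: float) -> set[str]:
        return self.up.get(dose, set()) | self.down.get(dose, set())


def _linear_fc(table: pd.DataFrame) -> pd.Series:
    """Signed linear fold change from whichever column the table carries.

    ``fc`` is signed linear fold change (|fc| >= 1 by convention, sign =
    direction); ``log2fc`` is converted via sign(l)*2**|l|.
    """
    if "fc" in table.columns:
        fc = pd.to_numeric(table["fc"])
        if (fc == 0).any():
            raise ValueError("linear fold change of 0 is malformed")
        if ((fc > -1) & (fc < 1)).any():
            raise ValueError(
                "linear fold changes must satisfy |fc| >= 1; "
                "ratios < 1 are encoded as negative fold changes"
            )
        return fc
    if "log2fc" in table.columns:
        l2 = pd.to_numeric(table["log2fc"])
        return np.sign(l2).replace(0, 1) * 2.0 ** l2.abs()
    raise ValueError("DE table needs an 'fc' or 'log2fc' column")


def deg_filter(
    table: pd.DataFrame,
    fc_thresh: float = 1.5,
    fdr_thresh: float = 0.05,
    dataset: str = "",
) -> DegSets:
    """Call DEGs at joint |fold change| and FDR thresholds.

    A gene is differentially expressed at a dose iff |FC| >= ``fc_thresh``
    and FDR <= ``fdr_thresh``; direction is the sign of the fold change.
    The defaults are the standard criteria; the relaxed variant (1.4, 0.1)
    is obtained by passing those values.
    """
    if fc_thresh < 1:
        raise ValueError("fc_thresh must be >= 1 (linear fold change)")
    if not (0 < fdr_thresh <= 1):
        raise ValueError("fdr_thresh must be in (0, 1]")
    fc = _linear_fc(table)
    fdr = pd.to_numeric(table["fdr"])
    hit = (fc.abs() >= fc_thresh) & (fdr <= fdr_thresh)
    out = DegSets(dataset=dataset or str(table.get("dataset", pd.Series([""])).iloc[0]))
    sub = table.loc[hit, ["gene", "dose"]].assign(up=(fc[hit] > 0).to_numpy())
    for (dose, up), grp in sub.groupby(["dose", "up"]):
        target = out.up if up else out.down
        target.setdefault(float(dose), set()).update(grp["gene"])
    return out


def overlap_analysis(sets: list[set[str]]) -> dict:
    """Exact intersection/union cardinalities and membership for >= 2 sets."""
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    inter = set.intersection(*sets)
    union = set.union(*sets)
    return {
        "n_intersection": len(inter),
        "n_union": len(union),
        "intersection": inter,
        "union": union,
    }


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the Student-t formula."""
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_test(values, alpha: float = 0.05):
    """Two-sided single-outlier Grubbs test.

    G = max|x_i - mean| / sd with the sample (n-1) standard deviation.
    Returns ``(G, critical_value, index_of_outlier_or_None)``. At most one
    observation is flagged per call; iterative removal is intentionally not
    performed.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: Grubbs statistic undefined")
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    g = dev[i] / sd
    crit = grubbs_critical_value(n, alpha)
    return g, crit, (i if g > crit else None)


def bartlett_test(groups):
    """Bartlett's chi-square test of variance homogeneity.

    Classic statistic: T = [(N-k) ln Sp^2 - sum (n_i-1) ln s_i^2] / C with
    C = 1 + (sum 1/(n_i-1) - 1/(N-k)) / (3(k-1)); p from chi-square(k-1).
    Used as the exclusion gate for apical series (p <= 0.05 flags a series).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("Bartlett needs >= 2 groups with n >= 2 each")
    ns = np.array([g.size for g in gs])
    vs = np.array([g.var(ddof=1) for g in gs])
    if (vs == 0).any():
        raise ValueError("a group has zero variance")
    k = len(gs)
    big_n = int(ns.sum())
    sp2 = ((ns - 1) * vs).sum() / (big_n - k)
    t = (big_n - k) * np.log(sp2) - ((ns - 1) * np.log(vs)).sum()
    c = 1 + (np.sum(1 / (ns - 1)) - 1 / (big_n - k)) / (3 * (k - 1))
    statistic = t / c
    p = float(stats.chi2.sf(statistic, k - 1))
    return float(statistic), p


def fc_distribution(
    table: pd.DataFrame,
    dose: float,
    fc_thresh: float = 1.5,
    fdr_thresh: float = 0.05,
    bins: tuple[float, ...] = (1.5, 2.0, 3.0),
) -> pd.DataFrame:
    """Percent of DEGs at ``dose`` falling in |FC| magnitude bins.

    Default bins are [1.5, 2), [2, 3), [3, inf). Returns an empty frame when
    no gene passes the DEG criteria at the dose.
    """
    fc = _linear_fc(table)
    sel = (
        (pd.to_numeric(table["dose"]) == dose)
        & (fc.abs() >= fc_thresh)
        & (pd.to_numeric(table["fdr"]) <= fdr_thresh)
    )
    mags = fc[sel].abs().to_numpy()
    edges = list(bins) + [np.inf]
    labels = [
        f"{edges[i]:g}-{edges[i + 1]:g}" if np.isfinite(edges[i + 1]) else f">={edges[i]:g}"
        for i in range(len(bins))
    ]
    if mags.size == 0:
        return pd.DataFrame({"bin": labels, "count": 0, "percent": np.nan})
    counts = np.histogram(mags, bins=edges)[0]
    return pd.DataFrame(
        {"bin": labels, "count": counts, "percent": 100.0 * counts / mags.size}
    )
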