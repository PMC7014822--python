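"""Gene-set enrichment and transcriptional point-of-departure aggregation.

Genes surviving the per-gene benchmark-dose filter cascade are matched to
gene-set collections; a set is called enriched when a one-tailed Fisher
exact (hypergeometric over-representation) test gives p <= 0.1 with at
least 10 surviving member genes — raw p-values, no multiple-testing
correction, matching standard rodent-bioassay practice.  A battery of
pathway-agnostic and pathway-based strategies then turns per-gene
BMDL_t/BMD_t/BMDU_t triples into a single transcriptional POD estimate,
so the robustness of the POD to the aggregation choice can be examined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "PathwayPod",
    "PodEstimate",
    "fisher_enrichment",
    "pathway_pods",
    "aggregate_pod",
    "concordance_report",
    "STRATEGIES",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. one GMT file)."""

    sets: dict[str, set[str]]
    source: str = ""

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def restricted_to(self, universe: set[str]) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: s & universe for n, s in self.sets.items() if s & universe},
            self.source)


def fisher_enrichment(
    selected: set[str], collection: GeneSetCollection, universe: set[str],
) -> pd.DataFrame:
    """One-tailed over-representation p-value per gene set.

    p = P[overlap >= observed] under the hypergeometric null of drawing
    |selected| genes from the universe.  Sets are intersected with the
    universe first; no multiple-testing correction is applied by default.
    """
    if not universe:
        raise ValueError("empty universe")
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    m = len(universe)
    n_sel = len(selected)
    rows = []
    for name, members in collection.sets.items():
        inset = members & universe
        k = len(inset & selected)
        p = float(stats.hypergeom.sf(k - 1, m, len(inset), n_sel)) if inset else 1.0
        rows.append((name, len(inset), k, p))
    return pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])


@dataclass
class PathwayPod:
    set_name: str
    overlap: int
    p: float
    bmdl: float
    bmd: float
    bmdu: float


def pathway_pods(
    records: pd.DataFrame, collection: GeneSetCollection, universe: set[str],
    p_max: float = 0.1, min_overlap: int = 10,
) -> pd.DataFrame:
    """Median BMD triple per enriched pathway.

    ``records`` is the surviving per-gene table (columns gene, bmd, bmdl,
    bmdu).  A pathway is reported only when its enrichment p <= ``p_max``
    and it holds at least ``min_overlap`` surviving genes.
    """
    surviving = set(records["gene"])
    enr = fisher_enrichment(surviving & universe, collection, universe)
    keep = enr[(enr["p"] <= p_max) & (enr["overlap"] >= min_overlap)]
    rows = []
    indexed = records.set_index("gene")
    for r in keep.itertuples():
        members = collection.sets[r.set] & surviving
        sub = indexed.loc[sorted(members)]
        rows.append(PathwayPod(r.set, int(r.overlap), float(r.p),
                               float(sub["bmdl"].median()),
                               float(sub["bmd"].median()),
                               float(sub["bmdu"].median())))
    return pd.DataFrame([vars(p) for p in rows],
                        columns=["set_name", "overlap", "p", "bmdl", "bmd", "bmdu"])


@dataclass
class PodEstimate:
    strategy: str
    description: str
    bmdl: float
    bmd: float
    bmdu: float
    n_items: int

    @property
    def interval(self) -> tuple[float, float]:
        return (self.bmdl, self.bmdu)


def _median_triple(df: pd.DataFrame) -> tuple[float, float, float]:
    return (float(df["bmdl"].median()), float(df["bmd"].median()),
            float(df["bmdu"].median()))


def _gene_fc_rank(records: pd.DataFrame, deg_table: pd.DataFrame) -> pd.DataFrame:
    """Per surviving gene: extreme signed log2FC across doses plus best FDR."""
    from .qc import _linear_fc

    fc = _linear_fc(deg_table)
    l2 = np.sign(fc) * np.log2(fc.abs())
    aux = pd.DataFrame({"gene": deg_table["gene"], "l2": l2,
                        "fdr": pd.to_numeric(deg_table["fdr"])})
    grp = aux.groupby("gene")
    summary = pd.DataFrame({
        "max_l2": grp["l2"].max(),
        "min_l2": grp["l2"].min(),
        "abs_l2": grp["l2"].apply(lambda s: s.abs().max()),
        "best_fdr": grp["fdr"].min(),
    })
    return records.merge(summary, left_on="gene", right_index=True, how="left")


def _top20(df: pd.DataFrame, by: str, ascending: bool) -> pd.DataFrame:
    # deterministic ordering: key, then FDR, then gene id
    return df.sort_values([by, "best_fdr", "gene"],
                          ascending=[ascending, True, True]).head(20)


STRATEGIES = (
    "all_genes",
    "lowest20_genes",
    "top20_induced",
    "top20_repressed",
    "top20_absfc",
    "pathway_medians",
    "lowest20_pathways",
    "most_sensitive_pathway",
    "common_pathways",
)


def aggregate_pod(
    records: pd.DataFrame,
    strategy: str,
    deg_table: pd.DataFrame | None = None,
    pathways: pd.DataFrame | None = None,
    pathway_tables: list[pd.DataFrame] | None = None,
) -> PodEstimate:
    """One transcriptional POD estimate from surviving gene records.

    Pathway-agnostic strategies use ``records`` (and the DE table for
    fold-change ranking); pathway-based ones use the enriched-pathway
    table(s) from :func:`pathway_pods`.  ``common_pathways`` averages the
    median BMDL over the pathways enriched in every provided dataset.
    """
    if records is None or len(records) == 0:
        raise ValueError("no surviving gene records to aggregate")
    if strategy == "all_genes":
        l, b, u = _median_triple(records)
        return PodEstimate(strategy, "median over all surviving genes",
                           l, b, u, len(records))
    if strategy == "lowest20_genes":
        sub = records.sort_values(["bmd", "gene"]).head(20)
        l, b, u = _median_triple(sub)
        return PodEstimate(strategy, "20 genes with the lowest BMD_t",
                           l, b, u, len(sub))
    if strategy in ("top20_induced", "top20_repressed", "top20_absfc"):
        if deg_table is None:
            raise ValueError(f"strategy {strategy} needs the DE table")
        ranked = _gene_fc_rank(records, deg_table)
        if strategy == "top20_induced":
            sub = _top20(ranked, "max_l2", ascending=False)
            desc = "20 most induced genes"
        elif strategy == "top20_repressed":
            sub = _top20(ranked, "min_l2", ascending=True)
            desc = "20 most repressed genes"
        else:
            sub = _top20(ranked, "abs_l2", ascending=False)
            desc = "20 genes with the largest |fold change|"
        l, b, u = _median_triple(sub)
        return PodEstimate(strategy, desc, l, b, u, len(sub))
    if strategy in ("pathway_medians", "lowest20_pathways", "most_sensitive_pathway"):
        if pathways is None or pathways.empty:
            raise ValueError(f"strategy {strategy} needs enriched pathways "
                             "(none passed the enrichment thresholds)")
        if strategy == "pathway_medians":
            sub = pathways
            desc = "median over enriched-pathway medians"
        elif strategy == "lowest20_pathways":
            sub = pathways.sort_values(["bmd", "set_name"]).head(20)
            desc = "20 enriched pathways with the lowest median BMD_t"
        else:
            sub = pathways.sort_values(["bmd", "set_name"]).head(1)
            desc = "most sensitive enriched pathway"
        return PodEstimate(strategy, desc, float(sub["bmdl"].median()),
                           float(sub["bmd"].median()),
                           float(sub["bmdu"].median()), len(sub))
    if strategy == "common_pathways":
        tables = pathway_tables if pathway_tables is not None else [pathways]
        if not tables or any(t is None or t.empty for t in tables):
            raise ValueError("common_pathways needs enriched pathways for "
                             "every dataset")
        common = set(tables[0]["set_name"])
        for t in tables[1:]:
            common &= set(t["set_name"])
        if not common:
            raise ValueError("no pathway enriched in every dataset")
        meds = []
        for t in tables:
            sub = t[t["set_name"].isin(common)]
            meds.append(sub[["bmdl", "bmd", "bmdu"]].median())
        avg = pd.concat(meds, axis=1).mean(axis=1)  # arithmetic mean of medians
        return PodEstimate(strategy,
                           "mean of per-dataset medians over common pathways",
                           float(avg["bmdl"]), float(avg["bmd"]),
                           float(avg["bmdu"]), len(common))
    raise KeyError(f"unknown strategy {strategy!r}; known: {STRATEGIES}")


def concordance_report(
    estimates: list[PodEstimate], apical_interval: tuple[float, float],
) -> pd.DataFrame:
    """Classify each POD estimate against the apical BMDL-BMDU interval.

    Closed-interval convention: an estimate exactly touching a bound still
    "spans"; "above" means its lower bound exceeds the apical upper bound,
    "below" the mirror case.
    """
    lo, hi = apical_interval
    if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo <= hi):
        raise ValueError("degenerate apical interval")
    rows = []
    for e in estimates:
        if e.bmdl > hi:
            cls = "above"
        elif e.bmdu < lo:
            cls = "below"
        else:
            cls = "spans"
        rows.append((e.strategy, e.bmdl, e.bmd, e.bmdu, e.n_items, cls))
    return pd.DataFrame(rows, columns=["strategy", "bmdl", "bmd", "bmdu",
                                       "n_items", "vs_apical"])
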