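#!/usr/bin/env python
"""Per-gene benchmark-dose modeling of the synthetic study.

Prefilters on raw counts, fits the model battery per gene, selects the
best model hierarchically, computes BMD_t at 1.349 residual SD with
profile bounds, applies the four-rule filter cascade, and measures
parameter recovery against the generator's truth.  Writes
results/gene_bmd.tsv.  Requires 01_simulate_study.py to have run.
"""

from pathlib import Path

import pandas as pd
from scipy import stats

from tgxpod import genebmd, io
from tgxpod.qc import _linear_fc

BASE = Path(__file__).resolve().parents[1] / "results"
SYN = BASE / "synthetic"


def main() -> None:
    matrix = io.read_expression(SYN / "expression.tsv", SYN / "samples.tsv",
                                SYN / "raw_counts.tsv")
    deg = io.read_deg_table(SYN / "deg_table.tsv")
    truth = pd.read_csv(SYN / "truth.tsv", sep="\t")
    max_fc = _linear_fc(deg).abs().groupby(deg["gene"]).max()
    table = genebmd.gene_bmd_table(matrix, max_fc)
    table.to_csv(BASE / "gene_bmd.tsv", sep="\t", index=False)

    surv = table[table["survives"]].set_index("gene")
    tr = truth.set_index("gene")
    joined = surv.join(tr[["responsive", "true_bmd"]])
    frac_resp = joined["responsive"].mean()
    both = joined[joined["responsive"]].dropna(subset=["true_bmd"])
    rho = stats.spearmanr(both["bmd"], both["true_bmd"]).statistic
    print(f"{len(table)} genes fit; {len(surv)} survive the filter cascade")
    print(f"{100 * frac_resp:.1f}% of survivors are truly responsive; "
          f"rank correlation of recovered vs true BMD: {rho:.3f}")
    print(f"wrote {BASE / 'gene_bmd.tsv'}")


if __name__ == "__main__":
    main()
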