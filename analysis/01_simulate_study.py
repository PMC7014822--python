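#!/usr/bin/env python
"""Generate the synthetic dose-response study used by the later steps.

Emulates the 28-day design (doses 0/300/500/750/1000/1500 mkd, n = 6):
2000 genes of which 10% respond along Hill-shaped log2 curves, plus the
stand-in differential-expression table.  Writes everything, including the
analytic truth table, under results/synthetic/.
"""

from pathlib import Path

from tgxpod import io, synth

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 17


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design = synth.StudyDesign(seed=SEED)
    matrix, truth = synth.simulate_expression_study(
        design, n_genes=2000, responsive_fraction=0.10)
    deg = synth.make_deg_table(matrix)
    io.write_expression(matrix, OUT / "expression.tsv", OUT / "samples.tsv",
                        OUT / "raw_counts.tsv")
    io.write_deg_table(deg, OUT / "deg_table.tsv")
    truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)
    n_resp = int(truth["responsive"].sum())
    print(f"simulated {len(matrix.genes)} genes x {matrix.doses.size} samples "
          f"(seed {SEED}); {n_resp} truly responsive genes")
    print(f"wrote expression, raw counts, DE table and truth to {OUT}")


if __name__ == "__main__":
    main()
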