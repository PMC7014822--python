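#!/usr/bin/env python
"""DEG-count D1/D1* point of departure.

Two demonstrations: (a) the synthetic study's DE table, counting DEGs at
fold-change thresholds feasible for its modest effect sizes; (b) the
study's printed per-dose DEG counts (females day 29, 1.5-fold criterion)
taken directly as a count curve.  Writes results/d1star.json.
Requires step 01 for part (a).
"""

import json
from pathlib import Path

from tgxpod import d1, fixtures, io

BASE = Path(__file__).resolve().parents[1] / "results"
SYN = BASE / "synthetic"
SEED = 17


def main() -> None:
    payload = {}

    deg = io.read_deg_table(SYN / "deg_table.tsv")
    synth_results = []
    for k in (1.2, 1.5, 2.0):
        try:
            curves = d1.count_degs_by_threshold(deg, [k])
            fit = d1.fit_hill_count(curves[float(k)])
            d1_hat = d1.compute_d1(fit)
            star = d1.bootstrap_d1star(fit, n_sim=10000, seed=SEED)
            synth_results.append({"k": k, "counts": list(curves[float(k)].counts),
                                  "d50": round(fit.d50, 1), "n": round(fit.n, 3),
                                  "d1": round(d1_hat, 2), "d1_star": round(star, 2)})
            print(f"synthetic K={k}: counts {curves[float(k)].counts.astype(int)}"
                  f"  D1 {d1_hat:8.2f}  D1* {star:8.2f}")
        except (ValueError, RuntimeError) as exc:
            print(f"synthetic K={k}: {exc}")
    payload["synthetic"] = synth_results

    # printed per-dose DEG counts, females day 29, up+down, 1.5-fold
    counts = fixtures.deg_count_table()
    sub = counts[(counts.experiment == "B") & (counts.series == "females_d29")]
    per_dose = sub.groupby("dose")["count"].sum().sort_index()
    curve = d1.DegCountCurve(1.5, per_dose.index.to_numpy(float),
                             per_dose.to_numpy(float))
    # the top-dose count (1680) exceeds the canonical 1000-gene plateau,
    # which suits the stricter K >= 2 curves; use a plateau above the
    # observed maximum for this 1.5-fold demonstration
    fit = d1.fit_hill_count(curve, plateau=2000.0)
    d1_hat = d1.compute_d1(fit)
    star = d1.bootstrap_d1star(fit, n_sim=10000, seed=SEED)
    payload["printed_females_d29"] = {
        "k": 1.5, "counts": list(per_dose), "d50": round(fit.d50, 1),
        "n": round(fit.n, 3), "d1": round(d1_hat, 2), "d1_star": round(star, 2)}
    print(f"printed counts (females d29, 1.5-fold): {list(per_dose)}")
    print(f"  d50 {fit.d50:.1f}, n {fit.n:.2f} -> D1 {d1_hat:.1f}, D1* {star:.1f}")

    (BASE / "d1star.json").write_text(json.dumps(payload, indent=2))
    print(f"wrote {BASE / 'd1star.json'}")


if __name__ == "__main__":
    main()
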