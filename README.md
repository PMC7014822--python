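# tgxpod

Benchmark-dose points of departure (PODs) from toxicogenomic dose-response
studies.

In chemical risk assessment, a POD is the dose used as the reference point
for deriving acceptable exposure levels — typically the lower bound (BMDL)
of a benchmark dose (BMD), the dose producing a stated benchmark response
(BMR). Short-term transcriptomic studies are increasingly used to estimate
PODs without waiting for chronic bioassays. This package implements, end
to end, the inference stack such an assessment needs:

- **Apical BMD modeling** (`tgxpod.apical`): continuous endpoints (cell
  proliferation, clinical chemistry) fit with the EFSA/PROAST exponential
  `y = a[c − (c−1)e^(−bx^d)]` and Hill `y = a[1 + (c−1)x^d/(b^d+x^d)]`
  families under a lognormal likelihood, a combined sex×time "study"
  covariate, BMR = 10%, and profile-likelihood BMDL₁₀/BMDU₁₀ (90% CI);
  the reported interval is the min/max over the two families.
- **Per-gene transcriptomic BMD** (`tgxpod.genebmd`): linear, polynomial,
  power, Hill and exponential fits per gene, hierarchical best-model
  selection, BMD_t at a BMR of 1.349 residual SD with 95% profile bounds,
  and the four-rule filter cascade (fit p > 0.1, BMDU/BMDL < 40,
  BMD ≤ highest dose, |fold change| ≥ 1.5).
- **POD aggregation** (`tgxpod.pod`): Fisher-exact gene-set enrichment
  (p ≤ 0.1, ≥ 10 genes) and nine pathway-agnostic/pathway-based strategies
  turning per-gene BMDs into a transcriptional POD, with concordance
  classification against the apical interval.
- **D1/D1\* DEG-count POD** (`tgxpod.d1`): the count of K-fold DEGs per
  dose fit with `Count = 1000/[1 + (d50/Dose)^n]` by Poisson-weighted
  IRLS; D1 = `d50·999^(−1/n)` is the dose predicting a single DEG and D1*
  its one-tailed 95% parametric-bootstrap lower bound (10,000 draws).
- **Gate statistics** (`tgxpod.qc`): Grubbs outlier and Bartlett
  variance-homogeneity tests, DEG thresholding (|FC| ≥ 1.5 & FDR ≤ 0.05,
  relaxed 1.4/0.1), cross-dataset overlap, fold-change histograms.
- **Synthetic studies with known truth** (`tgxpod.synth`): the 6-dose,
  n = 6 design with Hill-shaped responsive genes whose benchmark doses are
  analytic, so recovery is measurable exactly.

The package bundles machine-readable copies of the source study's printed
group-summary tables (hepatic Ki67 labeling index, plasma AST/ALT/total
bilirubin, per-dose DEG counts) so the apical analyses run with no
download.

## Worked example

Apical BMD for the bundled Ki67 labeling-index summaries (three
experiment-B series as covariate levels, outlier-adjusted, dispersions
read as SD):

```python
from tgxpod import apical, fixtures

table = fixtures.ki67_covariate_series()
pod = apical.apical_pod(table[["series", "dose", "n", "mean", "sd"]])
print(f"BMDL10 {pod.bmdl:.1f}  BMDU10 {pod.bmdu:.1f}  ratio {pod.ratio:.2f}")
```

prints

```
BMDL10 207.2  BMDU10 494.2  ratio 2.39
```

i.e. a 10% increase in Ki67 labeling over background is estimated between
207 and 494 mg/kg/day (90% CI, lowest/highest over the exponential and
Hill families); the interval spans a factor of 2.4. The same call on
`fixtures.alt_covariate_series()` gives `BMDL10 356.0  BMDU10 1091.6`
for plasma ALT (here the potency carries the covariate, so the range is
over families and covariate levels).

The numbered scripts under `analysis/` run the full narrative on a
synthetic study (generate → apical BMD → per-gene BMD → aggregation →
D1*), writing tables to `results/`:

```sh
python analysis/01_simulate_study.py
python analysis/02_apical_bmd.py
python analysis/03_gene_bmd.py
python analysis/04_pod_strategies.py
python analysis/05_d1star.py
```

Step 03, for example, reports that 156 of 2000 genes survive the filter
cascade, all of them truly responsive, with a rank correlation of 0.86
between recovered and generating BMDs. A `tgxpod` CLI
(`simulate`, `apical-bmd`, `gene-bmd`, `aggregate-pod`, `d1star`,
`deg-filter`, `report`) wraps the same functions for shell use.

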