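# bloodpanel

Blood-transcriptome biomarker panels for discriminating viral from
bacterial infection, built on cross-dataset dysregulation frequency.

Whole-blood gene expression carries a strong, reproducible immune
signature: viral infections converge on interferon-stimulated genes
(e.g. *IFI27*, *IFI44L*, *ISG15*), while bacterial infections elevate a
different set of host-response genes (e.g. *HP*, *ANXA3*, *ARG1*).
`bloodpanel` implements, as a tested and reusable pipeline, a
frequency-based approach to finding and using such panels: instead of
fitting a classifier to one cohort, genes are ranked by *how many
independent case/control datasets* show them fold-change-dysregulated,
making the resulting 10-gene virus-response (VRG) and 10-gene
bacteria-response (BRG) panels robust to cohort-specific noise.

It is aimed at computational biologists working with GEO-style expression
matrices (microarray or normalized RNA-seq) who want a transparent,
fold-change-based alternative to black-box signatures — plus a synthetic
cohort generator with planted ground truth so every stage of the pipeline
can be validated end to end.

## The method

For each case/control dataset (rows = probes/genes, columns = samples,
log2 intensities):

1. **QC** — drop probes with > 50 % bad entries (missing or below the
   intensity floor log2(100)), floor the survivors at log2(100), and
   average probes per gene on the log2 scale.
2. **Differential expression** — per-gene median fold change
   FC = 2^(median(case) − median(control)), with two-sample rank-product
   statistics (geometric mean of per-comparison ranks; permutation-based
   pfp) for ranking. A gene is called dysregulated when FC > 2.0 or
   FC < 0.5 (lenient preset: 1.5 / 0.7).
3. **Panel selection** — across N datasets, candidates are genes
   dysregulated in ≥ 8; VRGs are the top 10 candidates by mean FC over
   the viral datasets; BRGs combine mean-FC > 8 in the bacterial
   datasets, a ≥ 13-dataset frequency rescue, and a mid-FC (5–8,
   ≥ 10 datasets) rule, with explicit include/exclude overrides.
4. **Scoring** — each sample's per-gene fold change against the
   control-group median gives the counts NG_V and NG_B of panel genes
   with FC > 2; the pair (NG_V, NG_B) is the discrimination feature.
5. **Classification** — 2-cluster K-means on (NG_V, NG_B) separates
   viral- from bacterial-pattern samples; single genes support a
   univariate logistic model F(x) = 1/(1 + e^−(a0 + a1·x)) and plain
   fold-threshold rules. Performance is reported as precision
   TP/(TP+FP), recall TP/(TP+FN) and F1 = 2·TP/(2·TP+FP+FN).
6. **Networks, covariates, monitoring** — Pearson co-expression networks
   (edge iff PCC > 0.50), sex-stratified fold changes and age
   correlations, and longitudinal fold-vs-baseline tracking of the
   20-gene panel with event flagging for personal health monitoring.

## Worked example

Recover planted panels from a synthetic 20-cohort discovery study (4
viral, 4 bacterial, 12 mixed cohorts, 20 cases vs 20 controls each), then
discriminate an independent mixed cohort:

```python
from bloodpanel.simulate import (paper_scale_study, generate_study,
                                 generate_discrimination_cohort)
from bloodpanel.pipeline import panel_from_cohorts, discriminate_cohort
from bloodpanel.classify import confusion_metrics

design = paper_scale_study(master_seed=42)
cohorts = generate_study(design)
panel = panel_from_cohorts(cohorts, design.viral_cohorts,
                           design.bacterial_cohorts)
print("VRG panel:", ", ".join(panel.vrg))

expr, meta, val_panel = generate_discrimination_cohort(seed=42)
fit, scores = discriminate_cohort(expr, meta, val_panel, seed=42)
truth = meta.loc[fit.labels.index, "class_label"]
m = confusion_metrics(fit.labels.to_numpy(), truth.to_numpy(), "viral")
print(m.to_dict(ndigits=2))
```

Output:

```
VRG panel: VRG07, VRG03, VRG10, VRG06, VRG04, VRG02, VRG01, VRG05, VRG09, VRG08
{'tp': 40, 'fn': 0, 'fp': 0, 'tn': 40, 'precision': 1.0, 'recall': 1.0, 'f1': 1.0}
```

All 10 planted virus-response genes are recovered (ordered by their mean
fold change in the viral cohorts), and K-means on the (NG_V, NG_B) score
vectors separates the 40 viral from the 40 bacterial cases perfectly —
at the planted effect sizes (mean panel FC ≈ 5–17) the two score clouds
barely overlap. Real cohorts are noisier; the acceptance suite pins the
expected behaviour (≥ 9/10 panel recovery in ≥ 90 % of seeds, median
F1 ≥ 0.95).

A command-line interface covers the same stages
(`bloodpanel de | select-panel | score | discriminate | single-gene |
network | covariates | monitor | simulate`); run `bloodpanel --help`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the main computation from scratch — synthetic discovery study,
probe QC, fold changes, panel selection, validation-cohort scoring and
K-means discrimination, and the longitudinal monitoring round trip —
logging progress to stderr and writing the results JSON to `--out`.
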