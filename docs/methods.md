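# Methods

This note documents the statistical procedures implemented in
`bloodpanel`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical decisions made
where the underlying method left room.

## Quality control

Input intensities are log2-transformed at read time. A probe is removed
when the fraction of its entries that are *bad* — missing or below the
intensity floor — strictly exceeds `max_missing_fraction` (default 0.5).
The two defect types are pooled into a single bad-entry fraction: this is
the most literal reading of the filtering rule, and it is monotone in
both defect types (adding a missing or a sub-floor entry can only push a
probe toward removal). Surviving values below the floor are set to the
floor (`log2(100)` by default, the conventional background level of
two-colour and single-channel arrays); flooring is applied before
probe-to-gene aggregation, so the gene-level mean never averages
background noise with signal. Aggregation is the arithmetic mean of a
gene's probes on the log2 scale, skipping missing entries; a gene-level
entry is missing only when all of its probes are. Probes annotated to
several genes contribute to each (keeping aggregation a simple masked
mean); users who consider multi-mapping probes unreliable should filter
the probe map beforehand. Only explicitly missing entries count as
missing — platform absent/flagged calls are not interpreted.

## Differential expression

Fold changes are median-based: FC = 2^(median case − median control) on
the log2 scale. The median damps samples far from the group centre,
which matters in blood cohorts with occasional extreme responders; the
generator's optional heavy-tail contamination exists to exercise exactly
this property.

The rank product is the two-sample pairwise variant: every case is
compared with every control (all pairs, or a seeded uniform subsample of
`max_pairs`, default 200, when the product is larger); within each
comparison genes are ranked by log-ratio, descending for the
up-statistic (rank 1 = most up-regulated) and ascending for the
down-statistic; RP is the geometric mean of a gene's ranks. Ties take
average ranks. Significance is estimated by the standard resampling
scheme: each of `n_perm` (default 100) permutations shuffles the gene
labels within each comparison independently, giving a null RP
distribution; the pfp (proportion of false predictions, an FDR-like
quantity) for gene *g* is the expected number of null RP values at or
below RP(g), divided by g's position in the observed RP ordering, and
clamped to [0, 1]. Defaults (100 permutations, 200 pairs) bound the cost
at roughly a second for a 20k-gene, 20v20 dataset.

DEG calls use strict inequalities at the cutoffs (a gene at exactly
FC = 2.0 is not called), with a stringent preset (2.0 / 0.5) and a
lenient one (1.5 / 0.7). Downstream panel selection keys on the FC
cutoffs only; rank-product statistics are computed and reported for
ordering but no pfp threshold is imposed. No normalization is applied
beyond the QC steps above.

## Panel selection

Per-gene dysregulation counts are taken over the per-dataset FC tables
(a gene absent from a dataset contributes nothing there; each dataset
contributes one direction, so n_up + n_down = n_significant). Candidates
are genes significant in at least `min_datasets` (default 8). VRGs are
the top `n_viral_top` (default 10) candidates by arithmetic mean linear
FC over the viral datasets. BRGs are the union of three rules —
(a) bacterial mean FC > 8.0, (b) significant in ≥ 13 datasets,
(c) bacterial mean FC in the closed interval [5, 8] *and* significant in
≥ 10 datasets — with explicit include/exclude overrides applied last
(the historical panel involved one manual substitution, which these
overrides reproduce as configuration rather than hard-coded logic), then
truncated or padded to 10 by bacterial mean FC. Down-regulated genes
stay in the frequency table but never enter panels. The two panels are
kept disjoint with viral precedence: a gene qualifying for both goes to
the VRG list and the BRG list is filled from the remaining pool.

Tie-breaking in every ranking is mean FC, then dysregulation count, then
alphabetical gene symbol — deterministic, and stated here because the
method itself specifies no rule.

The disease-specific screen inverts the logic: genes significant in
*every* target dataset and significant in at most `max_background_count`
of the remaining datasets.

## Scoring and classification

The FC matrix expresses each sample against the per-gene median of the
control group, on the QC'd, floored log2 scale (flooring first matters
at the boundary). NG_V and NG_B count panel genes with FC strictly
above the threshold (default 2.0). When a platform lacks panel genes the
score table carries the effective panel sizes so consumers can
normalize; the counts themselves are left raw. For datasets without
healthy controls, `relative_expression` provides the housekeeping-gene
alternative (2^(target − reference), e.g. against *B2M*).

K-means (k = 2) clusters the raw (NG_V, NG_B) vectors — both axes share
the same 0–10 unit, so no standardization is applied. For n ≤ 10 samples
the minimum within-cluster sum of squares partition is found exactly by
enumerating all 2-partitions (Lloyd's algorithm with random restarts
cannot guarantee the global optimum, and at this size enumeration is
cheaper than restarting); larger inputs use Lloyd's algorithm with 10
seeded restarts. Ties in the exact search keep the first optimum in
enumeration order. The cluster whose centroid has the larger
NG_V − NG_B is labelled the viral-pattern class. Clustering all-identical
score vectors is an error, not a silent degenerate answer.

The single-gene logistic model F(x) = 1/(1 + e^−(a0 + a1 x)) is fitted
by penalized maximum likelihood with a weak ridge (1e-4) on the slope,
which leaves non-separable fits numerically at the ML solution while
guaranteeing finite coefficients on separable data. The feature is the
linear fold change by default; a log2 option is recorded in the model so
prediction applies the same transform. The decision threshold is 0.5
unless configured. Precision, recall and F1 follow the standard count
formulas with degenerate denominators mapped to 0; rounding happens only
at presentation (2 decimals).

Fold-threshold classification is strict (positive iff FC > threshold);
paired treatment response is boundary-inclusive (responder iff
pre − post ≥ log2(fold_reduction)).

## Networks and covariates

Co-expression uses pairwise-complete Pearson correlation; zero-variance
genes yield undefined (missing) correlations. Edges require *signed*
PCC strictly above the cutoff (default 0.50) — the intended use is
retaining strong positive co-expression among up-regulated response
genes, and negative correlations carry no meaning in that reading.
Connected components are reported descriptively (union-find via
networkx); no community detection is applied.

Sex effects are assessed by computing the median FC within each sex
stratum and reporting the max/min ratio, flagged above 1.4 — the
conventional reporting threshold for a between-sex difference in this
setting. Age effects are per-gene Pearson correlations of log2
expression with age (invariant to affine rescaling of age units).

## Monitoring

The longitudinal profile fixes a per-gene baseline as the median over
user-designated healthy timepoints (a reference is required to convert
plotted expression into fold changes; "all timepoints outside annotated
events" is the sensible default designation) and flags a timepoint when
at least `min_genes` (default 3) genes of either panel exceed
`fold_threshold` (default 2.0). This is an explicit operational stand-in
for reading events off a longitudinal plot; it makes no claim of
equivalence to any published event annotation. Inputs are
already-normalized expression values; RNA-seq count processing is out of
scope.

## Synthetic data

`CohortSpec`/`generate_cohort` emulate a case/control blood cohort:
per-gene log2 baselines uniform on (7, 12) (a lognormal intensity
population comfortably above the log2(100) ≈ 6.64 floor), i.i.d.
Gaussian log2 noise per sample (default sd 0.5; 0.7 in the discovery
study, matching the noisier end of real cohorts), optional heavy-tail
contamination, additive log2(FC) case effects on planted genes, latent
single-factor co-expression blocks (one VRG-like, one BRG-like,
mimicking the two observed sub-networks), probe replication with
per-probe offsets (sd 0.25) and noise (sd 0.1), and injected missing
(default 1 % in the study) and sub-floor values (drawn uniform below the
floor) so the QC path is genuinely exercised. The `baseline_sd` field
adds optional gene-level jitter on top of the uniform baseline range;
default 0 because the range already spreads gene means.

`paper_scale_study` is the stated discovery world: 20 cohorts of
20 cases vs 20 controls over 1000 genes — 4 viral cohorts planting the
10 VRGs with per-cohort mean FC uniform in [4.97, 17.42], 4 bacterial
cohorts planting the 10 BRGs in [4.90, 15.91] (the documented per-panel
mean-FC ranges), and 12 mixed cohorts alternately re-using one panel at
moderate FC, uniform in [3, 8] — consistent with the moderate-to-strong
panel up-regulation seen in the non-infection diseases that motivated
the frequency criterion. Per-gene FCs scatter around the cohort mean by
0.2 on the log2 scale. All randomness flows from one master seed through
numpy's PCG64 generator (fixed by construction, not environment), so
identical specs are bit-reproducible.

Longitudinal series use per-gene AR(1) baselines (stationary sd 0.3,
autocorrelation 0.6 — slow physiological drift plus assay noise) with
multiplicative events on one panel per window; overlapping windows on
the same panel are rejected.

What the generator does **not** emulate: platform-specific probe
behaviour, batch effects, cell-composition shifts, and correlated
missingness. A green recovery test therefore establishes that the
selection and scoring logic is correct under the assumed statistical
structure — not that the panels would replicate on any particular real
platform.

## Numerical choices and degenerate inputs

- Strict inequalities at every FC/count threshold; boundary-inclusive
  only for paired treatment response (documented above).
- Missing values are NaN throughout; statistics are masked (median,
  mean, pairwise-complete correlation).
- Even-sized control groups make the control-median of the FC matrix
  only approximately 1 (the even-count median interpolates on the log
  scale); it is exactly 1 for odd control counts.
- Empty case or control groups, all-identical clustering inputs,
  one-class logistic training sets, constant age vectors, and all-probes
  -removed QC are errors, not warnings.
- Genes entirely missing in a group get NaN fold change and are excluded
  downstream; panel genes absent from a platform are dropped with a
  warning and reflected in the effective panel sizes.

## Known limitations

- The rank-product permutation null assumes mostly-complete data; pfp
  estimates degrade when many ratios are missing.
- Panel selection reproduces the published *procedure*; reproducing the
  published gene identities requires the original public datasets and is
  out of scope (the overrides mechanism exists so a known panel can be
  pinned as configuration).
- The K-means label map assumes the two clusters differ along
  NG_V − NG_B; cohorts mixing three or more response patterns need a
  different model.
- Monitoring event flags are a fixed-threshold rule, not a changepoint
  statistic.
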