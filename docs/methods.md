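# Methods

This note documents the statistical procedures the package implements,
the choices made where the procedures were underdetermined, what the
synthetic cohort generator does and does not emulate, and known
limitations.

## Data model

Three matched layers per cohort: an LFQ intensity matrix (proteome,
genes × samples; 0 encodes non-detection), a TPM matrix (transcriptome)
and a media-LFQ matrix (conditioned-media secretome, TU and TAM only).
Samples are annotated with patient, cell type (TU / TAM / TAT) and assay.
Gene identifiers are opaque strings; no identifier translation is
performed, so callers must supply consistent symbols across layers.
Protein groups matching several gene annotations are expanded to one row
per member gene (flagged, so amplified families can be dropped from
enrichment-style summaries); when duplication puts a gene into several
rows, downstream matrix construction keeps the first occurrence and logs
the collision.

## Imputation

Missing LFQ values are replaced by `v_min * (1 + eps)`,
`eps ~ N(0, rel_sd)` with `rel_sd = 0.59` (the overall relative standard
deviation across protein groups in the data the default mirrors) and
`v_min` the minimum nonzero intensity of the matrix (per-sample scope
available via `vmin_scope="per_sample"`). Draws are i.i.d. per entry and
deterministic given the seed; detected values are never altered.

By default the Gaussian is *not* truncated, so the imputed distribution
has mean `v_min` and relative SD exactly `rel_sd`; at `rel_sd = 0.59`
about 4.5% of draws are nonpositive. Any positivity truncation at this
noise level visibly distorts the stated distribution: resampling at
`eps > -1` shifts the mean by +5.9% and compresses the relative SD to
≈ 0.50. Callers whose downstream steps take logs or medians of
intensities (as the pipeline does) should use `truncate="resample"`,
which guarantees strictly positive values and is what `run-all` uses;
the distributional cost is documented rather than hidden.

## Concordance and detection deficits

Per-gene concordance is the Spearman correlation between LFQ and TPM
across matched samples (midranks for ties; two-sided p from the usual
t approximation). Genes with zero variance in either layer are reported
as undefined and excluded from the summary (median ρ, sign fractions).

Detection curves threshold genes by a per-gene mRNA summary (median TPM
across the relevant samples) on a grid of 25 log-spaced thresholds over
the observed range and report, at each threshold, the number of genes
remaining, the number with any protein-group evidence, and the detected
fraction.

The detection-deficit p-value draws `n_draws` random gene subsets of the
query's size from the universe (without replacement). A subset counts as
"equal or better" than the query when, over the thresholds at which the
query retains at least `min_remaining = 20` genes, it has strictly more
missing proteins at some threshold, or exactly as many at every
threshold; p is the fraction of such subsets. Two properties of this
published procedure matter for interpretation:

* it is a *global curve-wise* comparison, not a scalar exceedance test.
  Under the null a typical random subset beats a typical query somewhere
  along the grid, so null p-values pile up near 1. The test is therefore
  conservative — its nominal size is far below the usual α — and a small
  p indicates a deficit that holds across the whole expression range;
* tie handling is not cosmetic. If single-threshold ties counted
  ("ties" mode, available as an option), any valid threshold where the
  query happens to have zero missing proteins would let every draw beat
  and force p = 1. The default strict rule avoids this degeneracy; the
  everywhere-tie branch keeps p = 1 for the query-equals-universe edge
  case, where every draw reproduces the query curve.

Power is limited by the highest valid thresholds, where only
~`min_remaining` query genes survive and counting noise lets occasional
draws exceed the query even under a genuine deficit; with a 4-fold
detection-odds deficit on a 200-gene class in a 4000-gene universe the
test yields p ≤ 0.01 in roughly half of replicates under the generator's
detection model. Larger query classes, larger `min_remaining`, or grids
that stop before the sparse tail all raise power.

## Expression calls

* Protein expressed: per-cell-type median LFQ strictly above the
  linear-interpolation sample quantile (default 0.25) of all values of
  the combined matrix. The quantile definition is a choice; only the
  resulting threshold (50e6 in the motivating cohort) is fixed by the
  procedure being mirrored.
* Cell-type selective: median LFQ > 5e7 in the cell type and at most
  5-fold higher in each other cell type — the fold guard keeps
  cross-contamination between sorted fractions from mimicking
  expression.
* RNA expressed: per-cell-type median TPM ≥ 2 (0.3 for the permissive
  secreted-factor overlap). Tiers use strict thresholds on the median
  (> 50 high, > 10 intermediate, > 2 low); below that, a gene is
  "sporadic" if TPM > 3 in more than zero but fewer than 10% of samples,
  else "none". Tier assignment is monotone in the median.
* Media detection: nonzero in at least half of the producing cell
  type's media samples; the "most abundant" table additionally requires
  the gene's median to exceed the median of all genes' medians in that
  cell type, and never compares intensities across cell types (media
  lack a shared normalizer).
* Differential test: statistic is the difference of group means of
  log(LFQ + 1); labels are permuted exhaustively when at most `iters`
  distinct splits exist, otherwise `iters` sampled splits with the
  add-one estimate (c + 1)/(B + 1) so p is never zero and type-I error
  stays controlled. Fold change is the ratio of group medians of raw
  LFQ (larger over smaller); hits need BH q < 0.05 and fold ≥ 2. Both
  the log-for-test and raw-for-fold choices are switchable at the call
  sites that need otherwise.

## Interaction map

A ligand–receptor group is mapped when ≥ 1 ligand and ≥ 1 receptor are
expressed (tier ≠ none) in ≥ 1 cell type; edges are enumerated per
expressed (ligand, receptor) pair, carrying the expressing cell types
with tiers on both sides. Sporadic expression counts toward mapping but
flags the edge (the "open square" convention in the field's figures).
Lipid-modality groups put mediator-synthesizing enzymes on the ligand
side, standing in for the mediator itself. The per-group "main target"
is the cell type with the unique highest receptor tier (ties reported as
"All"); this unique-max rule is an interpretation and is labeled as such
in the output.

## Outcome-surrogate coexpression

The bTAM score — the poor-prognosis macrophage axis — is the mean of the
rank-transformed CD163 and MRC1 TPM across TAM samples. Rank averaging
(rather than averaging raw TPM, available as an option) makes the
combined score invariant to the markers' scales and keeps the downstream
Spearman screens well defined. Candidate genes are screened against the
score within TAM (hits at ρ > 0.5 / ρ < −0.6) or across patient-matched
TU–TAM pairs (±0.7), with significance stars at p < 0.05 / 0.01 / 0.001
/ 0.0001.

Surrogate grouping: genes with survival z-scores |z| > 4 present in the
TU proteome seed groups; seeds must correlate with their own mRNA at
ρ > 0.3; each seed's LFQ profile is min–max scaled to [0, 1] (strictly
monotone, hence a no-op for Spearman, performed and exported to mirror
the stated procedure) and its neighborhood is every proteome gene with
ρ > 0.95 against it, the seed included in the count; neighborhoods with
≥ 8 members are retained and overlapping retained neighborhoods are
merged by connected components. Both the pre-merge per-seed groups and
the merged groups are emitted, because the grouping operator could also
be read as one-group-per-seed.

## Synthetic cohorts

The generator emulates the data structure the pipeline assumes, with
defaults of 24 patients × 6000 genes × 3 cell types (every stage runs in
well under two minutes on one CPU at this scale):

* log-TPM per gene and sample from a log-normal gene baseline
  (ln-mean 0.5, ln-SD 1.8) plus per-sample noise (SD 0.8); 50 selective
  markers per cell type boosted 8–30-fold in their own type; the five
  epithelial tumor markers get strong TU boosts with large patient
  variability, so tumor-marker sums span a realistic range.
* log-LFQ via a Gaussian copula on the per-sample noise: the latent
  correlation is `r = 2 sin(pi * rho_S / 6)` so the population Spearman
  between a gene's TPM and LFQ equals `target_concordance_rho` (0.5 by
  default) in closed form.
* protein detection: per-gene Bernoulli with logistic probability in
  median log-TPM (midpoint TPM = 1, scale 1.1), shifted by additive
  class offsets (secreted, membrane receptor, growth factor each +0.6,
  so growth factors — which are also secreted — sit 1.2 units deeper).
  At TPM ≈ 1 roughly half of unflagged genes but only a quarter of
  growth factors are detected. Detected genes additionally lose
  individual samples at rate 0.3·(1 − p_detect) to exercise imputation;
  undetected genes are all-zero rows.
* a latent per-patient score u ~ N(0, 1) drives CD163/MRC1 in TAM
  (slope 1.2, noise SD 0.15) and planted ligand sets (13 positive, 28
  negative by default) at slope ±1.16, chosen so the planted population
  Spearman against the combined marker score is ≈ 0.8 given the
  sample-noise SD of 0.8; TU-side secreted sets (41 positive, 6
  negative) use the same slope for the matched-pair screen.
* surrogate blocks (sizes 10, 10, 7 by default) are scaled copies of a
  latent per-patient profile with configurable noise, mirrored into the
  TU transcriptome and tagged with z = ±5 in the z-score table, plus
  five decoy seeds with z = 4.5 and no block structure.
* contamination: three TAT samples receive `contamination_spike` (0.2)
  of the mean TU proteome profile, and one TAT plus one TAM receive
  5× that, emulating mildly and heavily contaminated sorts.
* media: secreted-flagged genes with independent presence noise
  (present with probability 0.8 if protein-detected, 0.35 otherwise),
  for the first five patients' TU and TAM.

Same seed, byte-identical cohort. What the generator does *not* emulate:
peptide-level structure of MS quantification, intensity-dependent
technical variance, batch effects, correlated gene programs beyond the
planted structures, tumor-contamination in the transcriptome, or
realistic gene-gene correlation of TPM. Tests passing on these cohorts
show the *procedures* behave as specified under their assumptions, not
that the assumptions hold in any particular real data set.

A small worked membership fixture (synthetic, generated in code) with
fixed three-set region sizes exercises the Venn/percentage arithmetic of
the secreted-factor overlap analysis end to end.

## Numerical choices and degenerate inputs

* Spearman uses midranks; constant vectors yield NaN and are excluded
  (summaries) or skipped with a log entry (screens).
* All published thresholds are applied strictly as printed ("> 50
  million", "TPM > 50"); RNA "expressed" uses ≥ for the minimum-TPM
  phrasing.
* Sampled permutation statistics pass through the same matrix-product
  path as the observed statistic, with a 1e-9 slack absorbing BLAS
  summation-order differences.
* Exhaustive enumeration of label splits includes the observed split,
  so exhaustive p ≥ 1/#splits by construction.
* The imputer refuses all-zero matrices (no v_min exists); the QC
  refuses cohorts without a TU reference; catalog construction refuses
  empty description tables and non-4 prediction-set counts.

## Limitations

* The detection-deficit test's conservativeness (above) means its
  p-values are not comparable to nominal α levels; they order classes by
  deficit strength rather than calibrate it.
* The receptor catalog's curated and CD-marker inputs are taken on
  trust; the description-mining rule is a heuristic with known false
  negatives (descriptions not containing "receptor").
* Expression calls depend on cohort-wide quantiles, so adding samples
  can change calls for untouched genes; this mirrors the procedure being
  implemented and is not corrected for.
* With few patients, the matched-pair screen at |ρ| > 0.7 has high
  variance; hit lists at n ≈ 10 pairs should be read as candidates, not
  detections.
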