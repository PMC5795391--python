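# asciteome

Cell-type-resolved proteotranscriptomic analysis of the ovarian-cancer
ascites microenvironment.

High-grade serous ovarian cancer spreads through the peritoneal fluid,
where tumor-cell spheroids (TU), tumor-associated macrophages (TAM) and
tumor-associated T cells (TAT) exchange growth factors, cytokines and
lipid mediators. Mapping this signaling network requires integrating two
imperfect readouts per sorted cell population: label-free-quantification
(LFQ) shotgun proteomics, which systematically under-detects secreted and
membrane proteins, and bulk RNA-seq (TPM), which sees those transcripts
but not the proteins. This package implements that integration as a
tested, reusable pipeline, exercised end-to-end on a synthetic cohort
generator that reproduces the statistical structure of such data.

## What it computes

* **Concordance** — per-gene Spearman ρ between LFQ and TPM across
  matched samples, with summary median and sign fractions.
* **Detection-deficit test** — detection curves (fraction of
  protein-detected genes among genes with median TPM ≥ t) and a
  permutation p-value asking whether a gene class (e.g. ligands) is
  missing from the proteome more than random same-size gene sets, at
  matched expression: a random subset is "equal or better" than the query
  class if it has strictly more missing proteins at some threshold (or
  ties everywhere) over thresholds where the query keeps ≥ 20 genes;
  p = (# equal-or-better subsets)/(# subsets drawn).
* **Missing-value imputation** — LFQ zeros replaced by
  v_min·(1 + ε), ε ~ N(0, 0.59), v_min the minimum nonzero intensity.
* **QC** — tumor contamination scored as Σ LFQ(EPCAM, PAX8, MSLN,
  MUC16, ITGB4) against the range of TU samples, with per-analysis
  exclusion lists.
* **Expression calls** — expressed (median LFQ > 0.25-quantile of the
  combined proteome), cell-type selective (median LFQ > 5·10⁷ and ≤
  5-fold higher elsewhere), RNA tiers (median TPM > 50 / > 10 / > 2,
  "sporadic" when TPM > 3 in < 10% of samples), conditioned-media
  detection (nonzero in ≥ 50% of media samples), three-set Venn
  partitions, and an unpaired permutation test on differences of mean
  log LFQ with BH-FDR < 0.05 and fold ≥ 2.
* **Catalogs** — receptome mined from gene descriptions ("receptor"
  minus 21 false-positive terms, plus curated and CD-marker lists),
  secretome as the 4-way intersection of secretion predictors, and
  ligand–receptor group tables (protein and lipid-mediator modalities).
* **Interaction map** — groups with both an expressed ligand and an
  expressed receptor become edges between producing and receiving cell
  types; remaining groups are classified ligand-only / receptor-only /
  orphan-expressed / silent.
* **Outcome-surrogate coexpression** — a per-patient bTAM score (mean
  rank of CD163 and MRC1 TPM in TAM) screened against ligand expression
  in TAM (hits at ρ > 0.5 / ρ < −0.6) and against TU expression across
  patient-matched pairs (|ρ| > 0.7), plus survival-z-score surrogate
  grouping (seeds with |z| > 4, protein–mRNA ρ > 0.3, neighborhoods at
  ρ > 0.95, groups kept at ≥ 8 members and merged on overlap).

## Worked example

```python
from asciteome import (CohortConfig, generate_cohort, gene_concordance,
                       surrogate_score, coexpress_with_surrogate)
from asciteome.preprocess import impute_missing_lfq, assess_tumor_contamination

cohort = generate_cohort(CohortConfig(seed=11))   # 24 patients x 6000 genes
reports = assess_tumor_contamination(cohort.proteome, cohort.annotation)
print("QC flags:", {r.sample_id: r.flag for r in reports if r.flag != "clean"})

imputed = impute_missing_lfq(cohort.proteome, seed=11, truncate="resample")
detected = (cohort.proteome.data > 0).any(axis=1)
res = gene_concordance(imputed.subset_genes(detected[detected].index),
                       cohort.transcriptome, cohort.pairing())
print(f"median mRNA-protein Spearman rho (detected genes): {res.median_rho:.2f}")

tam = cohort.transcriptome.subset_samples(
    cohort.annotation.samples_of("TAM", "transcriptome"))
score = surrogate_score(tam)
gf = sorted(cohort.catalog.genes_with("growth_factor_cytokine"))
hits, _ = coexpress_with_surrogate(tam, score, gf)
print(f"outcome-correlated ligands: "
      f"{sum(h.direction == 'positive' for h in hits)} positive, "
      f"{sum(h.direction == 'inverse' for h in hits)} inverse")
```

prints

```
QC flags: {'TAM24_P': 'contaminated', 'TAT01_P': 'low_contamination',
 'TAT02_P': 'low_contamination', 'TAT03_P': 'low_contamination',
 'TAT04_P': 'contaminated'}
median mRNA-protein Spearman rho (detected genes): 0.42
outcome-correlated ligands: 14 positive, 28 inverse
```

The generator spikes a TU profile into one TAM and four TAT samples, and
the QC recovers exactly the heavily contaminated samples (excluded from
everything) versus the mildly contaminated TAT samples (excluded only
from tumor-specificity calls). The recovered median ρ of 0.42 sits below
the population target of 0.5 because per-sample dropout and imputation
noise attenuate the per-gene correlations — the same mechanism that
motivates complementing proteomes with transcriptomes in the first
place. The coexpression screen recovers 14 positive / 28 inverse ligands
against 13 / 28 planted.

The same pipeline runs from a shell:

```sh
asciteome run-all --synthetic --seed 7 --out run7
```

which writes the cohort, all stage outputs (QC report, imputed matrix,
concordance and detection-deficit tables, call tables, Venn counts,
interaction edges, coexpression hit lists, surrogate groups) and a
manifest with input/output digests; reruns are byte-identical.

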