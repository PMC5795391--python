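"""Expressed / selective / tier calls and the unpaired permutation test.

Thresholds follow the study design they implement:

* protein "expressed": median LFQ above the 0.25 quantile of the combined
  proteome (50e6 in the original cohort);
* protein "cell-type selective": median LFQ > 50e6 AND at most 5-fold
  higher in any other cell type (guards against cross-contamination
  mimicking expression);
* mRNA "expressed": TPM >= 2 (0.3 for the permissive secretome overlap);
* mRNA tiers by median TPM: high > 50, intermediate > 10, low > 2,
  sporadic if the median is <= 2 but TPM > 3 in fewer than 10% of samples
  (and at least one);
* differential abundance: unpaired permutation test on the difference of
  group means of log LFQ, BH-FDR < 0.05 and at least 2-fold change.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from ._stats import bh_adjust
from .containers import CELL_TYPES, ExpressionMatrix, SampleAnnotation

log = logging.getLogger(__name__)

TIER_ORDER = ("none", "sporadic", "low", "intermediate", "high")
TIER_RANK = {t: i for i, t in enumerate(TIER_ORDER)}


@dataclass
class ExpressionCallSet:
    """Bundle of per gene x cell type call tables (boolean / tier labels)."""

    expressed_protein: pd.DataFrame | None = None
    selective_protein: pd.DataFrame | None = None
    expressed_rna: pd.DataFrame | None = None
    tier: pd.DataFrame | None = None
    media_detected: pd.DataFrame | None = None

    def validate(self) -> None:
        if self.tier is not None and self.expressed_rna is not None:
            common = self.tier.index.intersection(self.expressed_rna.index)
            for ct in self.tier.columns:
                if ct in self.expressed_rna.columns:
                    high = self.tier.loc[common, ct] == "high"
                    if (high & ~self.expressed_rna.loc[common, ct]).any():
                        raise ValueError("tier=high gene not called RNA-expressed")
        if self.selective_protein is not None and self.expressed_protein is not None:
            common = self.selective_protein.index.intersection(self.expressed_protein.index)
            cols = [c for c in self.selective_protein.columns
                    if c in self.expressed_protein.columns]
            sel = self.selective_protein.loc[common, cols]
            exp = self.expressed_protein.loc[common, cols]
            if (sel & ~exp).any().any():
                raise ValueError("selective call without expressed call")


def _celltype_groups(m: ExpressionMatrix, ann: SampleAnnotation) -> dict[str, list[str]]:
    ctype = ann.cell_type_of()
    groups: dict[str, list[str]] = {}
    for s in m.sample_ids:
        ct = ctype.get(s)
        if ct is not None:
            groups.setdefault(ct, []).append(s)
    return groups


def _celltype_medians(m: ExpressionMatrix, ann: SampleAnnotation) -> pd.DataFrame:
    groups = _celltype_groups(m, ann)
    return pd.DataFrame(
        {ct: m.data[samps].median(axis=1) for ct, samps in groups.items()}
    )


# ---------------------------------------------------------------------------
# protein calls
# ---------------------------------------------------------------------------

def call_expressed_protein(
    m: ExpressionMatrix,
    ann: SampleAnnotation,
    quantile: float = 0.25,
) -> tuple[pd.DataFrame, float]:
    """Expressed iff per-cell-type median LFQ > the combined-proteome quantile.

    The threshold is the linear-interpolation sample quantile of *all*
    values of the matrix (every gene, every sample, every cell type).
    Returns (boolean genes x cell-types table, threshold used).
    """
    groups = _celltype_groups(m, ann)
    empty = [ct for ct, s in groups.items() if not s]
    if not groups or empty:
        raise ValueError(f"empty cell-type group(s): {empty or 'no annotated samples'}")
    thr = float(np.quantile(m.values(), quantile))
    med = _celltype_medians(m, ann)
    return med.gt(thr), thr


def call_celltype_selective(
    m: ExpressionMatrix,
    ann: SampleAnnotation,
    lfq_min: float = 5e7,
    fold: float = 5.0,
) -> pd.DataFrame:
    """Expressed-in-c iff median_c > lfq_min and no other cell type exceeds
    fold x median_c (cross-contamination guard)."""
    med = _celltype_medians(m, ann)
    missing = [ct for ct in CELL_TYPES if ct not in med.columns]
    if missing:
        raise ValueError(f"selectivity rule needs all three cell types; missing {missing}")
    out = {}
    for ct in med.columns:
        others = [o for o in med.columns if o != ct]
        ok = med[ct] > lfq_min
        for o in others:
            ok &= med[o] <= fold * med[ct]
        out[ct] = ok
    return pd.DataFrame(out)


def venn_partition(calls: pd.DataFrame) -> dict[str, int]:
    """Counts of the 7 nonempty membership regions of a 3-set call table.

    Keys are '&'-joined column names (e.g. ``"TU&TAM"`` = expressed in TU
    and TAM but not TAT). Counts sum to the number of genes expressed in
    at least one set.
    """
    cols = list(calls.columns)
    if len(cols) != 3:
        raise ValueError(f"expected 3 call columns, got {cols}")
    out: dict[str, int] = {}
    b = calls.astype(bool)
    for r in range(1, 8):
        members = [cols[i] for i in range(3) if r >> i & 1]
        mask = pd.Series(True, index=calls.index)
        for i, c in enumerate(cols):
            mask &= b[c] if (r >> i & 1) else ~b[c]
        out["&".join(members)] = int(mask.sum())
    return out


# ---------------------------------------------------------------------------
# permutation fold-change test
# ---------------------------------------------------------------------------

@dataclass
class DifferentialResult:
    table: pd.DataFrame  # gene_id, fold_change, p, q, flagged
    exhaustive: bool
    n_permutations: int


def permutation_fold_change_test(
    m: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    iters: int = 100000,
    seed: int | np.random.Generator | None = None,
    fdr: float = 0.05,
    min_fold: float = 2.0,
    method: str = "auto",
    _chunk: int = 1024,
) -> DifferentialResult:
    """Unpaired permutation test of group differences, gene by gene.

    Statistic: difference of group means of log(LFQ + 1). Labels are
    permuted exhaustively when the number of distinct splits is <= iters,
    else ``iters`` random splits are drawn and the add-one estimate
    (c+1)/(iters+1) is reported. Fold change is the ratio of group medians
    of raw LFQ (reported as the larger-over-smaller ratio). A gene is
    flagged when BH q < ``fdr`` and fold >= ``min_fold``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    na, nb = len(group_a), len(group_b)
    cols = list(group_a) + list(group_b)
    x = m.data[cols].to_numpy()
    logx = np.log1p(x)
    n = na + nb

    if method not in ("auto", "exhaustive", "sampled"):
        raise ValueError(f"unknown method {method!r}")
    n_splits = math.comb(n, na)
    exhaustive = n_splits <= iters if method == "auto" else method == "exhaustive"
    if exhaustive:
        masks = np.zeros((n_splits, n))
        for i, idx in enumerate(combinations(range(n), na)):
            masks[i, list(idx)] = 1.0
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def stat_chunk(mask_rows: np.ndarray) -> np.ndarray:
        w = mask_rows / na - (1.0 - mask_rows) / nb  # +1/na on A, -1/nb on B
        return logx @ w.T

    # observed statistic through the same numerical path as the permutations
    obs_mask = np.zeros((1, n))
    obs_mask[0, :na] = 1.0
    obs = stat_chunk(obs_mask)[:, 0]

    count = np.zeros(x.shape[0], dtype=np.int64)
    abs_obs = np.abs(obs)[:, None]
    total = n_splits if exhaustive else iters
    done = 0
    while done < total:
        b = min(_chunk, total - done)
        if exhaustive:
            rows = masks[done:done + b]
        else:
            rows = np.zeros((b, n))
            for i in range(b):
                rows[i, rng.choice(n, size=na, replace=False)] = 1.0
        stats_ = stat_chunk(rows)
        # tiny slack absorbs BLAS summation-order differences across chunks
        count += (np.abs(stats_) >= abs_obs - 1e-9).sum(axis=1)
        done += b

    if exhaustive:
        p = count / n_splits
    else:
        p = (count + 1) / (iters + 1)

    med_a = np.median(x[:, :na], axis=1)
    med_b = np.median(x[:, na:], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(med_b > 0, med_a / med_b, np.inf)
        r = np.where((med_a == 0) & (med_b == 0), 1.0, r)
        fold = np.where(r >= 1, r, np.where(r > 0, 1.0 / r, np.inf))

    q = bh_adjust(p)
    table = pd.DataFrame(
        {
            "gene_id": m.gene_ids,
            "fold_change": fold,
            "p": p,
            "q": q,
            "flagged": (q < fdr) & (fold >= min_fold),
        }
    )
    return DifferentialResult(table, exhaustive, total)


# ---------------------------------------------------------------------------
# RNA calls and tiers
# ---------------------------------------------------------------------------

def call_expressed_rna(
    m: ExpressionMatrix,
    ann: SampleAnnotation,
    min_tpm: float = 2.0,
) -> pd.DataFrame:
    """Expressed iff per-cell-type median TPM >= min_tpm (2 by default;
    0.3 for the permissive growth-factor overlap analysis)."""
    med = _celltype_medians(m, ann)
    return med.ge(min_tpm)


def assign_tier(median_tpm: float, frac_samples_gt3: float) -> str:
    """Expression tier from the median TPM and the fraction of samples
    with TPM > 3 (strict thresholds)."""
    if median_tpm > 50:
        return "high"
    if median_tpm > 10:
        return "intermediate"
    if median_tpm > 2:
        return "low"
    if 0.0 < frac_samples_gt3 < 0.1:
        return "sporadic"
    return "none"


def call_tiers(m: ExpressionMatrix, ann: SampleAnnotation) -> pd.DataFrame:
    """Genes x cell types tier table (high/intermediate/low/sporadic/none)."""
    groups = _celltype_groups(m, ann)
    out = {}
    for ct, samps in groups.items():
        sub = m.data[samps]
        med = sub.median(axis=1).to_numpy()
        frac = (sub.to_numpy() > 3).mean(axis=1)
        out[ct] = [assign_tier(mv, fv) for mv, fv in zip(med, frac)]
    return pd.DataFrame(out, index=m.data.index)


def tier_long_format(tiers: pd.DataFrame) -> pd.DataFrame:
    long = tiers.stack().rename("tier").reset_index()
    long.columns = ["gene_id", "cell_type", "tier"]
    return long


# ---------------------------------------------------------------------------
# conditioned media (secretome readout)
# ---------------------------------------------------------------------------

def call_secretome_detected(
    media: ExpressionMatrix,
    ann: SampleAnnotation,
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Detected in a cell type's conditioned media iff nonzero LFQ in at
    least ``min_fraction`` of that type's media samples."""
    groups = _celltype_groups(media, ann)
    out = {}
    for ct, samps in groups.items():
        frac = (media.data[samps] > 0).mean(axis=1)
        out[ct] = frac >= min_fraction
    return pd.DataFrame(out)


def abundant_media_table(
    media: ExpressionMatrix,
    ann: SampleAnnotation,
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Most-abundant media proteins per producing cell type.

    A gene qualifies in a cell type if present (nonzero) in at least
    ``min_fraction`` of that type's media samples AND its median LFQ
    exceeds the median of all genes' medians in that cell type. Rows are
    genes qualifying in at least one cell type with per-cell-type medians
    (no cross-cell-type normalization is attempted: conditioned media have
    no shared normalizer).
    """
    groups = _celltype_groups(media, ann)
    med = {}
    qual = {}
    for ct, samps in groups.items():
        sub = media.data[samps]
        m_ct = sub.median(axis=1)
        present = (sub > 0).mean(axis=1) >= min_fraction
        med[ct] = m_ct
        qual[ct] = present & (m_ct > m_ct.median())
    med_df = pd.DataFrame(med)
    qual_df = pd.DataFrame(qual)
    keep = qual_df.any(axis=1)
    out = med_df[keep].copy()
    out.columns = [f"median_{ct}" for ct in out.columns]
    for ct in qual_df.columns:
        out[f"qualifies_{ct}"] = qual_df.loc[keep, ct]
    out.index.name = "gene_id"
    return out.reset_index()
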