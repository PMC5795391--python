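"""LFQ missing-value imputation, tumor-contamination QC, variance filtering.

Shotgun proteomics leaves many protein groups unquantified in individual
samples; MaxQuant writes these as LFQ = 0. Imputation replaces each zero by
the minimum nonzero intensity of the matrix perturbed by a Gaussian
*relative* error (default SD 0.59, the overall relative standard deviation
across protein groups), i.e. a draw at the detection floor.

Sorted ascites cell populations can carry tumor-cell (spheroid)
contamination; QC scores every sample by the summed LFQ of epithelial
tumor markers (EPCAM, PAX8, MSLN, MUC16, ITGB4) and flags non-tumor
samples whose marker load reaches tumor-sample levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import TUMOR_MARKERS, ExpressionMatrix, Layer, SampleAnnotation


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_missing_lfq(
    m: ExpressionMatrix,
    rel_sd: float = 0.59,
    seed: int | np.random.Generator | None = None,
    truncate: str = "none",
    vmin_scope: str = "global",
) -> ExpressionMatrix:
    """Replace LFQ zeros by ``v_min * (1 + eps)``, ``eps ~ N(0, rel_sd)``.

    Parameters
    ----------
    rel_sd : relative standard deviation of the Gaussian error.
    truncate : ``"none"`` draws the plain Gaussian, so the imputed values
        have mean ``v_min`` and relative SD exactly ``rel_sd`` (at
        rel_sd = 0.59 about 4.5% of draws fall at or below zero);
        ``"resample"`` redraws eps <= -1 so every imputed value is
        strictly positive, at the cost of a slight upward shift of the
        imputed distribution.
    vmin_scope : ``"global"`` uses the minimum nonzero value of the whole
        matrix; ``"per_sample"`` uses each sample's own minimum nonzero.

    Detected (nonzero) entries are never altered. Deterministic given seed.
    """
    if m.layer is not Layer.LFQ and m.layer is not Layer.MEDIA:
        raise ValueError(f"imputation expects an LFQ-type layer, got {m.layer}")
    if truncate not in ("none", "resample"):
        raise ValueError(f"unknown truncate mode {truncate!r}")
    if vmin_scope not in ("global", "per_sample"):
        raise ValueError(f"unknown vmin scope {vmin_scope!r}")

    vals = m.values().copy()
    nonzero = vals > 0
    if not nonzero.any():
        raise ValueError("all-zero matrix: no minimum nonzero value exists")

    if vmin_scope == "global":
        vmin = np.full(vals.shape[1], vals[nonzero].min())
    else:
        vmin = np.array(
            [col[col > 0].min() if (col > 0).any() else vals[nonzero].min()
             for col in vals.T]
        )

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    miss = ~nonzero
    n_miss = int(miss.sum())
    if n_miss:
        eps = rng.normal(0.0, rel_sd, size=n_miss)
        if truncate == "resample":
            bad = eps <= -1.0
            while bad.any():
                eps[bad] = rng.normal(0.0, rel_sd, size=int(bad.sum()))
                bad = eps <= -1.0
        vmin_per_entry = np.broadcast_to(vmin, vals.shape)[miss]
        vals[miss] = vmin_per_entry * (1.0 + eps)

    df = pd.DataFrame(vals, index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(df, m.layer, allow_negative=(truncate == "none"))


# ---------------------------------------------------------------------------
# contamination QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QcReport:
    sample_id: str
    cell_type: str
    tumor_marker_sum: float
    reference_min: float
    reference_median: float
    flag: str  # clean | low_contamination | contaminated

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "cell_type": self.cell_type,
            "tumor_marker_sum": self.tumor_marker_sum,
            "reference_min": self.reference_min,
            "reference_median": self.reference_median,
            "flag": self.flag,
        }


def assess_tumor_contamination(
    proteomes: ExpressionMatrix,
    ann: SampleAnnotation,
    markers: set[str] | tuple[str, ...] = TUMOR_MARKERS,
) -> list[QcReport]:
    """Flag non-tumor samples whose tumor-marker load reaches TU levels.

    A non-TU sample is ``low_contamination`` if its summed marker LFQ
    exceeds the *lowest* TU marker sum (exclude from tumor-specificity
    analyses only) and ``contaminated`` if it reaches the *median* TU
    marker sum, i.e. marker expression at tumor-cell levels (exclude from
    all analyses). TU samples themselves are always ``clean``.
    """
    marker_rows = [g for g in markers if g in proteomes.data.index]
    sums = proteomes.data.loc[marker_rows].sum(axis=0) if marker_rows else pd.Series(
        0.0, index=proteomes.data.columns
    )
    ctype = ann.cell_type_of()
    tu_sums = [sums[s] for s in proteomes.sample_ids if ctype.get(s) == "TU"]
    if not tu_sums:
        raise ValueError("no TU sample present; contamination QC needs a tumor reference")
    ref_min = float(min(tu_sums))
    ref_median = float(np.median(tu_sums))

    reports = []
    for s in proteomes.sample_ids:
        ct = ctype.get(s, "")
        val = float(sums[s])
        if ct == "TU":
            flag = "clean"
        elif val >= ref_median:
            flag = "contaminated"
        elif val > ref_min:
            flag = "low_contamination"
        else:
            flag = "clean"
        reports.append(QcReport(s, ct, val, ref_min, ref_median, flag))
    return reports


def exclusion_lists(reports: list[QcReport]) -> dict[str, list[str]]:
    """Samples to drop per analysis scope.

    ``all_analyses``: contaminated samples; ``tumor_specificity``:
    contaminated plus low-contamination samples (the latter only bias
    tumor-selectivity calls).
    """
    contaminated = [r.sample_id for r in reports if r.flag == "contaminated"]
    low = [r.sample_id for r in reports if r.flag == "low_contamination"]
    return {"all_analyses": contaminated, "tumor_specificity": contaminated + low}


def qc_report_frame(reports: list[QcReport]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in reports])


# ---------------------------------------------------------------------------
# variance filter
# ---------------------------------------------------------------------------

def select_high_variance(m: ExpressionMatrix) -> set[str]:
    """Genes whose across-sample variance strictly exceeds the median variance."""
    if m.shape[1] < 2:
        raise ValueError("variance filter needs at least 2 samples")
    var = m.data.var(axis=1, ddof=1)
    med = var.median()
    return set(var.index[var > med])
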