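"""Proteome/transcriptome concordance and detection-deficit statistics.

Three questions about how well protein abundance tracks mRNA:

1. Per-gene Spearman correlation between LFQ and TPM across matched
   samples, summarized by the median rho and the sign fractions.
2. Detection curves: among genes whose mRNA summary level is at least a
   TPM threshold t, which fraction has any protein-group evidence? Plotted
   over a grid of t this is the detection-probability-vs-expression curve.
3. A permutation test for class-specific detection deficits: is a gene
   class (e.g. secreted ligands) missing from the proteome more often than
   random gene sets of the same size, at matched mRNA levels? A random
   subset "beats" the query class if at any grid threshold where the query
   still has at least ``min_remaining`` genes, the subset has at least as
   many missing proteins; p = fraction of beating subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import rowwise_spearman
from .containers import ExpressionMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# per-gene correlation
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceResult:
    per_gene: pd.DataFrame  # gene_id, rho, p, n_pairs, defined
    median_rho: float
    fraction_positive: float
    fraction_negative: float
    fraction_zero: float
    n_defined: int
    n_undefined: int


def gene_concordance(
    lfq: ExpressionMatrix,
    tpm: ExpressionMatrix,
    pairing: dict[str, str],
) -> ConcordanceResult:
    """Per-gene Spearman rho between protein (LFQ) and mRNA (TPM).

    ``pairing`` maps proteome sample id -> matched transcriptome sample id.
    Genes must be present in both layers; genes with zero variance in
    either layer are reported as undefined and excluded from the summary.
    """
    pairs = [(p, t) for p, t in pairing.items()
             if p in lfq.data.columns and t in tpm.data.columns]
    dropped = len(pairing) - len(pairs)
    if dropped:
        log.warning("dropped %d pairing entr(ies) not present in both matrices", dropped)
    if len(pairs) < 3:
        raise ValueError(f"need >=3 matched sample pairs, got {len(pairs)}")

    genes = [g for g in lfq.data.index if g in set(tpm.data.index)]
    if not genes:
        raise ValueError("no gene shared between layers")
    x = lfq.data.loc[genes, [p for p, _ in pairs]].to_numpy()
    y = tpm.data.loc[genes, [t for _, t in pairs]].to_numpy()
    rho, p = rowwise_spearman(x, y)
    defined = ~np.isnan(rho)

    table = pd.DataFrame(
        {"gene_id": genes, "rho": rho, "p": p,
         "n_pairs": len(pairs), "defined": defined}
    )
    r = rho[defined]
    n_def = int(defined.sum())
    return ConcordanceResult(
        per_gene=table,
        median_rho=float(np.median(r)) if n_def else float("nan"),
        fraction_positive=float((r > 0).mean()) if n_def else float("nan"),
        fraction_negative=float((r < 0).mean()) if n_def else float("nan"),
        fraction_zero=float((r == 0).mean()) if n_def else float("nan"),
        n_defined=n_def,
        n_undefined=int((~defined).sum()),
    )


# ---------------------------------------------------------------------------
# detection curves
# ---------------------------------------------------------------------------

@dataclass
class DetectionCurve:
    table: pd.DataFrame  # threshold, n_remaining, n_detected, n_missing, fraction_detected

    def __post_init__(self) -> None:
        t = self.table
        if (np.diff(t["n_remaining"].to_numpy()) > 0).any():
            raise ValueError("n_remaining must be non-increasing in threshold")


def default_grid(tpm_level: np.ndarray, n: int = 25) -> np.ndarray:
    """Log-spaced TPM thresholds over the observed positive range."""
    pos = np.asarray(tpm_level, dtype=float)
    pos = pos[pos > 0]
    if pos.size == 0:
        raise ValueError("no positive TPM level to build a grid from")
    lo, hi = pos.min(), pos.max()
    if lo == hi:
        return np.array([lo])
    return np.geomspace(lo, hi, n)


def _align(genes, detected, tpm_level) -> tuple[list[str], np.ndarray, np.ndarray]:
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    if isinstance(detected, pd.Series):
        det = detected.reindex(genes).fillna(False).to_numpy(dtype=bool)
    else:
        det = np.array([bool(detected[g]) for g in genes])
    if isinstance(tpm_level, pd.Series):
        tpm = tpm_level.reindex(genes).to_numpy(dtype=float)
    else:
        tpm = np.array([float(tpm_level[g]) for g in genes])
    return genes, det, tpm


def detection_curve(
    genes,
    detected,
    tpm_level,
    grid: np.ndarray | None = None,
) -> DetectionCurve:
    """Fraction of protein-detected genes among genes with TPM >= t, per t.

    ``detected``/``tpm_level`` are per-gene (mapping or Series);
    ``tpm_level`` is a per-gene mRNA summary (median TPM across the
    relevant samples). Fraction is NaN where no gene remains.
    """
    genes, det, tpm = _align(genes, detected, tpm_level)
    if grid is None:
        grid = default_grid(tpm)
    grid = np.sort(np.asarray(grid, dtype=float))
    rem = np.array([(tpm >= t).sum() for t in grid])
    n_det = np.array([(det & (tpm >= t)).sum() for t in grid])
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(rem > 0, n_det / np.maximum(rem, 1), np.nan)
    return DetectionCurve(
        pd.DataFrame(
            {"threshold": grid, "n_remaining": rem, "n_detected": n_det,
             "n_missing": rem - n_det, "fraction_detected": frac}
        )
    )


# ---------------------------------------------------------------------------
# detection-deficit permutation test
# ---------------------------------------------------------------------------

@dataclass
class DeficitTestResult:
    pvalue: float          # (# beating draws) / n_draws
    n_beat: int
    n_draws: int
    is_floor: bool         # no draw beat the query; report p < 1/n_draws
    query_size: int
    n_valid_thresholds: int
    grid: np.ndarray = field(repr=False)

    @property
    def p_string(self) -> str:
        return f"< {1.0 / self.n_draws:g}" if self.is_floor else f"{self.pvalue:g}"


def _suffix_counts(bins: np.ndarray, n_thresholds: int) -> np.ndarray:
    """#elements with bin index >= k, for k = 0..K-1 (bin -1 = below grid)."""
    hist = np.bincount(bins + 1, minlength=n_thresholds + 1)[1:]
    return hist[::-1].cumsum()[::-1]


def detection_deficit_pvalue(
    query,
    universe,
    detected,
    tpm_level,
    n_draws: int = 10000,
    min_remaining: int = 20,
    grid: np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
    tie_rule: str = "strict",
    _chunk: int = 2048,
) -> DeficitTestResult:
    """Permutation p-value for a protein-detection deficit of a gene class.

    Random subsets of the universe, the same size as the query, are drawn
    without replacement. A subset is "equal or better" than the query if,
    over the thresholds where the query has >= ``min_remaining`` genes
    remaining, it has strictly more missing (undetected) proteins at some
    threshold or exactly as many at every threshold
    (``tie_rule="strict"``, the default). ``tie_rule="ties"`` counts any
    single-threshold equality as a beat; note that then any threshold
    where the query has zero missing proteins lets every draw beat,
    degenerating the p-value to 1.

    The test is a global (curve-wise) comparison and is conservative under
    the null: most random subsets beat a typical query somewhere along the
    grid, so null p-values concentrate near 1 rather than being uniform.
    Small p-values therefore indicate a deficit robust across the whole
    expression range.
    """
    uni, det, tpm = _align(universe, detected, tpm_level)
    pos = {g: i for i, g in enumerate(uni)}
    qset = list(dict.fromkeys(query))
    missing_genes = [g for g in qset if g not in pos]
    if missing_genes:
        raise ValueError(f"query gene(s) outside universe: {missing_genes[:5]}")
    if len(qset) > len(uni):
        raise ValueError("query larger than universe")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if tie_rule not in ("strict", "ties"):
        raise ValueError(f"unknown tie rule {tie_rule!r}")

    if grid is None:
        grid = default_grid(tpm)
    grid = np.sort(np.asarray(grid, dtype=float))
    k = len(grid)
    bins = np.searchsorted(grid, tpm, side="right") - 1  # -1 = below all thresholds

    qidx = np.fromiter((pos[g] for g in qset), dtype=np.intp)
    q_rem = _suffix_counts(bins[qidx], k)
    q_miss = _suffix_counts(bins[qidx[~det[qidx]]], k)
    valid = q_rem >= min_remaining
    if not valid.any():
        log.warning("no threshold with >=%d query genes remaining; p-value is vacuous",
                    min_remaining)

    miss_bins = np.where(det, -1, bins)  # detected genes never count as missing
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m, n = len(qidx), len(uni)
    q_miss_valid = q_miss[valid]
    n_beat = 0
    done = 0
    while done < n_draws:
        b = min(_chunk, n_draws - done)
        # b subsets of size m without replacement, via row-wise permutation
        perm = rng.permuted(
            np.broadcast_to(np.arange(n), (b, n)).copy(), axis=1
        )[:, :m]
        sub_bins = miss_bins[perm] + 1  # 0 = not missing-above-grid
        offsets = (np.arange(b) * (k + 1))[:, None]
        flat = np.bincount((sub_bins + offsets).ravel(), minlength=b * (k + 1))
        hist = flat.reshape(b, k + 1)[:, 1:]
        miss = hist[:, ::-1].cumsum(axis=1)[:, ::-1]  # suffix counts per draw
        if valid.any():
            if tie_rule == "strict":
                # "equal or better": tied everywhere, or strictly more somewhere
                mv = miss[:, valid]
                beat = (mv > q_miss_valid).any(axis=1) | (mv == q_miss_valid).all(axis=1)
            else:
                beat = (miss[:, valid] >= q_miss_valid).any(axis=1)
            n_beat += int(beat.sum())
        done += b

    return DeficitTestResult(
        pvalue=n_beat / n_draws,
        n_beat=n_beat,
        n_draws=n_draws,
        is_floor=(n_beat == 0),
        query_size=m,
        n_valid_thresholds=int(valid.sum()),
        grid=grid,
    )
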