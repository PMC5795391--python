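"""Outcome-surrogate coexpression screens.

Macrophages (TAM) in ovarian-cancer ascites stratify by CD163/CD206
(MRC1) into a poor-prognosis (bTAM, marker-high) and a favorable
(gTAM, marker-low) phenotype. With too few patients for survival
modeling, the combined CD163/MRC1 mRNA level serves as a per-patient
outcome surrogate:

* TAM-internal screen: Spearman correlation of candidate genes in TAM
  against the surrogate score (hits at rho > 0.5 / rho < -0.6);
* matched-pair screen: tumor-cell (TU) gene expression against the same
  patient's TAM score (hits at |rho| > 0.7);
* survival-z-score grouping: proteome genes with |outcome z| > 4 seed
  tightly correlated protein groups (rho > 0.95, at least 8 members),
  merged when neighborhoods overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._stats import significance_stars, spearman_vs_vector
from .containers import ExpressionMatrix

log = logging.getLogger(__name__)

SURROGATE_MARKERS = ("CD163", "MRC1")


# ---------------------------------------------------------------------------
# surrogate score
# ---------------------------------------------------------------------------

def surrogate_score(
    tpm_tam: ExpressionMatrix,
    markers: tuple[str, ...] = SURROGATE_MARKERS,
    method: str = "rank_mean",
) -> pd.Series:
    """Combined per-sample marker score across TAM samples.

    ``rank_mean`` (default) averages the rank-transformed TPM of the
    markers (midranks for ties), keeping the downstream Spearman
    well-defined; ``tpm_mean`` averages raw TPM.
    """
    missing = [g for g in markers if g not in tpm_tam.data.index]
    if missing:
        raise ValueError(f"surrogate marker(s) missing from matrix: {missing}")
    sub = tpm_tam.data.loc[list(markers)]
    if method == "rank_mean":
        ranks = sub.apply(lambda row: stats.rankdata(row), axis=1, result_type="expand")
        ranks.columns = sub.columns
        score = ranks.mean(axis=0)
        rho = stats.spearmanr(sub.iloc[0], sub.iloc[1]).statistic if len(markers) == 2 else 1.0
        if len(markers) == 2 and rho < 0:
            log.warning("surrogate markers are anti-correlated (rho=%.2f); "
                        "combined score is near-degenerate", rho)
    elif method == "tpm_mean":
        score = sub.mean(axis=0)
    else:
        raise ValueError(f"unknown method {method!r}")
    score.name = "surrogate_score"
    return score


# ---------------------------------------------------------------------------
# coexpression screens
# ---------------------------------------------------------------------------

@dataclass
class CoexpressionHit:
    gene: str
    rho: float
    p: float
    direction: str  # positive | inverse
    screen: str     # TAM_internal | TU_vs_TAM
    stars: str


def _screen(
    expr: pd.DataFrame,
    score: np.ndarray,
    candidates,
    pos_thr: float,
    neg_thr: float,
    screen: str,
) -> tuple[list[CoexpressionHit], pd.DataFrame]:
    cand = [g for g in candidates if g in expr.index]
    skipped = [g for g in candidates if g not in expr.index]
    if skipped:
        log.warning("%d candidate(s) absent from matrix, skipped", len(skipped))
    x = expr.loc[cand].to_numpy()
    const = x.std(axis=1) == 0
    if const.any():
        log.warning("%d constant candidate(s) skipped", int(const.sum()))
    rho, p = spearman_vs_vector(x, score)
    rows, hits = [], []
    for g, r, pv, c in zip(cand, rho, p, const):
        if c or np.isnan(r):
            continue
        direction = "positive" if r > pos_thr else ("inverse" if r < neg_thr else "")
        rows.append({"gene_id": g, "rho": r, "p": pv,
                     "direction": direction, "stars": significance_stars(pv)})
        if direction:
            hits.append(CoexpressionHit(g, float(r), float(pv), direction, screen,
                                        significance_stars(pv)))
    return hits, pd.DataFrame(rows, columns=["gene_id", "rho", "p", "direction", "stars"])


def coexpress_with_surrogate(
    expr: ExpressionMatrix,
    score: pd.Series,
    candidates,
    pos_thr: float = 0.5,
    neg_thr: float = -0.6,
) -> tuple[list[CoexpressionHit], pd.DataFrame]:
    """TAM-internal screen: candidate expression vs the surrogate score
    across the same samples."""
    common = [s for s in expr.sample_ids if s in score.index]
    if len(common) < 5:
        raise ValueError(f"need >=5 shared samples, got {len(common)}")
    return _screen(expr.data[common], score.loc[common].to_numpy(),
                   candidates, pos_thr, neg_thr, "TAM_internal")


def matched_pair_coexpression(
    tu_expr: ExpressionMatrix,
    tam_score: pd.Series,
    tu_patient_of: dict[str, str],
    tam_patient_of: dict[str, str],
    candidates=None,
    pos_thr: float = 0.7,
    neg_thr: float = -0.7,
) -> tuple[list[CoexpressionHit], pd.DataFrame]:
    """Matched-pair screen: TU expression vs the same patient's TAM score.

    A patient may contribute multiple TU samples (spheroid fractions);
    each is paired with that patient's TAM score. Unmatched TU samples are
    dropped with a log entry.
    """
    score_by_patient = {}
    for s, v in tam_score.items():
        pat = tam_patient_of.get(s)
        if pat is not None:
            score_by_patient[pat] = v
    cols, vals = [], []
    for s in tu_expr.sample_ids:
        pat = tu_patient_of.get(s)
        if pat in score_by_patient:
            cols.append(s)
            vals.append(score_by_patient[pat])
        else:
            log.warning("TU sample %s has no matched TAM score; dropped", s)
    if len(cols) < 5:
        raise ValueError(f"need >=5 matched pairs, got {len(cols)}")
    if candidates is None:
        candidates = list(tu_expr.data.index)
    return _screen(tu_expr.data[cols], np.asarray(vals, dtype=float),
                   candidates, pos_thr, neg_thr, "TU_vs_TAM")


# ---------------------------------------------------------------------------
# survival-z-score surrogate groups
# ---------------------------------------------------------------------------

@dataclass
class SurrogateGroup:
    seed_markers: tuple[str, ...]  # seeds merged into this group
    members: frozenset[str]
    min_internal_rho: float        # lowest member-vs-seed rho across the group


def minmax_scale_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Scale each row to [0, 1] across samples (constant rows stay 0)."""
    lo = df.min(axis=1)
    rng = df.max(axis=1) - lo
    rng = rng.replace(0, np.nan)
    return df.sub(lo, axis=0).div(rng, axis=0).fillna(0.0)


def precog_surrogate_groups(
    proteome_tu: ExpressionMatrix,
    tpm_tu: ExpressionMatrix,
    zscores: pd.Series,
    pairing: dict[str, str] | None = None,
    z_thr: float = 4.0,
    rna_rho_min: float = 0.3,
    group_rho: float = 0.95,
    min_size: int = 8,
    merge_overlaps: bool = True,
) -> tuple[list[SurrogateGroup], list[SurrogateGroup]]:
    """Group proteome genes around outcome-z-score seed markers.

    Steps: (1) seeds = genes with |z| > z_thr present in the TU proteome;
    (2) seeds kept iff their protein-mRNA Spearman rho > rna_rho_min over
    matched TU samples; (3) seed LFQ profiles min-max scaled to [0, 1];
    (4) group(seed) = proteome genes with Spearman rho > group_rho against
    the scaled seed profile (the seed itself always included and counted);
    (5) groups with >= min_size members retained; (6) retained groups
    sharing members merged via connected components (logged).

    Returns (final groups, pre-merge retained per-seed groups).
    """
    prot = proteome_tu.data
    seeds = [g for g in zscores.index if abs(zscores[g]) > z_thr and g in prot.index]
    if not seeds:
        log.warning("no outcome-z seed present in the TU proteome")
        return [], []

    # (2) protein-mRNA concordance filter over matched samples
    if pairing is None:
        shared = [s for s in prot.columns if s in tpm_tu.data.columns]
        pairing = {s: s for s in shared}
    pcols = [p for p in pairing if p in prot.columns and pairing[p] in tpm_tu.data.columns]
    tcols = [pairing[p] for p in pcols]
    kept = []
    for g in seeds:
        if g not in tpm_tu.data.index:
            continue
        rho, _ = spearman_vs_vector(prot.loc[[g], pcols].to_numpy(),
                                    tpm_tu.data.loc[g, tcols].to_numpy())
        if not np.isnan(rho[0]) and rho[0] > rna_rho_min:
            kept.append(g)
    if not kept:
        log.warning("no seed passed the protein-mRNA concordance filter")
        return [], []

    # (3)+(4) per-seed neighborhoods (min-max scaling is monotone, so the
    # Spearman is unchanged; performed to mirror the stated procedure)
    scaled_seeds = minmax_scale_rows(prot.loc[kept])
    all_vals = prot.to_numpy()
    per_seed: list[SurrogateGroup] = []
    for g in kept:
        rho, _ = spearman_vs_vector(all_vals, scaled_seeds.loc[g].to_numpy())
        members = set(np.asarray(prot.index)[np.nan_to_num(rho, nan=-2.0) > group_rho])
        members.add(g)
        if len(members) >= min_size:
            idx = [prot.index.get_loc(m) for m in sorted(members)]
            per_seed.append(SurrogateGroup((g,), frozenset(members),
                                           float(np.nanmin(rho[idx]))))

    if not merge_overlaps:
        return per_seed, per_seed

    # (6) merge overlapping retained neighborhoods
    graph = nx.Graph()
    for i, grp in enumerate(per_seed):
        graph.add_node(i)
        for j in range(i):
            if per_seed[j].members & grp.members:
                graph.add_edge(i, j)
    merged: list[SurrogateGroup] = []
    for comp in nx.connected_components(graph):
        comp = sorted(comp)
        if len(comp) > 1:
            log.info("merging %d overlapping surrogate groups (seeds %s)",
                     len(comp), [per_seed[i].seed_markers[0] for i in comp])
        members = frozenset().union(*(per_seed[i].members for i in comp))
        seeds_t = tuple(sorted(s for i in comp for s in per_seed[i].seed_markers))
        merged.append(SurrogateGroup(seeds_t, members,
                                     min(per_seed[i].min_internal_rho for i in comp)))
    merged.sort(key=lambda g: g.seed_markers)
    return merged, per_seed


def groups_to_frame(groups: list[SurrogateGroup]) -> pd.DataFrame:
    rows = [
        {"group": "+".join(g.seed_markers), "gene_id": m, "n_members": len(g.members),
         "min_internal_rho": g.min_internal_rho}
        for g in groups for m in sorted(g.members)
    ]
    return pd.DataFrame(rows, columns=["group", "gene_id", "n_members", "min_internal_rho"])
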