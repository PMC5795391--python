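"""Intercellular ligand-receptor interaction map over cell-type tiers.

A ligand-receptor group is *mapped* when at least one of its ligands and
at least one of its receptors is expressed (tier != none) in at least one
cell type; edges are enumerated per expressed (ligand, receptor) pair,
with the expressing cell types and tiers attached on each side. Groups
with only one side expressed are ``ligand_only`` / ``receptor_only``;
orphan-ligand groups (no known receptor) with an expressed ligand are
``orphan_expressed``; everything else is ``silent``. Sporadic expression
counts toward mapping but is flagged so renderings can distinguish it
(the "open square" convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .calls import TIER_RANK
from .catalogs import LigandReceptorGroup

log = logging.getLogger(__name__)

GROUP_STATUSES = ("mapped", "ligand_only", "receptor_only", "silent", "orphan_expressed")


@dataclass(frozen=True)
class InteractionEdge:
    group_id: int
    ligand_gene: str
    receptor_gene: str
    source_cell_types: tuple[tuple[str, str], ...]  # (cell_type, tier)
    target_cell_types: tuple[tuple[str, str], ...]
    modality: str
    sporadic_only_source: bool
    sporadic_only_target: bool


@dataclass(frozen=True)
class GroupStatus:
    group_id: int
    status: str


def _expression_of(gene: str, tiers: pd.DataFrame, unknown: set[str]) -> list[tuple[str, str]]:
    """(cell_type, tier) pairs where the gene is expressed (tier != none)."""
    if gene not in tiers.index:
        unknown.add(gene)
        return []
    row = tiers.loc[gene]
    return [(ct, row[ct]) for ct in tiers.columns if row[ct] != "none"]


def build_interaction_map(
    tiers: pd.DataFrame,
    groups: list[LigandReceptorGroup],
) -> tuple[list[InteractionEdge], list[GroupStatus]]:
    """Enumerate edges and classify every group's mapping status.

    ``tiers`` is a genes x cell-types tier table. Genes absent from it are
    treated as not expressed (logged once at the end).
    """
    edges: list[InteractionEdge] = []
    statuses: list[GroupStatus] = []
    unknown: set[str] = set()

    for g in groups:
        lig_expr = {gene: _expression_of(gene, tiers, unknown) for gene in sorted(g.ligand_gene_ids)}
        rec_expr = {gene: _expression_of(gene, tiers, unknown) for gene in sorted(g.receptor_gene_ids)}
        any_lig = any(lig_expr.values())
        any_rec = any(rec_expr.values())

        if g.is_orphan:
            statuses.append(GroupStatus(g.group_id, "orphan_expressed" if any_lig else "silent"))
            continue
        if any_lig and any_rec:
            statuses.append(GroupStatus(g.group_id, "mapped"))
            for lg, lsrc in lig_expr.items():
                if not lsrc:
                    continue
                for rg, rtgt in rec_expr.items():
                    if not rtgt:
                        continue
                    edges.append(
                        InteractionEdge(
                            group_id=g.group_id,
                            ligand_gene=lg,
                            receptor_gene=rg,
                            source_cell_types=tuple(lsrc),
                            target_cell_types=tuple(rtgt),
                            modality=g.modality,
                            sporadic_only_source=all(t == "sporadic" for _, t in lsrc),
                            sporadic_only_target=all(t == "sporadic" for _, t in rtgt),
                        )
                    )
        elif any_lig:
            statuses.append(GroupStatus(g.group_id, "ligand_only"))
        elif any_rec:
            statuses.append(GroupStatus(g.group_id, "receptor_only"))
        else:
            statuses.append(GroupStatus(g.group_id, "silent"))

    if unknown:
        log.warning("%d gene(s) in groups absent from tier table (treated as not expressed), e.g. %s",
                    len(unknown), sorted(unknown)[:5])
    return edges, statuses


def status_counts(statuses: list[GroupStatus]) -> dict[str, int]:
    out = {s: 0 for s in GROUP_STATUSES}
    for st in statuses:
        out[st.status] += 1
    return out


def cell_source_target_summary(edges: list[InteractionEdge]) -> pd.DataFrame:
    """Per group: the cell type that is the unique highest-tier receptor
    expresser ("main target"); ties across cell types are listed as "All".

    The unique-max rule is an interpretation of the published source/target
    table and is labeled as such in the ``criterion`` column.
    """
    best: dict[int, dict[str, int]] = {}
    for e in edges:
        per_ct = best.setdefault(e.group_id, {})
        for ct, tier in e.target_cell_types:
            r = TIER_RANK[tier]
            if r > per_ct.get(ct, -1):
                per_ct[ct] = r
    rows = []
    for gid in sorted(best):
        per_ct = best[gid]
        top = max(per_ct.values())
        winners = sorted(ct for ct, r in per_ct.items() if r == top)
        main = winners[0] if len(winners) == 1 else "All"
        rows.append({"group_id": gid, "main_target": main,
                     "tied_cell_types": ";".join(winners),
                     "criterion": "unique-max-receptor-tier"})
    return pd.DataFrame(rows, columns=["group_id", "main_target", "tied_cell_types", "criterion"])


def edges_to_frame(edges: list[InteractionEdge]) -> pd.DataFrame:
    """Flat edge list: one row per (edge, source cell type, target cell type)."""
    rows = []
    for e in edges:
        for sct, stier in e.source_cell_types:
            for tct, ttier in e.target_cell_types:
                rows.append(
                    {"group_id": e.group_id, "ligand": e.ligand_gene,
                     "receptor": e.receptor_gene, "source": sct,
                     "source_tier": stier, "target": tct, "target_tier": ttier,
                     "modality": e.modality,
                     "sporadic_flag": stier == "sporadic" or ttier == "sporadic"}
                )
    return pd.DataFrame(
        rows,
        columns=["group_id", "ligand", "receptor", "source", "source_tier",
                 "target", "target_tier", "modality", "sporadic_flag"],
    )


def interaction_graph(edges: list[InteractionEdge]) -> nx.MultiDiGraph:
    """Cell-type-level directed multigraph (source type -> target type)."""
    g = nx.MultiDiGraph()
    for _, row in edges_to_frame(edges).iterrows():
        g.add_edge(row["source"], row["target"], group_id=row["group_id"],
                   ligand=row["ligand"], receptor=row["receptor"],
                   modality=row["modality"])
    return g
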