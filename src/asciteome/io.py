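"""Readers/writers for the pipeline's tabular formats.

Everything is plain TSV (tab-separated, UTF-8, one header row). The
protein-group reader tolerates MaxQuant ``proteinGroups.txt`` column naming
("Protein IDs", "Gene names", "LFQ intensity <sample>").
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    Layer,
    MatrixValidationError,
    ProteinGroupTable,
    SampleAnnotation,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path, layer: Layer | str) -> ExpressionMatrix:
    """Read a genes x samples TSV (gene-id first column) into a matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        return ExpressionMatrix(df, Layer(layer))
    except MatrixValidationError as err:
        raise MatrixValidationError(f"{path}: {err}") from err


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    out = m.data.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_sample_annotation(path: str | Path) -> SampleAnnotation:
    return SampleAnnotation(pd.read_csv(path, sep="\t", dtype={"patient_id": str}))


def write_sample_annotation(ann: SampleAnnotation, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# protein groups
# ---------------------------------------------------------------------------

_MQ_GROUP_COL = ("Protein IDs", "protein_ids", "group_id")
_MQ_GENE_COL = ("Gene names", "gene_names", "member_gene_ids")
_MQ_PEP_COL = ("Unique peptides", "unique_peptides")
_MQ_LFQ_PREFIX = "LFQ intensity "


def read_protein_groups(path: str | Path) -> ProteinGroupTable:
    """Read a MaxQuant-style (or normalized) protein-group TSV.

    Gene-name cells may hold ``;``-separated member lists — groups matching
    multiple Ensembl gene annotations are common (e.g. LILRA4, histones).
    """
    raw = pd.read_csv(path, sep="\t")

    def pick(cands: tuple[str, ...], what: str) -> str:
        for c in cands:
            if c in raw.columns:
                return c
        raise MatrixValidationError(f"{path}: no {what} column (tried {cands})")

    gcol = pick(_MQ_GROUP_COL, "group id")
    ncol = pick(_MQ_GENE_COL, "gene names")
    pcol = pick(_MQ_PEP_COL, "unique peptides")

    lfq_cols = [c for c in raw.columns if c.startswith(_MQ_LFQ_PREFIX)]
    if lfq_cols:
        samples = [c[len(_MQ_LFQ_PREFIX):] for c in lfq_cols]
    else:  # normalized layout: every non-reserved column is a sample
        reserved = {gcol, ncol, pcol}
        lfq_cols = [c for c in raw.columns if c not in reserved]
        samples = lfq_cols

    table = pd.DataFrame(
        {
            "group_id": raw[gcol].astype(str),
            "member_gene_ids": [
                [g for g in str(cell).split(";") if g and g != "nan"]
                for cell in raw[ncol]
            ],
            "unique_peptides": raw[pcol].astype(int),
        }
    )
    for samp, col in zip(samples, lfq_cols):
        table[samp] = raw[col].astype(float)
    return ProteinGroupTable(table, sample_columns=list(samples))


def expand_protein_groups(t: ProteinGroupTable) -> pd.DataFrame:
    """Expand protein groups to one row per (group, member gene).

    A group matching k genes yields k identical LFQ rows, each keyed by one
    gene id. Rows born from multi-gene groups carry ``multi_gene=True`` so
    amplified families can be dropped from enrichment-style summaries. A
    gene claimed by two groups keeps both rows; the ambiguity is logged.
    """
    rows = []
    for _, rec in t.table.iterrows():
        members = rec["member_gene_ids"]
        for gene in members:
            row = {"gene_id": gene, "group_id": rec["group_id"],
                   "multi_gene": len(members) > 1}
            for s in t.sample_columns:
                row[s] = rec[s]
            rows.append(row)
    out = pd.DataFrame(rows, columns=["gene_id", "group_id", "multi_gene", *t.sample_columns])
    dup = out.loc[out["gene_id"].duplicated(), "gene_id"].unique()
    if len(dup):
        log.warning("gene id(s) appearing in multiple protein groups: %s", list(dup))
    return out


def expanded_to_matrix(expanded: pd.DataFrame, layer: Layer | str = Layer.LFQ) -> ExpressionMatrix:
    """Collapse an expanded table to a matrix, keeping the first row per gene."""
    n_dup = int(expanded["gene_id"].duplicated().sum())
    if n_dup:
        log.info("deduplicating %d repeated gene row(s) by first occurrence", n_dup)
    first = expanded.drop_duplicates("gene_id", keep="first")
    samples = [c for c in expanded.columns if c not in ("gene_id", "group_id", "multi_gene")]
    df = first.set_index("gene_id")[samples].astype(float)
    return ExpressionMatrix(df, Layer(layer))


# ---------------------------------------------------------------------------
# gene lists / small tables / manifests
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path) -> set[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def write_gene_list(genes: set[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def read_zscore_table(path: str | Path) -> pd.Series:
    """Outcome z-score table: columns ``gene_id``, ``z``."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["z"].to_numpy(dtype=float), index=df["gene_id"].astype(str))


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
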