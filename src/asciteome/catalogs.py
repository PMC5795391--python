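"""Receptome/secretome classification sets and ligand-receptor group tables.

The receptor catalog is built by a description-mining rule over a
HUGO-style gene-description table (keep genes whose description contains
"receptor", drop known false-positive patterns), unioned with a curated
receptor list and a CD-marker list. The secreted-protein catalog is the
intersection of four independent secretion-prediction gene sets. Ligand-
receptor groups pair one or more ligands with their cognate receptors
(protein modality) or pair lipid-mediator-synthesizing enzymes with lipid
receptors (lipid modality); groups without any known receptor are orphan-
ligand groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: Description substrings marking receptor-catalog false positives
#: (e.g. non-receptor kinases, nuclear receptors, ER/Golgi residents).
DEFAULT_EXCLUSION_TERMS = (
    "putative",
    "accessory",
    "assoc",
    "bound",
    "chemosensory",
    "cornichon",
    "endoplasmic reticulum",
    "golgi",
    "interact",
    "intracellular",
    "non-receptor",
    "nuclear",
    "orphan",
    "peroxisome",
    "regulat",
    "retinoic",
    "retinoid",
    "signal recognition particle",
    "signal sequence",
    "steroid",
    "substrate",
)

GENE_FLAGS = (
    "membrane_receptor",
    "secreted",
    "growth_factor_cytokine",
    "orphan_ligand",
    "lipid_enzyme",
    "lipid_receptor",
)


@dataclass
class GeneCatalog:
    """Per-gene class flags with provenance of the rule that set each flag."""

    flags: dict[str, set[str]] = field(default_factory=dict)  # gene -> flags
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)

    def add(self, gene: str, flag: str, source: str) -> None:
        if flag not in GENE_FLAGS:
            raise ValueError(f"unknown flag {flag!r}")
        self.flags.setdefault(gene, set()).add(flag)
        self.provenance[(gene, flag)] = source

    def genes_with(self, flag: str) -> set[str]:
        return {g for g, fl in self.flags.items() if flag in fl}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "flag": f, "provenance": self.provenance.get((g, f), "")}
            for g, fl in sorted(self.flags.items())
            for f in sorted(fl)
        ]
        return pd.DataFrame(rows, columns=["gene_id", "flag", "provenance"])


@dataclass(frozen=True)
class LigandReceptorGroup:
    """One ligand-receptor signaling group (e.g. group 42 = EGF family/EGFR-ERBB)."""

    group_id: int
    ligand_gene_ids: frozenset[str]
    receptor_gene_ids: frozenset[str]
    modality: str = "protein"  # "protein" | "lipid"

    def __post_init__(self) -> None:
        if not self.ligand_gene_ids:
            raise ValueError(f"group {self.group_id}: ligand set is empty")
        if self.modality not in ("protein", "lipid"):
            raise ValueError(f"group {self.group_id}: unknown modality {self.modality!r}")

    @property
    def is_orphan(self) -> bool:
        return len(self.receptor_gene_ids) == 0


def build_receptor_catalog(
    descriptions: pd.DataFrame | dict[str, str],
    exclusion_terms: tuple[str, ...] | list[str] = DEFAULT_EXCLUSION_TERMS,
    curated_receptors: set[str] | None = None,
    cd_markers: set[str] | None = None,
) -> set[str]:
    """Mine a gene-description table for plasma-membrane receptors.

    Keeps genes whose description contains the substring "receptor"
    (case-insensitive) and none of the exclusion terms, then unions curated
    receptor and CD-marker lists (which are taken on trust, not filtered).
    """
    if isinstance(descriptions, pd.DataFrame):
        if descriptions.empty:
            raise ValueError("empty description table")
        pairs = zip(descriptions["gene_id"].astype(str), descriptions["description"].astype(str))
    else:
        if not descriptions:
            raise ValueError("empty description table")
        pairs = descriptions.items()

    terms = [t.lower() for t in exclusion_terms]
    mined = set()
    for gene, desc in pairs:
        d = desc.lower()
        if "receptor" in d and not any(t in d for t in terms):
            mined.add(gene)
    return mined | set(curated_receptors or ()) | set(cd_markers or ())


def build_secreted_catalog(prediction_sets: list[set[str]] | tuple[set[str], ...]) -> set[str]:
    """Consensus secreted-protein set: 4-way intersection of prediction sets."""
    if len(prediction_sets) != 4:
        raise ValueError(f"need exactly 4 prediction sets, got {len(prediction_sets)}")
    if any(not s for s in prediction_sets):
        raise ValueError("empty prediction set")
    out = set(prediction_sets[0])
    for s in prediction_sets[1:]:
        out &= set(s)
    return out


def load_lr_groups(path: str | Path) -> list[LigandReceptorGroup]:
    """Load a ligand-receptor group TSV (group_id, role, gene_id, modality).

    Roles: ``ligand``, ``receptor``, ``enzyme``. Enzyme rows are mapped onto
    the ligand side of lipid-modality groups — an enzyme stands in for the
    lipid mediator it synthesizes (e.g. PTGS2 for PGE2 upstream of
    PTGER2/4).
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return lr_groups_from_frame(df)


def lr_groups_from_frame(df: pd.DataFrame) -> list[LigandReceptorGroup]:
    groups: list[LigandReceptorGroup] = []
    for gid, sub in df.groupby("group_id", sort=True):
        ligands: set[str] = set()
        receptors: set[str] = set()
        modality = "protein"
        for _, row in sub.iterrows():
            role = str(row["role"])
            mod = str(row.get("modality", "protein"))
            if mod == "lipid":
                modality = "lipid"
            if role == "ligand":
                ligands.add(row["gene_id"])
            elif role == "receptor":
                receptors.add(row["gene_id"])
            elif role == "enzyme":
                ligands.add(row["gene_id"])  # enzyme == mediator proxy
            else:
                raise ValueError(f"group {gid}: unknown role {role!r}")
        if not ligands:
            raise ValueError(f"group {gid}: no ligand or enzyme row")
        groups.append(
            LigandReceptorGroup(int(gid), frozenset(ligands), frozenset(receptors), modality)
        )
    ids = [g.group_id for g in groups]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate group ids")
    return groups


def write_lr_groups(groups: list[LigandReceptorGroup], path: str | Path) -> None:
    rows = []
    for g in groups:
        for gene in sorted(g.ligand_gene_ids):
            role = "enzyme" if g.modality == "lipid" else "ligand"
            rows.append((g.group_id, role, gene, g.modality))
        for gene in sorted(g.receptor_gene_ids):
            rows.append((g.group_id, "receptor", gene, g.modality))
    pd.DataFrame(rows, columns=["group_id", "role", "gene_id", "modality"]).to_csv(
        path, sep="\t", index=False
    )
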