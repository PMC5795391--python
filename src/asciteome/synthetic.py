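"""Synthetic matched proteome/transcriptome/media cohorts with ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, at desk scale:

* three cell populations (TU, TAM, TAT) per patient, with matched
  proteome (LFQ) and transcriptome (TPM) samples;
* a Gaussian copula couples per-gene log-TPM and log-LFQ sample noise so
  the population Spearman correlation equals ``target_concordance_rho``
  in closed form (rho_S = (6/pi)*asin(r/2), hence r = 2*sin(pi*rho_S/6));
* protein detection follows a logistic curve in median log-TPM, shifted
  per gene class (secreted / membrane receptor / growth-factor-cytokine
  flags add to the dropout midpoint), reproducing the class-specific
  detection deficits the permutation test is built to find;
* a latent per-patient outcome score u ("bTAM score") drives CD163/MRC1
  in TAM and planted positively/negatively coexpressed ligand sets (and
  TU-side secreted sets for the matched-pair screen);
* tightly correlated surrogate blocks are planted in the TU proteome with
  matching outcome z-scores, for the grouping recovery tests;
* designated non-TU samples receive a spiked fraction of the mean TU
  proteome profile (tumor markers included), for contamination QC;
* conditioned-media matrices carry secreted-flagged genes with
  independent presence noise.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .catalogs import GeneCatalog, LigandReceptorGroup, write_lr_groups
from .containers import (
    TUMOR_MARKERS,
    ExpressionMatrix,
    Layer,
    SampleAnnotation,
)
from .io import write_expression_matrix, write_sample_annotation

CELL_TYPES = ("TU", "TAM", "TAT")
SPECIAL_GENES = (*TUMOR_MARKERS, "CD163", "MRC1")


@dataclass
class CohortConfig:
    """Generator parameters. Defaults are the cohort the pipeline is sized
    for: 24 patients x 6000 genes x 3 cell types; population mRNA-protein
    Spearman 0.5; detection midpoint at TPM 1 with class offsets tuned so
    ~50% of all genes but only ~25% of growth-factor/cytokine genes are
    detected at TPM = 1; planted coexpression sets of 13 positive and 28
    inverse ligands (TAM screen) and 41/6 secreted genes (TU matched-pair
    screen); surrogate blocks of sizes 10, 10 and 7."""

    n_patients: int = 24
    n_genes: int = 6000
    target_concordance_rho: float = 0.5
    # expression scales (natural-log units)
    mu_tpm: float = 0.5
    sd_tpm_gene: float = 1.8
    sigma_tpm: float = 0.8     # per-sample log-TPM noise (copula margin)
    sigma_lfq: float = 0.8     # per-sample log-LFQ noise (copula margin)
    lfq_log_center: float = 19.1  # ~ln(2e8)
    # gene classes
    n_membrane_receptor: int = 450
    n_secreted: int = 600
    n_growth_factor: int = 280   # subset of secreted
    n_orphan_ligand: int = 20    # subset of growth factors
    n_lipid_enzyme: int = 25
    n_lipid_receptor: int = 20
    # cell-type programs
    n_selective_per_type: int = 50
    # detection dropout (None-like switch via enabled flag)
    dropout_enabled: bool = True
    dropout_midpoint_tpm: float = 1.0
    dropout_scale: float = 1.1
    class_dropout_offsets: dict = field(
        default_factory=lambda: {"secreted": 0.6, "membrane_receptor": 0.6,
                                 "growth_factor_cytokine": 0.6}
    )
    sample_missing_rate: float = 0.3  # x (1 - detection prob), per sample
    # outcome surrogate structure
    btam_effect_beta: float = 1.16  # with sigma_tpm=0.8 -> planted pop |rho_S| ~ 0.8
    n_planted_positive: int = 13
    n_planted_negative: int = 28
    n_planted_tu_positive: int = 41
    n_planted_tu_negative: int = 6
    # surrogate blocks
    surrogate_block_sizes: tuple = (10, 10, 7)
    surrogate_block_noise_sd: float = 0.02
    # contamination
    contamination_spike: float = 0.2
    n_low_contam_tat: int = 3
    heavy_contam: bool = True  # one TAT + one TAM at 5x the low spike
    # media
    n_media_patients: int = 5
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_patients, self.n_genes) < 1:
            raise ValueError("counts must be positive")
        need = (len(SPECIAL_GENES) + self.n_membrane_receptor + self.n_secreted
                + self.n_lipid_enzyme + self.n_lipid_receptor
                + 3 * self.n_selective_per_type + sum(self.surrogate_block_sizes))
        if need > self.n_genes:
            raise ValueError(
                f"planted structure needs {need} genes but n_genes={self.n_genes}")
        if self.n_growth_factor > self.n_secreted:
            raise ValueError("growth factors are a subset of secreted")
        if self.n_planted_positive + self.n_planted_negative > self.n_growth_factor:
            raise ValueError("planted ligand sets exceed growth-factor pool")
        if self.n_planted_tu_positive + self.n_planted_tu_negative > self.n_secreted:
            raise ValueError("planted TU sets exceed secreted pool")
        if not 0.0 <= self.target_concordance_rho <= 1.0:
            raise ValueError("target_concordance_rho must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Planted structure, sufficient to score any recovery test."""

    btam_score: dict            # patient -> latent u
    gene_flags: dict            # gene -> sorted flag list
    true_concordance: float     # population Spearman per ordinary gene
    planted_positive: list
    planted_negative: list
    planted_tu_positive: list
    planted_tu_negative: list
    surrogate_blocks: list      # list of member lists
    selective_genes: dict       # cell type -> gene list
    contamination: dict         # sample -> spiked fraction
    detected_genes: list
    detection_prob: dict        # gene -> detection probability

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class Cohort:
    proteome: ExpressionMatrix
    transcriptome: ExpressionMatrix
    media: ExpressionMatrix
    annotation: SampleAnnotation
    catalog: GeneCatalog
    lr_groups: list
    zscores: pd.Series
    truth: SyntheticTruth
    config: CohortConfig

    def pairing(self) -> dict[str, str]:
        """proteome sample id -> matched transcriptome sample id."""
        return {
            s: s.replace("_P", "_R")
            for s in self.proteome.sample_ids
            if s.replace("_P", "_R") in set(self.transcriptome.sample_ids)
        }

    def write(self, outdir: str | Path) -> dict[str, Path]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteome": out / "proteome_lfq.tsv",
            "transcriptome": out / "transcriptome_tpm.tsv",
            "media": out / "media_lfq.tsv",
            "annotation": out / "samples.tsv",
            "catalog": out / "gene_catalog.tsv",
            "lr_groups": out / "lr_groups.tsv",
            "zscores": out / "zscores.tsv",
            "truth": out / "truth.json",
        }
        write_expression_matrix(self.proteome, paths["proteome"])
        write_expression_matrix(self.transcriptome, paths["transcriptome"])
        write_expression_matrix(self.media, paths["media"])
        write_sample_annotation(self.annotation, paths["annotation"])
        self.catalog.to_frame().to_csv(paths["catalog"], sep="\t", index=False)
        write_lr_groups(self.lr_groups, paths["lr_groups"])
        pd.DataFrame({"gene_id": self.zscores.index, "z": self.zscores.to_numpy()}).to_csv(
            paths["zscores"], sep="\t", index=False)
        paths["truth"].write_text(self.truth.to_json() + "\n")
        return paths


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(cfg: CohortConfig) -> Cohort:
    """Generate a full matched cohort plus ground truth (see module docs)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_g, n_p = cfg.n_genes, cfg.n_patients

    # ---- gene universe and class assignment ------------------------------
    genes = list(SPECIAL_GENES) + [f"G{i:05d}" for i in range(n_g - len(SPECIAL_GENES))]
    ordinary = [g for g in genes if g not in SPECIAL_GENES]
    pool = list(rng.permutation(ordinary))

    def take(k: int) -> list[str]:
        taken, rest = pool[:k], pool[k:]
        pool[:] = rest
        return taken

    receptors = take(cfg.n_membrane_receptor)
    secreted = take(cfg.n_secreted)
    gf = secreted[: cfg.n_growth_factor]
    orphan = gf[: cfg.n_orphan_ligand]
    lipid_enzymes = take(cfg.n_lipid_enzyme)
    lipid_receptors = take(cfg.n_lipid_receptor)
    blocks = [take(k) for k in cfg.surrogate_block_sizes]
    selective = {
        "TU": list(TUMOR_MARKERS) + take(cfg.n_selective_per_type - len(TUMOR_MARKERS)),
        "TAM": ["CD163", "MRC1"] + take(cfg.n_selective_per_type - 2),
        "TAT": take(cfg.n_selective_per_type),
    }
    planted_pos = gf[cfg.n_orphan_ligand: cfg.n_orphan_ligand + cfg.n_planted_positive]
    planted_neg = gf[cfg.n_orphan_ligand + cfg.n_planted_positive:
                     cfg.n_orphan_ligand + cfg.n_planted_positive + cfg.n_planted_negative]
    non_gf_secreted = secreted[cfg.n_growth_factor:]
    n_tu_gf = min(6, cfg.n_planted_tu_positive)
    tu_pos = (gf[-n_tu_gf:] if n_tu_gf else []) + non_gf_secreted[: cfg.n_planted_tu_positive - n_tu_gf]
    tu_neg = non_gf_secreted[cfg.n_planted_tu_positive - n_tu_gf:
                             cfg.n_planted_tu_positive - n_tu_gf + cfg.n_planted_tu_negative]

    catalog = GeneCatalog()
    for g in receptors + ["CD163", "MRC1"]:
        catalog.add(g, "membrane_receptor", "synthetic")
    for g in secreted:
        catalog.add(g, "secreted", "synthetic")
    for g in gf:
        catalog.add(g, "growth_factor_cytokine", "synthetic")
    for g in orphan:
        catalog.add(g, "orphan_ligand", "synthetic")
    for g in lipid_enzymes:
        catalog.add(g, "lipid_enzyme", "synthetic")
    for g in lipid_receptors:
        catalog.add(g, "lipid_receptor", "synthetic")

    gidx = {g: i for i, g in enumerate(genes)}

    # ---- samples ---------------------------------------------------------
    patients = [f"P{i + 1:02d}" for i in range(n_p)]
    prot_samples, rna_samples, ann_rows = [], [], []
    for ct in CELL_TYPES:
        for i, pat in enumerate(patients):
            sp, sr = f"{ct}{i + 1:02d}_P", f"{ct}{i + 1:02d}_R"
            prot_samples.append((sp, pat, ct))
            rna_samples.append((sr, pat, ct))
            ann_rows.append((sp, pat, ct, "proteome"))
            ann_rows.append((sr, pat, ct, "transcriptome"))
    n_media = min(cfg.n_media_patients, n_p)
    media_samples = []
    for ct in ("TU", "TAM"):
        for i in range(n_media):
            sm = f"{ct}{i + 1:02d}_M"
            media_samples.append((sm, patients[i], ct))
            ann_rows.append((sm, patients[i], ct, "secretome_media"))

    # ---- latent structure ------------------------------------------------
    u = rng.normal(size=n_p)                       # per-patient outcome score
    mu = rng.normal(cfg.mu_tpm, cfg.sd_tpm_gene, size=n_g)
    nu = (cfg.lfq_log_center + 0.9 * (mu - cfg.mu_tpm)
          + rng.normal(0.0, 0.7, size=n_g))
    boost = {}
    for ct, gl in selective.items():
        for g in gl:
            boost[(g, ct)] = rng.uniform(np.log(8), np.log(30))
    for g in TUMOR_MARKERS:                        # strong, variable TU markers
        boost[(g, "TU")] = rng.uniform(np.log(30), np.log(100))
    marker_patient_effect = rng.normal(0.0, 1.1, size=n_p)  # shared TU marker load

    # copula correlation for the target population Spearman
    r = 2.0 * np.sin(np.pi * cfg.target_concordance_rho / 6.0)

    n_s = len(prot_samples)  # == len(rna_samples), matched by construction
    z1 = rng.normal(size=(n_g, n_s))
    z2 = r * z1 + np.sqrt(1.0 - r * r) * rng.normal(size=(n_g, n_s))

    ln_tpm = mu[:, None] + cfg.sigma_tpm * z1
    ln_lfq = nu[:, None] + cfg.sigma_lfq * z2
    # cell-type boosts and marker patient effects
    for (g, ct), b in boost.items():
        gi = gidx[g]
        cols = [j for j, (_, _, c) in enumerate(prot_samples) if c == ct]
        ln_tpm[gi, cols] += b
        ln_lfq[gi, cols] += b
    for g in TUMOR_MARKERS:
        gi = gidx[g]
        for j, (_, pat, ct) in enumerate(prot_samples):
            if ct == "TU":
                eff = marker_patient_effect[patients.index(pat)]
                ln_tpm[gi, j] += eff
                ln_lfq[gi, j] += eff

    # bTAM surrogate markers and planted coexpression sets
    tam_cols = [j for j, (_, _, c) in enumerate(prot_samples) if c == "TAM"]
    tam_pat = [patients.index(p) for _, p, c in prot_samples if c == "TAM"]
    for g in ("CD163", "MRC1"):
        gi = gidx[g]
        ln_tpm[gi, tam_cols] = (np.log(30) + 1.2 * u[tam_pat]
                                + rng.normal(0.0, 0.15, size=len(tam_cols)))
    for g in planted_pos:
        ln_tpm[gidx[g], tam_cols] += cfg.btam_effect_beta * u[tam_pat]
    for g in planted_neg:
        ln_tpm[gidx[g], tam_cols] -= cfg.btam_effect_beta * u[tam_pat]
    tu_cols = [j for j, (_, _, c) in enumerate(prot_samples) if c == "TU"]
    tu_pat = [patients.index(p) for _, p, c in prot_samples if c == "TU"]
    for g in tu_pos:
        ln_tpm[gidx[g], tu_cols] += cfg.btam_effect_beta * u[tu_pat]
    for g in tu_neg:
        ln_tpm[gidx[g], tu_cols] -= cfg.btam_effect_beta * u[tu_pat]

    # surrogate blocks: scaled copies of a latent per-patient profile
    forced_detected = set(SPECIAL_GENES)
    for block in blocks:
        q = rng.normal(size=n_p)
        for m in block:
            gi = gidx[m]
            b_m = rng.uniform(0.8, 2.0)
            noise_p = rng.normal(0.0, cfg.surrogate_block_noise_sd, size=len(tu_cols))
            ln_lfq[gi, tu_cols] = nu[gi] + b_m * q[tu_pat] + noise_p
            ln_tpm[gi, tu_cols] = mu[gi] + 0.8 * q[tu_pat] + rng.normal(
                0.0, 0.1, size=len(tu_cols))
            forced_detected.add(m)

    tpm = np.exp(ln_tpm)
    lfq = np.exp(ln_lfq)

    # ---- protein detection dropout --------------------------------------
    offsets = np.zeros(n_g)
    for flag, off in cfg.class_dropout_offsets.items():
        for g in catalog.genes_with(flag):
            offsets[gidx[g]] += off
    med_ln_tpm = np.median(ln_tpm, axis=1)
    det_p = _sigmoid((med_ln_tpm - np.log(cfg.dropout_midpoint_tpm) - offsets)
                     / cfg.dropout_scale)
    if cfg.dropout_enabled:
        detected = rng.random(n_g) < det_p
        for g in forced_detected:
            detected[gidx[g]] = True
        lfq[~detected, :] = 0.0
        miss_rate = np.clip(cfg.sample_missing_rate * (1.0 - det_p), 0.0, 0.95)
        miss = rng.random((n_g, n_s)) < miss_rate[:, None]
        miss[~detected, :] = False
        for g in forced_detected:   # planted profiles stay fully quantified
            miss[gidx[g], :] = False
        # keep at least one quantified sample per detected gene
        all_miss = miss.all(axis=1)
        miss[all_miss, 0] = False
        lfq[miss] = 0.0
    else:
        detected = np.ones(n_g, dtype=bool)

    # ---- tumor-cell contamination spiking --------------------------------
    contamination: dict[str, float] = {}
    if cfg.contamination_spike > 0:
        mean_tu = lfq[:, tu_cols].mean(axis=1)
        tat_idx = [j for j, (_, _, c) in enumerate(prot_samples) if c == "TAT"]
        tam_idx = [j for j, (_, _, c) in enumerate(prot_samples) if c == "TAM"]
        spiked = [(j, cfg.contamination_spike) for j in tat_idx[: cfg.n_low_contam_tat]]
        if cfg.heavy_contam:
            heavy = 5.0 * cfg.contamination_spike
            if len(tat_idx) > cfg.n_low_contam_tat:
                spiked.append((tat_idx[cfg.n_low_contam_tat], heavy))
            if tam_idx:
                spiked.append((tam_idx[-1], heavy))
        for j, s in spiked:
            lfq[:, j] += s * mean_tu
            contamination[prot_samples[j][0]] = s

    # ---- media -----------------------------------------------------------
    media_rows = secreted
    med_vals = np.zeros((len(media_rows), len(media_samples)))
    for i, g in enumerate(media_rows):
        gi = gidx[g]
        p_present = 0.8 if detected[gi] else 0.35
        present = rng.random(len(media_samples)) < p_present
        vals = np.exp(nu[gi] + rng.normal(0.0, 0.7, size=len(media_samples)))
        med_vals[i] = np.where(present, vals, 0.0)

    # ---- ligand-receptor groups ------------------------------------------
    lr_groups: list[LigandReceptorGroup] = []
    gid = 0
    lig_pool = [g for g in gf if g not in orphan]
    rec_pool = list(receptors)
    li = ri = 0
    while li + 2 <= len(lig_pool) and ri + 1 <= len(rec_pool) and gid < 45:
        gid += 1
        nl = int(rng.integers(2, 5))
        nr = int(rng.integers(1, 4))
        lr_groups.append(LigandReceptorGroup(
            gid, frozenset(lig_pool[li:li + nl]), frozenset(rec_pool[ri:ri + nr])))
        li += nl
        ri += nr
    for i in range(0, len(orphan), 5):  # orphan-ligand groups
        gid += 1
        lr_groups.append(LigandReceptorGroup(
            gid, frozenset(orphan[i:i + 5]), frozenset()))
    ei = eri = 0
    for _ in range(3):  # lipid-mediator groups (enzymes on the ligand side)
        if ei + 2 > len(lipid_enzymes) or eri + 2 > len(lipid_receptors):
            break
        gid += 1
        lr_groups.append(LigandReceptorGroup(
            gid, frozenset(lipid_enzymes[ei:ei + 2]),
            frozenset(lipid_receptors[eri:eri + 2]), modality="lipid"))
        ei += 2
        eri += 2

    # ---- outcome z-scores -------------------------------------------------
    z = pd.Series(rng.normal(0.0, 1.5, size=n_g), index=genes)
    for bi, block in enumerate(blocks):
        z[block] = 5.0 if bi % 2 == 0 else -5.0
    decoys = take(5)
    z[decoys] = 4.5

    # ---- assemble ---------------------------------------------------------
    prot = ExpressionMatrix(
        pd.DataFrame(lfq, index=genes, columns=[s for s, _, _ in prot_samples]),
        Layer.LFQ)
    rna = ExpressionMatrix(
        pd.DataFrame(tpm, index=genes, columns=[s for s, _, _ in rna_samples]),
        Layer.TPM)
    media = ExpressionMatrix(
        pd.DataFrame(med_vals, index=media_rows,
                     columns=[s for s, _, _ in media_samples]),
        Layer.MEDIA)
    ann = SampleAnnotation(pd.DataFrame(
        ann_rows, columns=["sample_id", "patient_id", "cell_type", "assay"]))

    truth = SyntheticTruth(
        btam_score={p: float(v) for p, v in zip(patients, u)},
        gene_flags={g: sorted(f) for g, f in catalog.flags.items()},
        true_concordance=cfg.target_concordance_rho,
        planted_positive=list(planted_pos),
        planted_negative=list(planted_neg),
        planted_tu_positive=list(tu_pos),
        planted_tu_negative=list(tu_neg),
        surrogate_blocks=[list(b) for b in blocks],
        selective_genes={ct: list(gl) for ct, gl in selective.items()},
        contamination=contamination,
        detected_genes=[g for g, d in zip(genes, detected) if d],
        detection_prob={g: float(p) for g, p in zip(genes, det_p)},
    )
    return Cohort(prot, rna, media, ann, catalog, lr_groups, z, truth, cfg)


# ---------------------------------------------------------------------------
# worked three-set membership fixture
# ---------------------------------------------------------------------------

def worked_fixture_fig1f() -> pd.DataFrame:
    """Synthetic membership table for the growth-factor/cytokine overlap
    of transcriptome (TPM > 0.3), proteome and conditioned media.

    Region sizes are fixed so the derived overlap statistics can be
    checked against printed reference values: 44 proteome-detected factors
    of which 38 are media-detected, 224 transcriptome-but-not-proteome
    factors of which 131 are media-detected, and 62 media-only factors.
    """
    regions = [
        # (transcriptome, proteome, media, count)
        (True, True, True, 38),
        (True, True, False, 6),
        (True, False, True, 131),
        (True, False, False, 93),
        (False, False, True, 62),
    ]
    rows = []
    i = 0
    for t, p, m, count in regions:
        for _ in range(count):
            i += 1
            rows.append({"gene_id": f"GF{i:03d}", "transcriptome": t,
                         "proteome": p, "media": m})
    return pd.DataFrame(rows)
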