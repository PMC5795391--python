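"""End-to-end orchestration: qc -> impute -> concordance -> calls -> venn
-> network -> coexpression -> precog, with a reproducibility manifest.

Every stage reads the standard cohort files (see
:meth:`asciteome.synthetic.Cohort.write`) plus earlier stage outputs from
the results directory, and writes plain TSV/JSON. The manifest records the
configuration hash, the seed, input and output digests and the thresholds
actually used; a rerun with the same inputs and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calls import (
    ExpressionCallSet,
    abundant_media_table,
    call_celltype_selective,
    call_expressed_protein,
    call_expressed_rna,
    call_secretome_detected,
    call_tiers,
    tier_long_format,
    venn_partition,
)
from .catalogs import GeneCatalog, load_lr_groups
from .concordance import detection_curve, detection_deficit_pvalue, gene_concordance
from .containers import ExpressionMatrix, Layer, SampleAnnotation
from .coexpression import (
    coexpress_with_surrogate,
    groups_to_frame,
    matched_pair_coexpression,
    precog_surrogate_groups,
    surrogate_score,
)
from .io import (
    read_expression_matrix,
    read_sample_annotation,
    read_zscore_table,
    write_expression_matrix,
    write_manifest,
)
from .preprocess import (
    assess_tumor_contamination,
    exclusion_lists,
    impute_missing_lfq,
    qc_report_frame,
    select_high_variance,
)

log = logging.getLogger(__name__)

STAGES = ("qc", "impute", "concordance", "calls", "venn", "network",
          "coexpression", "precog")

#: Default thresholds (the study's printed values).
DEFAULT_CONFIG = {
    "impute": {"rel_sd": 0.59, "truncate": "resample", "vmin_scope": "global"},
    "protein_quantile": 0.25,
    "lfq_min": 5e7,
    "selective_fold": 5.0,
    "min_tpm": 2.0,
    "min_tpm_permissive": 0.3,
    "media_min_fraction": 0.5,
    "deficit": {"n_draws": 1000, "min_remaining": 20},
    "diff": {"iters": 100000, "fdr": 0.05, "min_fold": 2.0},
    "coexpression": {"pos_thr": 0.5, "neg_thr": -0.6,
                     "pair_pos_thr": 0.7, "pair_neg_thr": -0.7},
    "precog": {"z_thr": 4.0, "rna_rho_min": 0.3, "group_rho": 0.95, "min_size": 8},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    with open(path) as fh:
        return _merge(DEFAULT_CONFIG, yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineRun:
    """Stateful runner over a cohort directory; stages can run singly."""

    def __init__(self, cohort_dir: str | Path, out_dir: str | Path,
                 config: dict | None = None, seed: int = 0):
        self.cohort = Path(cohort_dir)
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.config = _merge(DEFAULT_CONFIG, config or {})
        self.seed = seed
        self.completed: list[str] = []
        self._cache: dict[str, object] = {}

    # -- inputs -----------------------------------------------------------
    def _load(self, key: str):
        if key in self._cache:
            return self._cache[key]
        loaders = {
            "proteome": lambda: read_expression_matrix(self.cohort / "proteome_lfq.tsv", Layer.LFQ),
            "transcriptome": lambda: read_expression_matrix(self.cohort / "transcriptome_tpm.tsv", Layer.TPM),
            "media": lambda: read_expression_matrix(self.cohort / "media_lfq.tsv", Layer.MEDIA),
            "annotation": lambda: read_sample_annotation(self.cohort / "samples.tsv"),
            "catalog": self._load_catalog,
            "lr_groups": lambda: load_lr_groups(self.cohort / "lr_groups.tsv"),
        }
        path_by_key = {"proteome": "proteome_lfq.tsv", "transcriptome": "transcriptome_tpm.tsv",
                       "media": "media_lfq.tsv", "annotation": "samples.tsv",
                       "catalog": "gene_catalog.tsv", "lr_groups": "lr_groups.tsv"}
        p = self.cohort / path_by_key[key]
        if not p.exists():
            raise FileNotFoundError(f"missing input: {p}")
        self._cache[key] = loaders[key]()
        return self._cache[key]

    def _load_catalog(self) -> GeneCatalog:
        df = pd.read_csv(self.cohort / "gene_catalog.tsv", sep="\t")
        cat = GeneCatalog()
        for _, row in df.iterrows():
            cat.add(str(row["gene_id"]), row["flag"], str(row.get("provenance", "")))
        return cat

    # -- stages -----------------------------------------------------------
    def stage_qc(self) -> dict:
        prot = self._load("proteome")
        ann = self._load("annotation")
        reports = assess_tumor_contamination(prot, ann)
        qc_report_frame(reports).to_csv(self.out / "qc_report.tsv", sep="\t", index=False)
        excl = exclusion_lists(reports)
        (self.out / "exclusions.json").write_text(json.dumps(excl, indent=2) + "\n")
        self.completed.append("qc")
        return excl

    def _exclusions(self) -> dict:
        p = self.out / "exclusions.json"
        return json.loads(p.read_text()) if p.exists() else {"all_analyses": [], "tumor_specificity": []}

    def _clean_proteome(self) -> ExpressionMatrix:
        prot = self._load("proteome")
        drop = set(self._exclusions()["all_analyses"])
        return prot.subset_samples([s for s in prot.sample_ids if s not in drop])

    def stage_impute(self) -> ExpressionMatrix:
        cfg = self.config["impute"]
        imputed = impute_missing_lfq(self._clean_proteome(), rel_sd=cfg["rel_sd"],
                                     seed=self.seed, truncate=cfg["truncate"],
                                     vmin_scope=cfg["vmin_scope"])
        write_expression_matrix(imputed, self.out / "imputed_lfq.tsv")
        self._cache["imputed"] = imputed
        self.completed.append("impute")
        return imputed

    def _imputed(self) -> ExpressionMatrix:
        if "imputed" not in self._cache:
            self._cache["imputed"] = read_expression_matrix(
                self.out / "imputed_lfq.tsv", Layer.LFQ)
        return self._cache["imputed"]

    def _pairing(self) -> dict[str, str]:
        ann = self._load("annotation")
        t = ann.table
        rna = t[t["assay"] == "transcriptome"].set_index(["patient_id", "cell_type"])
        pairing = {}
        for _, row in t[t["assay"] == "proteome"].iterrows():
            key = (row["patient_id"], row["cell_type"])
            if key in rna.index:
                match = rna.loc[[key], "sample_id"].iloc[0]
                pairing[row["sample_id"]] = match
        return pairing

    def stage_concordance(self) -> dict:
        imputed = self._imputed()
        tpm = self._load("transcriptome")
        cat = self._load("catalog")
        res = gene_concordance(imputed, tpm, self._pairing())
        res.per_gene.to_csv(self.out / "concordance_per_gene.tsv", sep="\t", index=False)
        summary = {"median_rho": res.median_rho,
                   "fraction_positive": res.fraction_positive,
                   "fraction_negative": res.fraction_negative,
                   "n_defined": res.n_defined}

        # detection curves: detected = any nonzero LFQ (pre-imputation)
        raw = self._clean_proteome()
        genes = [g for g in raw.data.index if g in set(tpm.data.index)]
        detected = (raw.data.loc[genes] > 0).any(axis=1)
        level = tpm.data.loc[genes].median(axis=1)
        curves = {"all": detection_curve(genes, detected, level)}
        for flag in ("secreted", "membrane_receptor", "growth_factor_cytokine"):
            sub = [g for g in genes if g in cat.genes_with(flag)]
            if sub:
                curves[flag] = detection_curve(sub, detected.loc[sub], level.loc[sub],
                                               grid=curves["all"].table["threshold"].to_numpy())
        pd.concat([c.table.assign(gene_set=k) for k, c in curves.items()]).to_csv(
            self.out / "detection_curves.tsv", sep="\t", index=False)

        dcfg = self.config["deficit"]
        rows = []
        for i, flag in enumerate(("membrane_receptor", "growth_factor_cytokine")):
            query = [g for g in genes if g in cat.genes_with(flag)]
            if not query:
                continue
            res_d = detection_deficit_pvalue(
                query, genes, detected, level, n_draws=dcfg["n_draws"],
                min_remaining=dcfg["min_remaining"], seed=self.seed + 1 + i)
            rows.append({"gene_set": flag, "p": res_d.pvalue, "p_report": res_d.p_string,
                         "n_draws": res_d.n_draws, "query_size": res_d.query_size})
            summary[f"deficit_p_{flag}"] = res_d.pvalue
        pd.DataFrame(rows).to_csv(self.out / "deficit_pvalues.tsv", sep="\t", index=False)
        (self.out / "concordance_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        self.completed.append("concordance")
        return summary

    def stage_calls(self) -> ExpressionCallSet:
        imputed = self._imputed()
        ann = self._load("annotation")
        tpm = self._load("transcriptome")
        media = self._load("media")

        expressed, thr = call_expressed_protein(imputed, ann,
                                                quantile=self.config["protein_quantile"])
        expressed.to_csv(self.out / "protein_calls.tsv", sep="\t")

        drop = set(self._exclusions()["tumor_specificity"])
        strict = imputed.subset_samples([s for s in imputed.sample_ids if s not in drop])
        selective = call_celltype_selective(strict, ann, lfq_min=self.config["lfq_min"],
                                            fold=self.config["selective_fold"])
        selective.to_csv(self.out / "selective_calls.tsv", sep="\t")

        rna = call_expressed_rna(tpm, ann, min_tpm=self.config["min_tpm"])
        rna.to_csv(self.out / "rna_calls.tsv", sep="\t")
        tiers = call_tiers(tpm, ann)
        tier_long_format(tiers).to_csv(self.out / "tiers.tsv", sep="\t", index=False)

        media_calls = call_secretome_detected(media, ann,
                                              min_fraction=self.config["media_min_fraction"])
        media_calls.to_csv(self.out / "media_calls.tsv", sep="\t")
        abundant_media_table(media, ann, min_fraction=self.config["media_min_fraction"]).to_csv(
            self.out / "abundant_media.tsv", sep="\t", index=False)

        callset = ExpressionCallSet(expressed_protein=expressed, selective_protein=selective,
                                    expressed_rna=rna, tier=tiers, media_detected=media_calls)
        callset.validate()
        (self.out / "call_thresholds.json").write_text(
            json.dumps({"protein_lfq_threshold": thr}, indent=2) + "\n")
        self._cache["callset"] = callset
        self.completed.append("calls")
        return callset

    def _callset(self) -> ExpressionCallSet:
        if "callset" not in self._cache:
            def rd(name):
                return pd.read_csv(self.out / name, sep="\t", index_col=0)
            tiers_long = pd.read_csv(self.out / "tiers.tsv", sep="\t")
            tiers = tiers_long.pivot(index="gene_id", columns="cell_type", values="tier")
            tiers.columns.name = None
            self._cache["callset"] = ExpressionCallSet(
                expressed_protein=rd("protein_calls.tsv").astype(bool),
                selective_protein=rd("selective_calls.tsv").astype(bool),
                expressed_rna=rd("rna_calls.tsv").astype(bool),
                tier=tiers,
                media_detected=rd("media_calls.tsv").astype(bool),
            )
        return self._cache["callset"]

    def stage_venn(self) -> dict:
        counts = venn_partition(self._callset().expressed_protein)
        (self.out / "venn_counts.json").write_text(json.dumps(counts, indent=2) + "\n")
        self.completed.append("venn")
        return counts

    def stage_network(self) -> dict:
        from .network import (build_interaction_map, cell_source_target_summary,
                              edges_to_frame, status_counts)
        tiers = self._callset().tier
        groups = self._load("lr_groups")
        edges, statuses = build_interaction_map(tiers, groups)
        edges_to_frame(edges).to_csv(self.out / "interaction_edges.tsv", sep="\t", index=False)
        pd.DataFrame([{"group_id": s.group_id, "status": s.status} for s in statuses]).to_csv(
            self.out / "group_status.tsv", sep="\t", index=False)
        cell_source_target_summary(edges).to_csv(self.out / "main_targets.tsv",
                                                 sep="\t", index=False)
        counts = status_counts(statuses)
        self.completed.append("network")
        return counts

    def stage_coexpression(self) -> dict:
        ann = self._load("annotation")
        tpm = self._load("transcriptome")
        cat = self._load("catalog")
        ccfg = self.config["coexpression"]

        tam = tpm.subset_samples(ann.samples_of("TAM", "transcriptome"))
        score = surrogate_score(tam)
        score.to_frame().to_csv(self.out / "surrogate_score.tsv", sep="\t")

        hv = select_high_variance(tam)
        gf = sorted((cat.genes_with("growth_factor_cytokine") & hv) - {"CD163", "MRC1"})
        _, table_gf = coexpress_with_surrogate(tam, score, gf,
                                               pos_thr=ccfg["pos_thr"], neg_thr=ccfg["neg_thr"])
        table_gf.to_csv(self.out / "coexpression_tam_gf.tsv", sep="\t", index=False)

        other = sorted(((cat.genes_with("secreted") - cat.genes_with("growth_factor_cytokine"))
                        & hv) - {"CD163", "MRC1"})
        _, table_sec = coexpress_with_surrogate(tam, score, other,
                                                pos_thr=ccfg["pos_thr"], neg_thr=ccfg["neg_thr"])
        table_sec.to_csv(self.out / "coexpression_tam_secreted.tsv", sep="\t", index=False)

        tu = tpm.subset_samples(ann.samples_of("TU", "transcriptome"))
        pat = ann.patient_of()
        _, table_tu = matched_pair_coexpression(
            tu, score, pat, pat, candidates=sorted(cat.genes_with("secreted")),
            pos_thr=ccfg["pair_pos_thr"], neg_thr=ccfg["pair_neg_thr"])
        table_tu.to_csv(self.out / "coexpression_tu.tsv", sep="\t", index=False)

        self.completed.append("coexpression")
        return {
            "tam_gf_hits": int((table_gf["direction"] != "").sum()),
            "tam_secreted_hits": int((table_sec["direction"] != "").sum()),
            "tu_pair_hits": int((table_tu["direction"] != "").sum()),
        }

    def stage_precog(self) -> dict:
        zpath = self.cohort / "zscores.tsv"
        if not zpath.exists():
            log.warning("no z-score table at %s; precog stage skipped", zpath)
            return {"skipped": True}
        z = read_zscore_table(zpath)
        ann = self._load("annotation")
        imputed = self._imputed()
        tpm = self._load("transcriptome")
        tu_prot = imputed.subset_samples(ann.samples_of("TU", "proteome"))
        tu_tpm = tpm.subset_samples(ann.samples_of("TU", "transcriptome"))
        pairing = {p: t for p, t in self._pairing().items() if p in set(tu_prot.sample_ids)}
        pcfg = self.config["precog"]
        merged, premerge = precog_surrogate_groups(
            tu_prot, tu_tpm, z, pairing=pairing, z_thr=pcfg["z_thr"],
            rna_rho_min=pcfg["rna_rho_min"], group_rho=pcfg["group_rho"],
            min_size=pcfg["min_size"])
        groups_to_frame(merged).to_csv(self.out / "surrogate_groups.tsv", sep="\t", index=False)
        groups_to_frame(premerge).to_csv(self.out / "surrogate_groups_premerge.tsv",
                                         sep="\t", index=False)
        self.completed.append("precog")
        return {"n_groups": len(merged), "n_premerge": len(premerge)}

    # -- manifest / run-all ----------------------------------------------
    def write_manifest(self) -> dict:
        inputs = {p.name: _sha256(p) for p in sorted(self.cohort.glob("*"))
                  if p.is_file()}
        outputs = {p.name: _sha256(p) for p in sorted(self.out.glob("*"))
                   if p.is_file() and p.name != "manifest.json"}
        manifest = {
            "version": __version__,
            "seed": self.seed,
            "config": self.config,
            "config_hash": hashlib.sha256(
                json.dumps(self.config, sort_keys=True).encode()).hexdigest(),
            "stages": list(self.completed),
            "inputs": inputs,
            "outputs": outputs,
            "exclusions": self._exclusions(),
        }
        write_manifest(manifest, self.out / "manifest.json")
        return manifest

    def run_all(self) -> dict:
        self.stage_qc()
        self.stage_impute()
        self.stage_concordance()
        self.stage_calls()
        self.stage_venn()
        self.stage_network()
        self.stage_coexpression()
        self.stage_precog()
        return self.write_manifest()


def run_all(cohort_dir: str | Path, out_dir: str | Path,
            config: dict | None = None, seed: int = 0) -> dict:
    """Run every stage over a cohort directory; returns the manifest."""
    return PipelineRun(cohort_dir, out_dir, config=config, seed=seed).run_all()
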