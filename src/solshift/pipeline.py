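"""End-to-end orchestration: preprocess -> QC -> differential statistics ->
rank shifts -> anchor correlations -> GSEA -> peptide tests.

``run_pipeline`` is a pure function of (inputs, config, seed): it executes
the enabled stages in order, writes TSV outputs per stage plus a
machine-readable JSON manifest (parameters, seed, package version, input
hashes, stages completed) into the output directory, and returns the
in-memory results bundle.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .containers import QuantMatrix, SampleMeta, SolshiftError
from .correlation import anchor_correlations
from .gsea import gsea_preranked, simplify_terms
from .io import (
    load_tau_2n4r,
    read_fasta_single,
    read_gmt,
    read_peptide_table,
    read_quant_table,
    read_sample_meta,
)
from .model import FDR_THRESHOLD, LFC_THRESHOLD, SolubilityLM, significant_summary
from .peptides import map_peptides_to_isoform, sum_peptide_detections, test_peptides_by_fraction
from .preprocess import (
    call_presence,
    filter_by_detection,
    impute_knn,
    modified_zscore,
    sparse_abundance_summary,
)
from .qc import covariate_group_anova, pca_qc
from .solubility import rank_shift

ALL_STAGES = (
    "preprocess",
    "qc",
    "diffstats",
    "rank_shift",
    "correlation",
    "gsea",
    "peptides",
)


@dataclass
class PipelineConfig:
    """Inputs, stage toggles and parameters for one run."""

    quant_path: str | None = None
    meta_path: str | None = None
    peptide_path: str | None = None
    reference_fasta: str | None = None  # default: packaged 2N4R tau
    gene_sets_path: str | None = None
    out_dir: str = "solshift_out"
    stages: tuple[str, ...] = ALL_STAGES
    min_detect: float = 0.5
    knn_k: int = 10
    lfc_threshold: float = LFC_THRESHOLD
    fdr_threshold: float = FDR_THRESHOLD
    rho_threshold: float = 0.7
    drop_low_variance_fraction: float = 0.3
    anchors: tuple[str, ...] = ()
    n_perm: int = 1000
    gsea_min_size: int = 5
    simplify_similarity: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise SolshiftError(f"unknown stages: {sorted(unknown)}")
        if not (0 < self.min_detect <= 1):
            raise SolshiftError("min_detect must be in (0, 1]")
        if not (0 < self.fdr_threshold < 1):
            raise SolshiftError("fdr_threshold must be in (0, 1)")
        if self.lfc_threshold < 0 or self.rho_threshold < 0:
            raise SolshiftError("thresholds must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("stages", "anchors"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    matrix: QuantMatrix | None = None,
    meta: SampleMeta | None = None,
    peptide_detections: pd.DataFrame | None = None,
    gene_sets: dict | None = None,
) -> dict:
    """Run the enabled stages; returns the results bundle.

    Inputs may be passed in memory (as from the synthetic generator) or
    read from the paths in the config.  Any stage failure aborts with the
    stage name in the message.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    input_hashes = {}
    for label, path in (
        ("quant", config.quant_path),
        ("meta", config.meta_path),
        ("peptides", config.peptide_path),
        ("gene_sets", config.gene_sets_path),
        ("reference", config.reference_fasta),
    ):
        if path is not None:
            input_hashes[label] = _sha256(path)

    if matrix is None:
        if config.quant_path is None:
            raise SolshiftError("no quant matrix provided (path or in-memory)")
        matrix = read_quant_table(config.quant_path, scale="raw")
    if meta is None:
        if config.meta_path is None:
            raise SolshiftError("no sample metadata provided (path or in-memory)")
        meta = read_sample_meta(config.meta_path)
    meta.check_matches(matrix)

    results: dict = {"config": config}
    completed: list[str] = []

    def stage(name: str) -> bool:
        return name in config.stages

    try:
        if stage("preprocess"):
            log2 = matrix.log2() if matrix.scale == "raw" else matrix
            normalized = modified_zscore(log2)
            filtered, excluded = filter_by_detection(normalized, config.min_detect)
            imputed = impute_knn(filtered, k=config.knn_k)
            presence = call_presence(matrix, meta)
            sparse_ids = presence.calls.index[
                (presence.calls == "sparse").any(axis=1)
            ].tolist()
            sparse_summary = sparse_abundance_summary(matrix, sparse_ids)
            results.update(
                normalized=normalized,
                imputed=imputed,
                excluded=excluded,
                presence=presence,
                sparse_summary=sparse_summary,
            )
            from .io import write_quant_table

            write_quant_table(imputed, out / "normalized_imputed.tsv")
            pd.Series(excluded, name="protein").to_csv(
                out / "excluded_features.tsv", sep="\t", index=False
            )
            presence.calls.to_csv(out / "presence_calls.tsv", sep="\t")
            completed.append("preprocess")
    except SolshiftError as err:
        raise SolshiftError(f"stage preprocess failed: {err}") from err

    try:
        if stage("qc"):
            report = pca_qc(
                matrix, meta, drop_low_variance_fraction=config.drop_low_variance_fraction
            )
            anovas = {}
            for cov in ("age", "pmd"):
                if cov in meta.table.columns and meta.table[cov].notna().all():
                    anovas[cov] = covariate_group_anova(meta, cov)
            results.update(qc=report, covariate_anova=anovas)
            report.scores.to_csv(out / "pca_scores.tsv", sep="\t")
            report.covariate_correlations.to_csv(
                out / "pca_covariate_correlations.tsv", sep="\t", index=False
            )
            completed.append("qc")
    except SolshiftError as err:
        raise SolshiftError(f"stage qc failed: {err}") from err

    fit = None
    contrast_families: dict[str, dict] = {}
    try:
        if stage("diffstats"):
            if "imputed" not in results:
                raise SolshiftError("diffstats requires the preprocess stage")
            fit = SolubilityLM(results["imputed"], meta).fit()
            kw = dict(
                lfc_threshold=config.lfc_threshold, fdr_threshold=config.fdr_threshold
            )
            contrast_families = {
                "soluble": fit.all_pairwise("soluble", **kw),
                "insoluble": fit.all_pairwise("insoluble", **kw),
                "shift": fit.all_pairwise("shift", **kw),
            }
            results.update(fit=fit, contrasts=contrast_families)
            for family, tables in contrast_families.items():
                for (a, b), table in tables.items():
                    table.to_csv(out / f"diff_{family}_{a}_vs_{b}.tsv", sep="\t")
            flat = {
                f"{family}:{a}-{b}": t
                for family, tables in contrast_families.items()
                for (a, b), t in tables.items()
            }
            significant_summary(flat).to_csv(
                out / "significant_counts.tsv", sep="\t", index=False
            )
            completed.append("diffstats")
    except SolshiftError as err:
        raise SolshiftError(f"stage diffstats failed: {err}") from err

    try:
        if stage("rank_shift"):
            if "imputed" not in results:
                raise SolshiftError("rank_shift requires the preprocess stage")
            ranks = rank_shift(results["imputed"], meta)
            results["ranks"] = ranks
            ranks.ranks.to_csv(out / "ranks.tsv", sep="\t")
            ranks.shifts.to_csv(out / "rank_shifts.tsv", sep="\t")
            completed.append("rank_shift")
    except SolshiftError as err:
        raise SolshiftError(f"stage rank_shift failed: {err}") from err

    try:
        if stage("correlation") and config.anchors:
            if "imputed" not in results:
                raise SolshiftError("correlation requires the preprocess stage")
            corr = {}
            for anchor in config.anchors:
                for disease in meta.diseases:
                    res = anchor_correlations(
                        results["imputed"], meta, anchor, disease,
                        threshold=config.rho_threshold,
                    )
                    corr[(anchor, disease)] = res
                    res.table.to_csv(
                        out / f"bicor_{anchor}_{disease}.tsv", sep="\t"
                    )
            results["correlations"] = corr
            completed.append("correlation")
        elif stage("correlation"):
            completed.append("correlation")  # nothing to do without anchors
    except SolshiftError as err:
        raise SolshiftError(f"stage correlation failed: {err}") from err

    try:
        if stage("gsea"):
            if gene_sets is None and config.gene_sets_path is not None:
                gene_sets = read_gmt(config.gene_sets_path)
            if gene_sets:
                if fit is None:
                    raise SolshiftError("gsea requires the diffstats stage")
                enrich = {}
                for family, tables in contrast_families.items():
                    for (a, b), table in tables.items():
                        res = gsea_preranked(
                            table["t"],
                            gene_sets,
                            n_perm=config.n_perm,
                            min_size=config.gsea_min_size,
                            seed=config.seed,
                        )
                        res = simplify_terms(res, config.simplify_similarity)
                        enrich[(family, a, b)] = res
                        res.table.drop(columns=["members", "leading_edge"]).to_csv(
                            out / f"gsea_{family}_{a}_vs_{b}.tsv", sep="\t"
                        )
                results["gsea"] = enrich
            completed.append("gsea")
    except SolshiftError as err:
        raise SolshiftError(f"stage gsea failed: {err}") from err

    try:
        if stage("peptides"):
            if peptide_detections is None and config.peptide_path is not None:
                peptide_detections = read_peptide_table(config.peptide_path)
            if peptide_detections is not None:
                reference = (
                    read_fasta_single(config.reference_fasta)
                    if config.reference_fasta
                    else load_tau_2n4r()
                )
                summed = sum_peptide_detections(peptide_detections)
                mapping = map_peptides_to_isoform(summed.index, reference)
                tests = test_peptides_by_fraction(summed, meta)
                results.update(
                    peptide_abundance=summed,
                    peptide_mapping=mapping,
                    peptide_tests=tests,
                )
                summed.to_csv(out / "peptide_summed.tsv", sep="\t")
                mapping.to_csv(out / "peptide_mapping.tsv", sep="\t")
                tests.to_csv(out / "peptide_tests.tsv", sep="\t", index=False)
            completed.append("peptides")
    except SolshiftError as err:
        raise SolshiftError(f"stage peptides failed: {err}") from err

    manifest = {
        "package": "solshift",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if not k.endswith("_path")
        },
        "input_hashes": input_hashes,
        "stages_completed": completed,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str, sort_keys=True)
    results["manifest"] = manifest
    return results
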