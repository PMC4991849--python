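"""End-to-end orchestration: preprocess -> PCA -> staging -> strain
patterns -> DLCS -> stage-transition SAM -> gene-set statistics.

Configured by :class:`PipelineConfig` (YAML-friendly); every step writes
its artifacts under the output directory and contributes row/column counts
and parameters to a JSON run manifest, so each output is re-derivable from
the manifest plus the inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .containers import ExpressionMatrix, ProbeIntensityTable
from .decompose import run_pca, strain_profile_correlation
from .dlcs import DEFAULT_FRACTIONS, bimodality_diagnostic, build_dlcs
from .genesets import HomologyTable, TermCollection, hypergeometric_enrichment, map_homologs
from .preprocess import PreprocessConfig, run_preprocess, variance_filter, zscore_rows
from .samde import stage_transition_de
from .staging import build_stage_map, fit_additive_model, fit_stage_model
from .strainpat import classify_genes, summarize_classes

logger = logging.getLogger("lungdev")


@dataclass
class PipelineConfig:
    """Paths, parameters and options for a full pipeline run."""

    # inputs: either a probe-level table or a gene-level matrix
    probe_table: str | None = None
    matrix: str | None = None
    metadata: str | None = None
    snp_annotation: str | None = None
    gmt: str | None = None
    homology_table: str | None = None

    # preprocessing
    variance_fraction: float = 0.30
    log2: bool = True
    drop_unannotated_probes: bool = False
    tol: float = 1e-6
    max_iter: int = 100

    # PCA / staging
    pca_k: int = 10
    staging_components: list[str] = field(
        default_factory=lambda: ["PC1", "PC2", "PC3"])
    n_stages: int = 9
    must_link: list[list[str]] = field(default_factory=list)
    fdr_q: float = 0.1

    # strain patterns / DLCS / SAM / enrichment
    hsd_alpha: float = 0.05
    dlcs_fractions: dict[str, list[float]] = field(
        default_factory=lambda: {c: list(v) for c, v in DEFAULT_FRACTIONS.items()})
    sam_n_perm: int = 300
    enrich_q: float = 0.05

    outdir: str = "lungdev_out"
    seed: int = 17

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.probe_table is None and self.matrix is None:
            raise ValueError("config needs 'probe_table' or 'matrix'")
        if self.metadata is None:
            raise ValueError("config field 'metadata' is required")
        for name in ("probe_table", "matrix", "metadata", "snp_annotation",
                     "gmt", "homology_table"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ValueError(f"config field '{name}': no such file {path}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": asdict(config), "steps": []}

    def record(step: str, **info):
        manifest["steps"].append({"step": step, **info})
        logger.info("step %s: %s", step, info)

    # 1. preprocess ---------------------------------------------------------
    if config.probe_table is not None:
        table = ProbeIntensityTable.from_tsv(config.probe_table, config.metadata)
        annotation = None
        if config.snp_annotation is not None:
            ann = pd.read_csv(config.snp_annotation, sep="\t")
            annotation = dict(zip(ann["probe_id"], ann["snp_flag"].astype(bool)))
        matrix = run_preprocess(
            table,
            PreprocessConfig(config.variance_fraction, config.log2,
                             config.drop_unannotated_probes, config.tol,
                             config.max_iter),
            annotation,
        )
    else:
        matrix = ExpressionMatrix.from_tsv(config.matrix, config.metadata)
        if not matrix.standardized:
            matrix = variance_filter(zscore_rows(matrix), config.variance_fraction)
    matrix.to_tsv(out / "matrix.tsv", out / "sample_meta.tsv")
    record("preprocess", genes=matrix.n_genes, samples=matrix.n_samples)

    # 2. PCA ----------------------------------------------------------------
    pca = run_pca(matrix, K=config.pca_k)
    pca.loadings.to_csv(out / "gene_loadings.tsv", sep="\t", index_label="gene_id")
    pca.scores.to_csv(out / "sample_scores.tsv", sep="\t", index_label="sample_id")
    with open(out / "variance_fractions.json", "w") as fh:
        json.dump(pca.var_frac.round(6).to_dict(), fh, indent=1)
    corr = strain_profile_correlation(pca)
    corr.to_frame().to_csv(out / "strain_correlations.tsv", sep="\t", index=False)
    record("pca", k=pca.K, var_frac_pc1=round(float(pca.var_frac.iloc[0]), 4))

    # 3. staging ------------------------------------------------------------
    tp_fit = fit_additive_model(pca.scores, matrix.sample_meta)
    tp_fit.apply_fdr(config.fdr_q)
    tp_fit.timepoint_effects.to_csv(out / "timepoint_effects.tsv", sep="\t",
                                    index_label="timepoint")
    effects = tp_fit.timepoint_effects[config.staging_components]
    stagemap = build_stage_map(effects, n_stages=config.n_stages,
                               must_link=[tuple(p) for p in config.must_link])
    stagemap.to_json(out / "stage_map.json")
    stagemap.to_tsv(out / "stage_map.tsv")
    stage_fit = fit_stage_model(pca.scores, matrix.sample_meta, stagemap)
    stage_fit.apply_fdr(config.fdr_q)
    stage_fit.pvalues.to_csv(out / "stage_model_pvalues.tsv", sep="\t",
                             index_label="component")
    record("staging", stages=stagemap.stage_names)

    # 4. strain patterns ----------------------------------------------------
    patterns = classify_genes(matrix, alpha=config.hsd_alpha)
    patterns.to_tsv(out / "strain_patterns.tsv")
    summary = summarize_classes(patterns)
    summary.to_csv(out / "strain_class_summary.tsv", sep="\t", index=False)
    record("strainpat",
           classified=int((patterns.calls["cls"] != "none").sum()))

    # 5. DLCS ---------------------------------------------------------------
    fractions = {c: tuple(v) for c, v in config.dlcs_fractions.items()}
    subtx = build_dlcs(pca, fractions)
    subtx.write_genes(out / "dlcs_genes.txt")
    subtx.provenance.to_csv(out / "dlcs_provenance.tsv", sep="\t", index=False)
    bimod = {c: bimodality_diagnostic(pca.loadings[c])[1]
             for c in fractions if c in pca.loadings.columns}
    record("dlcs", size=len(subtx), bimodality=bimod)

    # 6. SAM stage transitions ---------------------------------------------
    transitions = stage_transition_de(matrix, stagemap,
                                      n_perm=config.sam_n_perm, seed=config.seed)
    sam_counts = {}
    for (a, b), res in transitions.items():
        res.to_frame().to_csv(out / f"sam_{a}_to_{b}.tsv", sep="\t", index=False)
        sam_counts[f"{a}->{b}"] = {"up": len(res.called_up),
                                   "down": len(res.called_down)}
    record("samde", transitions=sam_counts)

    # 7. gene-set statistics ------------------------------------------------
    geneset_info = {}
    universe = set(matrix.gene_ids)
    if config.gmt is not None:
        terms = TermCollection.from_gmt(config.gmt)
        enr = hypergeometric_enrichment(sorted(subtx.genes & universe), terms,
                                        universe, q=config.enrich_q)
        enr.to_csv(out / "dlcs_enrichment.tsv", sep="\t", index=False)
        geneset_info["terms_tested"] = len(enr)
        geneset_info["terms_significant"] = int(enr["significant"].sum()) \
            if not enr.empty else 0
    if config.homology_table is not None:
        homology = HomologyTable.from_tsv(config.homology_table)
        mapped, unmapped = map_homologs(sorted(subtx.genes), homology)
        with open(out / "dlcs_homologs.txt", "w") as fh:
            fh.write("\n".join(mapped) + "\n")
        geneset_info["homologs_mapped"] = len(mapped)
        geneset_info["homologs_unmapped"] = len(unmapped)
    record("genesets", **geneset_info)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
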