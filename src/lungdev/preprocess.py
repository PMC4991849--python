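"""Probe-level intensities to the filtered, standardized gene x sample matrix.

Fixed order of operations: SNP-probe removal -> log2 -> quantile
normalization -> per-gene Tukey median polish summarization -> per-gene
z-score -> variance filter on the pre-z-score standard deviation.  Sample
standard deviations use the n-1 denominator throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ProbeIntensityTable

logger = logging.getLogger("lungdev")


@dataclass
class PreprocessConfig:
    variance_fraction: float = 0.30
    log2: bool = True
    drop_unannotated_probes: bool = False
    tol: float = 1e-6
    max_iter: int = 100


def remove_snp_probes(table: ProbeIntensityTable,
                      annotation: dict[str, bool] | None = None,
                      drop_unannotated: bool = False) -> ProbeIntensityTable:
    """Drop probes overlapping SNPs that segregate among the strains.

    ``annotation`` maps probe id -> flag; when None the table's own
    ``snp_flag`` column is used.  Genes left without any probe are dropped
    (and counted in the log).  An empty result is an error.
    """
    df = table.table
    if annotation is None:
        flagged = df["snp_flag"].to_numpy(bool)
    else:
        known = df["probe_id"].map(annotation)
        if drop_unannotated:
            flagged = known.fillna(True).to_numpy(bool)
        else:
            flagged = known.fillna(False).to_numpy(bool)
    kept = df.loc[~flagged].copy()
    if kept.empty:
        raise ValueError("SNP-probe removal left an empty probe table")
    genes_before = set(df["gene_id"])
    genes_after = set(kept["gene_id"])
    dropped_genes = genes_before - genes_after
    logger.info("remove_snp_probes: dropped %d/%d probes; %d genes lost all probes",
                int(flagged.sum()), df["probe_id"].nunique(), len(dropped_genes))
    kept["snp_flag"] = False
    return ProbeIntensityTable(kept.reset_index(drop=True), table.sample_meta)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force all columns onto the cross-column rank-mean reference
    distribution; within-column rank order is preserved.

    Tied values within a column receive the mean of the reference values at
    their rank positions.  Missing values are an error.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least two columns")
    if matrix.isna().any().any():
        raise ValueError("missing values are not supported")
    X = matrix.to_numpy(float)
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        assigned = np.empty(X.shape[0])
        assigned[order] = ref
        # average reference values over ties
        col = pd.Series(assigned)
        out[:, j] = col.groupby(pd.Series(X[:, j])).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def median_polish(X: np.ndarray, tol: float = 1e-6, max_iter: int = 100):
    """Tukey's iterative row/column median sweep.

    Returns ``(grand, row_effects, col_effects, residuals, converged)`` with
    grand + row + col + residual reconstructing the input exactly.  Sweeps
    rows then columns; the medians of the effect vectors are folded into the
    grand term each pass.  Convergence: maximum absolute change in any
    effect below ``tol``.
    """
    R = np.asarray(X, dtype=float).copy()
    nr, nc = R.shape
    grand = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    converged = False
    for _ in range(max_iter):
        delta = 0.0
        rmed = np.median(R, axis=1)
        R -= rmed[:, None]
        row += rmed
        delta = max(delta, float(np.max(np.abs(rmed))) if nr else 0.0)
        cmed_of_row = float(np.median(col))
        col -= cmed_of_row
        grand += cmed_of_row
        delta = max(delta, abs(cmed_of_row))

        cmed = np.median(R, axis=0)
        R -= cmed[None, :]
        col += cmed
        delta = max(delta, float(np.max(np.abs(cmed))) if nc else 0.0)
        rmed_of_col = float(np.median(row))
        row -= rmed_of_col
        grand += rmed_of_col
        delta = max(delta, abs(rmed_of_col))
        if delta < tol:
            converged = True
            break
    return grand, row, col, R, converged


def median_polish_summarize(table: ProbeIntensityTable, log2: bool = True,
                            tol: float = 1e-6, max_iter: int = 100,
                            pre_normalized: pd.DataFrame | None = None
                            ) -> ExpressionMatrix:
    """Summarize probe intensities to one value per gene per sample.

    Per gene, Tukey median polish decomposes the probe x sample log2 matrix
    into grand + probe + sample + residual; the gene-level value for a
    sample is grand + sample effect.  ``pre_normalized`` optionally supplies
    an already log2/quantile-normalized probe x sample wide matrix.
    """
    if pre_normalized is not None:
        wide = pre_normalized
    else:
        wide = probe_wide_matrix(table, log2=log2)
    probe_gene = table.probe_gene_map()
    sample_ids = list(table.sample_meta.index)
    wide = wide[sample_ids]
    rows = {}
    n_nonconv = 0
    for gene, sub in wide.groupby(wide.index.map(probe_gene), sort=True):
        grand, r, c, resid, conv = median_polish(sub.to_numpy(), tol, max_iter)
        if not conv:
            n_nonconv += 1
            logger.warning("median polish did not converge for gene %s "
                           "after %d iterations; using current estimate",
                           gene, max_iter)
        rows[gene] = grand + c
    values = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    if n_nonconv:
        logger.info("median polish: %d/%d genes stopped at max_iter",
                    n_nonconv, len(rows))
    return ExpressionMatrix(values.sort_index(), table.sample_meta.copy())


def probe_wide_matrix(table: ProbeIntensityTable, log2: bool = True) -> pd.DataFrame:
    """Pivot the long probe table to probe x sample, optionally log2-scaled."""
    wide = table.table.pivot(index="probe_id", columns="sample_id",
                             values="intensity")
    if wide.isna().any().any():
        raise ValueError("probe table is not complete over samples")
    if log2:
        if (wide <= 0).any().any():
            raise ValueError("intensities must be positive for log2")
        wide = np.log2(wide)
    return wide


def zscore_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene to mean 0 / SD 1 across samples (n-1 SD).

    Genes with zero variance are dropped with a log entry.  The
    pre-standardization SD is recorded for the later variance filter.
    Idempotent: an already standardized row is unchanged.
    """
    vals = matrix.values
    sd = vals.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.info("zscore_rows: dropping %d constant genes", int((~keep).sum()))
    vals = vals.loc[keep]
    sd = sd.loc[keep]
    z = vals.sub(vals.mean(axis=1), axis=0).div(sd, axis=0)
    if matrix.standardized and matrix.pre_z_sd is not None:
        pre = matrix.pre_z_sd.loc[keep]
    else:
        pre = sd.rename("pre_z_sd")
    return ExpressionMatrix(z, matrix.sample_meta.copy(), pre, standardized=True)


def variance_filter(matrix: ExpressionMatrix, fraction: float = 0.30
                    ) -> ExpressionMatrix:
    """Retain the ceil(fraction * G) genes with the largest pre-z-score SD.

    Deterministic: ties in SD are broken lexicographically by gene id.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if matrix.pre_z_sd is None:
        raise ValueError("variance filter requires the pre-z-score SD record")
    G = matrix.n_genes
    k = math.ceil(fraction * G)
    ranking = pd.DataFrame({"sd": matrix.pre_z_sd.loc[matrix.values.index]})
    ranking["gene"] = ranking.index
    ranking = ranking.sort_values(["sd", "gene"], ascending=[False, True])
    kept = sorted(ranking.head(k)["gene"])
    logger.info("variance_filter: retained %d/%d genes (fraction=%.2f)", k, G, fraction)
    return matrix.subset_genes(kept)


def run_preprocess(table: ProbeIntensityTable,
                   config: PreprocessConfig | None = None,
                   annotation: dict[str, bool] | None = None) -> ExpressionMatrix:
    """The full chain: SNP removal -> log2 -> quantile normalize ->
    median polish -> z-score -> variance filter."""
    cfg = config or PreprocessConfig()
    clean = remove_snp_probes(table, annotation,
                              drop_unannotated=cfg.drop_unannotated_probes)
    wide = probe_wide_matrix(clean, log2=cfg.log2)
    norm = quantile_normalize(wide)
    summarized = median_polish_summarize(clean, log2=cfg.log2, tol=cfg.tol,
                                         max_iter=cfg.max_iter,
                                         pre_normalized=norm)
    standardized = zscore_rows(summarized)
    filtered = variance_filter(standardized, cfg.variance_fraction)
    logger.info("run_preprocess: %d genes x %d samples after full chain",
                filtered.n_genes, filtered.n_samples)
    return filtered
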