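"""PCA of the standardized expression matrix.

Samples are the observations and genes the (already row-standardized)
variables, so the decomposition runs on the transposed gene x sample grid
without further centering.  Singular value decomposition X = U S V^T of
the sample x gene matrix yields

* sample scores  U_k s_k (one coordinate per sample per component),
* raw gene loadings V (unit singular vectors), and
* correlation loadings V_k s_k / sqrt(S - 1), which for z-scored genes
  equal the Pearson correlation between each gene's expression profile and
  the component's score profile.

Variance fractions are s_k^2 / sum s^2.  Signs are fixed deterministically:
each component is flipped so its largest-magnitude gene loading is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, order_timepoints

logger = logging.getLogger("lungdev")


@dataclass
class PCAResult:
    """Gene loadings, sample scores and variance fractions for K components."""

    loadings: pd.DataFrame        # gene x K, correlation-scaled
    raw_loadings: pd.DataFrame    # gene x K, unit singular vectors
    scores: pd.DataFrame          # sample x K
    var_frac: pd.Series           # K fractions of total variance
    singular_values: pd.Series
    sign_record: pd.Series        # +1/-1 flip applied per component
    sample_meta: pd.DataFrame

    @property
    def K(self) -> int:
        return self.scores.shape[1]

    @property
    def components(self) -> list[str]:
        return list(self.scores.columns)

    def reconstruct(self) -> pd.DataFrame:
        """Gene x sample reconstruction from the retained components."""
        approx = self.raw_loadings.to_numpy() @ np.diag(
            self.singular_values.to_numpy()) @ \
            (self.scores.to_numpy() / self.singular_values.to_numpy()).T
        return pd.DataFrame(approx, index=self.loadings.index,
                            columns=self.scores.index)


def run_pca(matrix: ExpressionMatrix, K: int = 10) -> PCAResult:
    """SVD-based PCA of a standardized gene x sample matrix."""
    if not matrix.standardized:
        raise ValueError("PCA expects a row-standardized matrix")
    G, S = matrix.n_genes, matrix.n_samples
    max_rank = min(G, S)
    if K > max_rank:
        raise ValueError(f"K={K} exceeds the matrix rank bound {max_rank}")
    X = matrix.values.to_numpy().T  # samples x genes
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float(np.sum(s ** 2))
    comp = [f"PC{i+1}" for i in range(K)]
    V = Vt[:K].T                      # gene x K
    signs = np.ones(K)
    for k in range(K):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            signs[k] = -1.0
    V = V * signs
    scoresU = U[:, :K] * signs
    scores = scoresU * s[:K]
    corr_loadings = V * (s[:K] / np.sqrt(max(S - 1, 1)))
    result = PCAResult(
        loadings=pd.DataFrame(corr_loadings, index=matrix.gene_ids, columns=comp),
        raw_loadings=pd.DataFrame(V, index=matrix.gene_ids, columns=comp),
        scores=pd.DataFrame(scores, index=matrix.sample_ids, columns=comp),
        var_frac=pd.Series(s[:K] ** 2 / total, index=comp),
        singular_values=pd.Series(s[:K], index=comp),
        sign_record=pd.Series(signs, index=comp),
        sample_meta=matrix.sample_meta.copy(),
    )
    logger.info("PCA: %d components, leading variance fractions %s",
                K, np.round(result.var_frac.to_numpy()[:3], 3))
    return result


@dataclass
class StrainCorrelation:
    """Pairwise strain R^2 between mean score profiles, per component.

    ``r2`` is indexed by (component, strain_a, strain_b) with strain_a <
    strain_b lexicographically; undefined pairs (fewer than 3 shared time
    points after the lag shift) hold NaN.
    """

    r2: pd.Series
    lag: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = self.r2.rename("r2").reset_index()
        df.columns = ["component", "strain_a", "strain_b", "r2"]
        df["lag"] = self.lag
        return df


def strain_profile_correlation(pca: PCAResult, lag: int = 0) -> StrainCorrelation:
    """Pearson R^2 between per-strain mean score profiles over shared
    time points, per component and strain pair.

    Replicates are averaged per (strain, time point).  ``lag`` shifts the
    second strain's profile by whole time-point steps; time points sampled
    in only one strain of a pair (e.g. an A/J-only E19.5) drop out of that
    pair's overlap.
    """
    meta = pca.sample_meta
    strains = sorted(meta["strain"].unique())
    records = {}
    profiles = {}
    for strain in strains:
        sub = meta.index[meta["strain"] == strain]
        sc = pca.scores.loc[sub]
        tp = meta.loc[sub, "timepoint"]
        prof = sc.groupby(tp.values).mean()
        profiles[strain] = prof.loc[order_timepoints(prof.index)]
    for comp in pca.components:
        for a, b in [(x, y) for i, x in enumerate(strains)
                     for y in strains[i + 1:]]:
            pa, pb = profiles[a][comp], profiles[b][comp]
            if lag == 0:
                shared = [t for t in pa.index if t in set(pb.index)]
                va = pa.loc[shared].to_numpy()
                vb = pb.loc[shared].to_numpy()
            else:
                shared = [t for t in pa.index if t in set(pb.index)]
                va_full = pa.loc[shared].to_numpy()
                vb_full = pb.loc[shared].to_numpy()
                if lag > 0:
                    va, vb = va_full[lag:], vb_full[:-lag]
                else:
                    va, vb = va_full[:lag], vb_full[-lag:]
            if len(va) < 3 or np.std(va) == 0 or np.std(vb) == 0:
                records[(comp, a, b)] = np.nan
                continue
            r, _ = stats.pearsonr(va, vb)
            records[(comp, a, b)] = r ** 2
    idx = pd.MultiIndex.from_tuples(records.keys(),
                                    names=["component", "strain_a", "strain_b"])
    return StrainCorrelation(pd.Series(records.values(), index=idx), lag=lag)
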