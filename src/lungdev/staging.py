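"""Molecular staging of the developmental time course.

Per-component sample scores (from :mod:`lungdev.decompose`) are modelled by
least squares with sum-to-zero effect coding:

* additive model:  score = mu + a(timepoint) + b(strain) + error
* stage model:     score = mu + d(stage) + b(strain) + g(stage, strain) + error

Time-point effects from the additive model are then segmented into
contiguous "molecular stages" by exact dynamic programming over contiguous
partitions, minimizing the within-stage sum of squared deviations of the
multi-component effect vectors.  The canonical nine-stage solution carries
the names EMB, PSG, CAN, SAC, ALV1-ALV4, MAT; whole-embryo samples (E9.5)
are kept apart under the WE label and excluded from lung-stage inference.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import order_timepoints

logger = logging.getLogger("lungdev")

#: canonical molecular stage names in developmental order (lung stages only)
CANONICAL_STAGES = ["EMB", "PSG", "CAN", "SAC", "ALV1", "ALV2", "ALV3", "ALV4", "MAT"]
#: label for whole-embryo samples, kept outside lung-stage inference
WE_STAGE = "WE"


# --------------------------------------------------------------------------- #
# Stage map container
# --------------------------------------------------------------------------- #

@dataclass
class StageMap:
    """Ordered assignment of time points to named molecular stages."""

    stages: list[tuple[str, list[str]]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.stages]
        if len(set(names)) != len(names):
            raise ValueError("duplicate stage names")
        tps = self.timepoints()
        if len(set(tps)) != len(tps):
            raise ValueError("a time point appears in more than one stage")
        if any(len(tps_) == 0 for _, tps_ in self.stages):
            raise ValueError("every stage needs at least one time point")

    def timepoints(self) -> list[str]:
        return [tp for _, tps in self.stages for tp in tps]

    @property
    def stage_names(self) -> list[str]:
        return [n for n, _ in self.stages]

    def timepoint_to_stage(self) -> dict[str, str]:
        return {tp: name for name, tps in self.stages for tp in tps}

    def is_contiguous(self) -> bool:
        """Stages are contiguous along the developmental axis."""
        return self.timepoints() == order_timepoints(self.timepoints())

    def boundaries(self) -> list[tuple[str, str]]:
        """(last timepoint of stage, first of next) for successive stages."""
        out = []
        for (_, a), (_, b) in zip(self.stages, self.stages[1:]):
            out.append((a[-1], b[0]))
        return out

    def transitions(self) -> list[tuple[str, str]]:
        names = self.stage_names
        return list(zip(names, names[1:]))

    # ---- I/O ------------------------------------------------------------- #

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"stages": [[n, tps] for n, tps in self.stages]}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "StageMap":
        with open(path) as fh:
            obj = json.load(fh)
        return cls([(n, list(tps)) for n, tps in obj["stages"]])

    def to_tsv(self, path) -> None:
        rows = [(tp, name) for name, tps in self.stages for tp in tps]
        pd.DataFrame(rows, columns=["timepoint", "stage"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "StageMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        stages: list[tuple[str, list[str]]] = []
        for tp, st in zip(df["timepoint"], df["stage"]):
            if stages and stages[-1][0] == st:
                stages[-1][1].append(tp)
            else:
                stages.append((st, [tp]))
        return cls(stages)


# --------------------------------------------------------------------------- #
# Sum-to-zero least squares machinery
# --------------------------------------------------------------------------- #

def _sum_code(values: pd.Series, levels: list[str]) -> np.ndarray:
    """Sum-to-zero (effects) coding: L-1 columns, last level coded -1."""
    n, L = len(values), len(levels)
    X = np.zeros((n, L - 1))
    idx = {lev: i for i, lev in enumerate(levels)}
    for r, v in enumerate(values):
        i = idx[v]
        if i < L - 1:
            X[r, i] = 1.0
        else:
            X[r, :] = -1.0
    return X


def _expand_effects(beta: np.ndarray, levels: list[str]) -> pd.Series:
    """Recover all L effects (summing to zero) from the L-1 free parameters."""
    full = np.append(beta, -beta.sum())
    return pd.Series(full, index=levels)


def _ols(X: np.ndarray, y: np.ndarray):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    return beta, fitted, resid


def _term_f_test(X_full, y, cols_of_term, rank_full, sse_full):
    """Extra-sum-of-squares F test for dropping one term."""
    keep = [c for c in range(X_full.shape[1]) if c not in cols_of_term]
    X_red = X_full[:, keep]
    _, _, resid_red = _ols(X_red, y)
    sse_red = float(resid_red @ resid_red)
    rank_red = np.linalg.matrix_rank(X_red)
    df_num = rank_full - rank_red
    df_den = len(y) - rank_full
    if df_num <= 0 or df_den <= 0:
        return np.nan, df_num, df_den
    F = ((sse_red - sse_full) / df_num) / (sse_full / df_den)
    return float(stats.f.sf(F, df_num, df_den)), df_num, df_den


@dataclass
class TimePointEffects:
    """Additive-model decomposition of per-component sample scores."""

    timepoint_effects: pd.DataFrame   # timepoint x component
    strain_effects: pd.DataFrame      # strain x component
    intercept: pd.Series              # per component
    pvalues: pd.DataFrame             # component x {timepoint, strain}
    fitted: pd.DataFrame              # sample x component
    residuals: pd.DataFrame           # sample x component
    fdr_flags: pd.DataFrame | None = None

    def apply_fdr(self, q: float = 0.1) -> pd.DataFrame:
        """BH flags across all (component, term) p-values as one family."""
        flat = self.pvalues.stack()
        rej, adj = benjamini_hochberg(flat.to_numpy(), q)
        self.fdr_flags = pd.Series(rej, index=flat.index).unstack()
        return self.fdr_flags


@dataclass
class StageEffects:
    """Stage + strain + interaction decomposition of sample scores."""

    stage_effects: pd.DataFrame       # stage x component
    strain_effects: pd.DataFrame      # strain x component
    interaction: dict[str, pd.DataFrame]  # component -> stage x strain grid
    intercept: pd.Series
    pvalues: pd.DataFrame             # component x {stage, strain, stage:strain}
    lsmeans_stage: pd.DataFrame       # stage x component
    lsmeans_strain: pd.DataFrame      # strain x component
    lsmeans_cell: dict[str, pd.DataFrame]  # component -> stage x strain
    fitted: pd.DataFrame
    residuals: pd.DataFrame
    fdr_flags: pd.DataFrame | None = None

    def apply_fdr(self, q: float = 0.1) -> pd.DataFrame:
        flat = self.pvalues.stack()
        rej, adj = benjamini_hochberg(flat.to_numpy(), q)
        self.fdr_flags = pd.Series(rej, index=flat.index).unstack()
        return self.fdr_flags


def fit_additive_model(scores: pd.DataFrame, meta: pd.DataFrame) -> TimePointEffects:
    """Fit score = mu + a(timepoint) + b(strain) + e per component.

    Missing design cells (e.g. an E19.5 sampled in one strain only) are
    handled by fitting on the available cells.  A single-strain design
    degenerates gracefully to time-point means.
    """
    meta = meta.loc[scores.index]
    tps = order_timepoints(meta["timepoint"])
    strains = sorted(meta["strain"].unique())
    if len(tps) < 2:
        raise ValueError("need at least two time points")

    blocks = [np.ones((len(meta), 1))]
    term_cols: dict[str, list[int]] = {}
    col = 1
    X_tp = _sum_code(meta["timepoint"], tps)
    blocks.append(X_tp)
    term_cols["timepoint"] = list(range(col, col + X_tp.shape[1]))
    col += X_tp.shape[1]
    if len(strains) > 1:
        X_st = _sum_code(meta["strain"], strains)
        blocks.append(X_st)
        term_cols["strain"] = list(range(col, col + X_st.shape[1]))
        col += X_st.shape[1]
    X = np.hstack(blocks)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            "rank-deficient design: time point and strain are confounded "
            f"(rank {rank} < {X.shape[1]} columns)"
        )

    tp_eff, st_eff, icepts, pvals, fit_cols, res_cols = {}, {}, {}, {}, {}, {}
    for comp in scores.columns:
        y = scores[comp].to_numpy(float)
        beta, fitted, resid = _ols(X, y)
        sse = float(resid @ resid)
        icepts[comp] = beta[0]
        tp_eff[comp] = _expand_effects(beta[term_cols["timepoint"]], tps)
        row = {}
        row["timepoint"], _, _ = _term_f_test(X, y, term_cols["timepoint"], rank, sse)
        if "strain" in term_cols:
            st_eff[comp] = _expand_effects(beta[term_cols["strain"]], strains)
            row["strain"], _, _ = _term_f_test(X, y, term_cols["strain"], rank, sse)
        else:
            st_eff[comp] = pd.Series(0.0, index=strains)
            row["strain"] = np.nan
        pvals[comp] = row
        fit_cols[comp] = fitted
        res_cols[comp] = resid

    return TimePointEffects(
        timepoint_effects=pd.DataFrame(tp_eff).loc[tps],
        strain_effects=pd.DataFrame(st_eff).loc[strains],
        intercept=pd.Series(icepts),
        pvalues=pd.DataFrame(pvals).T[["timepoint", "strain"]],
        fitted=pd.DataFrame(fit_cols, index=scores.index),
        residuals=pd.DataFrame(res_cols, index=scores.index),
    )


def fit_stage_model(scores: pd.DataFrame, meta: pd.DataFrame,
                    stagemap: StageMap) -> StageEffects:
    """Fit score = mu + d(stage) + b(strain) + g(stage, strain) + e.

    Every sample's time point must be covered by ``stagemap``.  Empty
    stage x strain cells are tolerated (the least-squares fit uses the
    pseudoinverse and only estimable contrasts are meaningful); a stage
    with no samples at all is an error.
    """
    meta = meta.loc[scores.index].copy()
    tp2stage = stagemap.timepoint_to_stage()
    unmapped = sorted(set(meta["timepoint"]) - set(tp2stage))
    if unmapped:
        raise ValueError(f"time points not covered by stage map: {unmapped}")
    meta["stage"] = meta["timepoint"].map(tp2stage)
    stage_levels = [s for s in stagemap.stage_names if s in set(meta["stage"])]
    missing_stages = [s for s in stagemap.stage_names if s not in stage_levels]
    if missing_stages:
        raise ValueError(f"stages with no samples: {missing_stages}")
    strains = sorted(meta["strain"].unique())

    cell_counts = meta.groupby(["stage", "strain"]).size()
    n_cells = len(stage_levels) * len(strains)
    if len(cell_counts) < n_cells:
        logger.warning(
            "stage model: %d of %d stage x strain cells are empty",
            n_cells - len(cell_counts), n_cells,
        )

    X_stage = _sum_code(meta["stage"], stage_levels)
    X_strain = _sum_code(meta["strain"], strains)
    inter = np.einsum("ni,nj->nij", X_stage, X_strain).reshape(len(meta), -1)
    X = np.hstack([np.ones((len(meta), 1)), X_stage, X_strain, inter])
    cs = X_stage.shape[1]
    cst = X_strain.shape[1]
    term_cols = {
        "stage": list(range(1, 1 + cs)),
        "strain": list(range(1 + cs, 1 + cs + cst)),
        "stage:strain": list(range(1 + cs + cst, X.shape[1])),
    }
    rank = np.linalg.matrix_rank(X)

    out: dict[str, dict] = {k: {} for k in
                            ("d", "b", "g", "mu", "p", "fit", "res", "cell")}
    for comp in scores.columns:
        y = scores[comp].to_numpy(float)
        beta, fitted, resid = _ols(X, y)
        sse = float(resid @ resid)
        out["mu"][comp] = beta[0]
        d = _expand_effects(beta[term_cols["stage"]], stage_levels)
        b = _expand_effects(beta[term_cols["strain"]], strains)
        # interaction grid with sum-to-zero rows and columns
        g_free = beta[term_cols["stage:strain"]].reshape(cs, cst)
        g = np.zeros((cs + 1, cst + 1))
        g[:cs, :cst] = g_free
        g[cs, :cst] = -g_free.sum(axis=0)
        g[:, cst] = -g[:, :cst].sum(axis=1)
        gdf = pd.DataFrame(g, index=stage_levels, columns=strains)
        out["d"][comp] = d
        out["b"][comp] = b
        out["g"][comp] = gdf
        out["cell"][comp] = gdf.add(d, axis=0).add(b, axis=1) + beta[0]
        row = {}
        for term in ("stage", "strain", "stage:strain"):
            row[term], _, _ = _term_f_test(X, y, term_cols[term], rank, sse)
        out["p"][comp] = row
        out["fit"][comp] = fitted
        out["res"][comp] = resid

    mu = pd.Series(out["mu"])
    d_df = pd.DataFrame(out["d"]).loc[stage_levels]
    b_df = pd.DataFrame(out["b"]).loc[strains]
    return StageEffects(
        stage_effects=d_df,
        strain_effects=b_df,
        interaction=out["g"],
        intercept=mu,
        pvalues=pd.DataFrame(out["p"]).T[["stage", "strain", "stage:strain"]],
        lsmeans_stage=d_df.add(mu, axis=1),
        lsmeans_strain=b_df.add(mu, axis=1),
        lsmeans_cell=out["cell"],
        fitted=pd.DataFrame(out["fit"], index=scores.index),
        residuals=pd.DataFrame(out["res"], index=scores.index),
    )


# --------------------------------------------------------------------------- #
# Multiple testing
# --------------------------------------------------------------------------- #

def benjamini_hochberg(pvalues, q: float = 0.1):
    """BH step-up FDR control.

    Returns ``(reject, adjusted)`` arrays aligned with the input.  NaNs are
    passed through unrejected.
    """
    p = np.asarray(pvalues, dtype=float)
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject = np.zeros(p.shape, dtype=bool)
    adjusted = np.full(p.shape, np.nan)
    if finite.any():
        rej, adj, *_ = multipletests(p[finite], alpha=q, method="fdr_bh")
        reject[finite] = rej
        adjusted[finite] = adj
    return reject, adjusted


# --------------------------------------------------------------------------- #
# Contiguous segmentation of time-point effects
# --------------------------------------------------------------------------- #

def _segment_costs(E: np.ndarray) -> np.ndarray:
    """cost[i, j] = within-segment SSE of rows i..j (inclusive), all columns."""
    T = E.shape[0]
    s1 = np.vstack([np.zeros(E.shape[1]), np.cumsum(E, axis=0)])
    s2 = np.vstack([np.zeros(E.shape[1]), np.cumsum(E * E, axis=0)])
    cost = np.full((T, T), np.inf)
    for i in range(T):
        for j in range(i, T):
            n = j - i + 1
            seg1 = s1[j + 1] - s1[i]
            seg2 = s2[j + 1] - s2[i]
            cost[i, j] = float(np.sum(seg2 - seg1 * seg1 / n))
    return cost


def _dp_partition(cost: np.ndarray, k: int, allowed: np.ndarray):
    """Min-cost contiguous k-partition; ``allowed[p]`` permits a boundary
    between positions p and p+1."""
    T = cost.shape[0]
    INF = np.inf
    dp = np.full((k + 1, T + 1), INF)
    back = np.zeros((k + 1, T + 1), dtype=int)
    dp[0, 0] = 0.0
    for kk in range(1, k + 1):
        for j in range(1, T + 1):
            best, arg = INF, 0
            for i in range(kk - 1, j):
                if i > 0 and not allowed[i - 1]:
                    continue
                v = dp[kk - 1, i] + cost[i, j - 1]
                if v < best - 1e-15:
                    best, arg = v, i
            dp[kk, j], back[kk, j] = best, arg
    # recover boundaries
    cuts = []
    j = T
    for kk in range(k, 0, -1):
        i = back[kk, j]
        if i > 0:
            cuts.append(i)
        j = i
    return dp[k, T], sorted(cuts)


def segment_stages(effects: pd.DataFrame, n_stages: int | None = None,
                   stage_names: list[str] | None = None,
                   must_link=(), must_split=(),
                   max_stages: int = 12, penalty: float = 1.0) -> StageMap:
    """Segment ordered time-point effects into contiguous molecular stages.

    Parameters
    ----------
    effects
        DataFrame of time-point effects, rows in developmental order,
        one column per selected component (default use: PCs 1-3).
    n_stages
        Fixed stage count; when None the count is chosen by a BIC-like
        penalty over 1..max_stages.
    must_link
        Pairs of time-point labels forced into the same stage (parity with
        the study's manual grouping choices, e.g. ("P2", "P3")).
    must_split
        Pairs of adjacent time-point labels forced into different stages.
    """
    tps = list(effects.index)
    T = len(tps)
    if n_stages is not None and n_stages > T:
        raise ValueError(f"requested {n_stages} stages for {T} time points")
    pos = {tp: i for i, tp in enumerate(tps)}
    allowed = np.ones(T - 1, dtype=bool)
    required = np.zeros(T - 1, dtype=bool)
    for a, b in must_link:
        lo, hi = sorted((pos[a], pos[b]))
        allowed[lo:hi] = False
    for a, b in must_split:
        lo, hi = sorted((pos[a], pos[b]))
        if hi - lo != 1:
            raise ValueError(f"must_split pair {(a, b)} is not adjacent")
        if not allowed[lo]:
            raise ValueError(f"conflicting pin at boundary {(a, b)}")
        required[lo] = True

    E = effects.to_numpy(float)
    cost = _segment_costs(E)
    # a segment may not straddle a required boundary
    for p in np.flatnonzero(required):
        cost[: p + 1, p + 1:] = np.inf

    def solve(k):
        return _dp_partition(cost, k, allowed)

    if n_stages is None:
        n_obs = E.size
        best = None
        for k in range(1, min(T, max_stages) + 1):
            sse, cuts = solve(k)
            if not np.isfinite(sse):
                continue
            score = n_obs * np.log(sse / n_obs + 1e-12) + penalty * k * np.log(n_obs)
            if best is None or score < best[0]:
                best = (score, k, cuts)
        if best is None:
            raise ValueError("no feasible segmentation under the given pins")
        _, k, cuts = best
    else:
        sse, cuts = solve(n_stages)
        if not np.isfinite(sse):
            raise ValueError("no feasible segmentation under the given pins")
        k = n_stages

    bounds = [0] + cuts + [T]
    if stage_names is None:
        stage_names = CANONICAL_STAGES if k == 9 else [f"S{i+1}" for i in range(k)]
    if len(stage_names) != k:
        raise ValueError("stage_names length does not match stage count")
    stages = [
        (stage_names[s], tps[bounds[s]:bounds[s + 1]]) for s in range(k)
    ]
    return StageMap(stages)


def build_stage_map(effects: pd.DataFrame, n_stages: int = 9,
                    we_timepoints=("E9.5",), **kwargs) -> StageMap:
    """Segment lung time points and prepend a WE stage for whole-embryo samples.

    Whole-embryo time points (E9.5 by default) are excluded from segmentation
    and assigned the WE label; the remaining time points are segmented into
    ``n_stages`` contiguous stages with canonical names when ``n_stages == 9``.
    """
    we_tps = [tp for tp in effects.index if tp in set(we_timepoints)]
    lung = effects.loc[[tp for tp in effects.index if tp not in we_tps]]
    smap = segment_stages(lung, n_stages=n_stages, **kwargs)
    if we_tps:
        return StageMap([(WE_STAGE, we_tps)] + smap.stages)
    return smap
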