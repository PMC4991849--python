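"""Two-class Significance Analysis of Microarrays (SAM) with permutation
FDR, applied between successive developmental stages.

For gene i with group means x1, x2 and pooled standard error

    s_i = sqrt( (1/n1 + 1/n2) * (ss1 + ss2) / (n1 + n2 - 2) ),

the moderated statistic is d_i = (x2 - x1) / (s_i + s0), where the fudge
constant s0 is chosen from the percentile grid of s to minimize the
coefficient of variation of the windowed median absolute deviation of d.
The null band is built from label permutations: all distinct group
assignments are enumerated when few enough, otherwise a seeded sample
without replacement; the expected order statistics are the mean of the
sorted permuted d.  Calling uses the band offset delta: cut-offs come
from the first sorted genes whose deviation from the expected order
statistic exceeds delta, and the "median FDR = 0" policy picks the
smallest delta at which the median permuted count of genes beyond the
cut-offs is zero.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .staging import StageMap, WE_STAGE

logger = logging.getLogger("lungdev")


@dataclass
class SAMResult:
    """d-statistics, permutation band, and (after calling) the called set."""

    genes: list[str]
    diff: np.ndarray
    s: np.ndarray
    d: np.ndarray
    s0: float
    order: np.ndarray            # argsort of d ascending
    dbar: np.ndarray             # expected order statistics, ascending
    perm_d_sorted: np.ndarray    # n_perm x G, each row sorted ascending
    nontrivial: np.ndarray       # rows that break the original grouping
    n_perm: int
    exhaustive: bool
    seed: int | None
    # set by call_significant
    delta: float | None = None
    cut_up: float = math.inf
    cut_low: float = -math.inf
    called_up: list[str] = field(default_factory=list)
    called_down: list[str] = field(default_factory=list)
    median_false: float | None = None

    @property
    def called(self) -> list[str]:
        return self.called_up + self.called_down

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"gene_id": self.genes, "diff": self.diff,
                           "s": self.s, "d": self.d})
        called = set(self.called_up) | set(self.called_down)
        df["called"] = df["gene_id"].isin(called)
        df["direction"] = np.where(df["gene_id"].isin(set(self.called_up)), "up",
                                   np.where(df["gene_id"].isin(set(self.called_down)),
                                            "down", ""))
        return df


def _sam_d(X: np.ndarray, g1: np.ndarray, g2: np.ndarray, s0: float | None):
    """diff, s, d for one label assignment (boolean index arrays)."""
    n1, n2 = int(g1.sum()), int(g2.sum())
    m1 = X[:, g1].mean(axis=1)
    m2 = X[:, g2].mean(axis=1)
    ss1 = ((X[:, g1] - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((X[:, g2] - m2[:, None]) ** 2).sum(axis=1)
    a = (1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2)
    s = np.sqrt(a * (ss1 + ss2))
    diff = m2 - m1
    if s0 is None:
        return diff, s, None
    return diff, s, diff / (s + s0)


def select_s0(diffs: np.ndarray, ses: np.ndarray, n_windows: int = 100
              ) -> float:
    """SAM fudge-factor selection.

    Candidates are the 0, 5, ..., 100 percentiles of s.  Genes are split
    into s-quantile windows; for each candidate the spread statistic is
    the coefficient of variation, across windows, of the scaled median
    absolute deviation of d = diff/(s + s0).  The candidate minimizing the
    CV wins; exact ties go to the smallest grid value.
    """
    s = np.asarray(ses, float)
    diffs = np.asarray(diffs, float)
    if np.allclose(s, s[0]):
        logger.warning("select_s0: all standard errors equal; s0 = 0")
        return 0.0
    alphas = np.arange(0, 101, 5)
    candidates = np.percentile(s, alphas)
    n_windows = max(2, min(n_windows, len(s) // 2))
    # quantile windows of s
    qs = np.quantile(s, np.linspace(0, 1, n_windows + 1))
    window = np.clip(np.searchsorted(qs, s, side="right") - 1, 0, n_windows - 1)
    best = None
    for s0 in candidates:
        d = diffs / (s + s0)
        vs = []
        for w in range(n_windows):
            dw = d[window == w]
            if len(dw) == 0:
                continue
            vs.append(np.median(np.abs(dw - np.median(dw))) / 0.64)
        vs = np.asarray(vs)
        mean_v = vs.mean()
        cv = vs.std(ddof=1) / mean_v if mean_v > 0 else np.inf
        if best is None or cv < best[0] - 1e-12:
            best = (cv, float(s0))
    return best[1]


def _all_splits(n: int, n1: int):
    return itertools.combinations(range(n), n1)


def sam_two_class(values: pd.DataFrame, labels, n_perm: int = 300,
                  seed: int | None = 17, s0: float | None = None) -> SAMResult:
    """SAM d-statistics and permutation band for a two-group comparison.

    ``values`` is genes x samples; ``labels`` assigns each sample to one of
    two groups (group order follows sorted label values; d > 0 means
    higher in the second group).  When the number of distinct label splits
    is at most ``n_perm`` they are all enumerated and the result is exact
    and seed-independent; otherwise distinct splits are sampled without
    replacement using ``seed``.
    """
    labels = np.asarray(labels)
    levels = sorted(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    g1 = labels == levels[0]
    g2 = labels == levels[1]
    n1, n2 = int(g1.sum()), int(g2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two samples")
    X = values.to_numpy(float)
    n = n1 + n2
    diff, s, _ = _sam_d(X, g1, g2, None)
    if s0 is None:
        s0 = select_s0(diff, s)
    d = diff / (s + s0)

    n_splits = math.comb(n, n1)
    exhaustive = n_splits <= n_perm
    # splits reproducing the original grouping (up to a label swap) carry no
    # information about the null and are excluded from the false-call estimate
    trivial = {tuple(np.flatnonzero(g1))}
    if n1 == n2:
        trivial.add(tuple(np.flatnonzero(g2)))
    if exhaustive:
        splits = list(_all_splits(n, n1))
    else:
        # sample distinct informative splits without replacement
        rng = np.random.default_rng(seed)
        chosen: set[tuple[int, ...]] = set()
        while len(chosen) < n_perm:
            perm = rng.permutation(n)[:n1]
            split = tuple(sorted(perm.tolist()))
            if split not in trivial:
                chosen.add(split)
        splits = sorted(chosen)
    perm_sorted = np.empty((len(splits), X.shape[0]))
    nontrivial = np.ones(len(splits), bool)
    for b, split in enumerate(splits):
        pg1 = np.zeros(n, bool)
        pg1[list(split)] = True
        pg2 = ~pg1
        pdiff, ps, _ = _sam_d(X, pg1, pg2, None)
        perm_sorted[b] = np.sort(pdiff / (ps + s0))
        nontrivial[b] = split not in trivial
    dbar = perm_sorted.mean(axis=0)

    return SAMResult(
        genes=list(values.index), diff=diff, s=s, d=d, s0=float(s0),
        order=np.argsort(d, kind="stable"), dbar=dbar,
        perm_d_sorted=perm_sorted, nontrivial=nontrivial, n_perm=len(splits),
        exhaustive=exhaustive, seed=seed,
    )


def _cutoffs(result: SAMResult, delta: float):
    """Band cut-offs: scan outward from the origin of the d vs dbar plot.

    The upper cut-off is the smallest d among right-half genes (dbar >= 0)
    whose deviation from the expected order statistic reaches delta; the
    lower cut-off mirrors it on the left half.
    """
    d_sorted = result.d[result.order]
    dev = d_sorted - result.dbar
    right = result.dbar >= 0
    left = result.dbar <= 0
    up = d_sorted[right & (dev >= delta)]
    down = d_sorted[left & (-dev >= delta)]
    cut_up = float(up.min()) if len(up) else math.inf
    cut_low = float(down.max()) if len(down) else -math.inf
    if cut_low >= cut_up:
        mid = (cut_low + cut_up) / 2
        cut_low, cut_up = np.nextafter(mid, -math.inf), np.nextafter(mid, math.inf)
    return cut_up, cut_low


def _false_counts(result: SAMResult, cut_up: float, cut_low: float
                  ) -> np.ndarray:
    """Per informative split, how many permuted d fall beyond the cut-offs."""
    P = result.perm_d_sorted[result.nontrivial]
    return (P >= cut_up).sum(axis=1) + (P <= cut_low).sum(axis=1)


def call_significant(result: SAMResult, policy: str = "median_fdr_zero",
                     delta: float | None = None,
                     false_summary: str = "mean") -> SAMResult:
    """Choose the band offset delta and call significant genes.

    ``median_fdr_zero``: smallest delta at which the falsely-called count
    summary across the informative label splits is zero (the result may
    legitimately be an empty call set on null data).  The default summary
    is the mean falsely-called count, the original SAM estimator; a zero
    mean implies the median is also zero, so the reported median FDR is 0
    at the chosen delta.  ``false_summary="median"`` gives the laxer
    median-count rule.  Policy ``"delta"`` uses a fixed offset instead.
    Returns the same result object with the calling fields filled in.
    """
    summarize = {"mean": np.mean, "median": np.median}[false_summary]

    def false_at(cu, cl):
        return float(summarize(_false_counts(result, cu, cl)))

    if policy == "delta":
        if delta is None:
            raise ValueError("policy 'delta' needs a delta value")
        chosen = float(delta)
    elif policy == "median_fdr_zero":
        dev = np.abs(result.d[result.order] - result.dbar)
        candidates = np.unique(np.concatenate([[0.0], dev]))
        # the false count is nonincreasing in delta: binary search the
        # smallest candidate achieving zero
        lo, hi = 0, len(candidates) - 1
        if false_at(*_cutoffs(result, candidates[hi])) > 0:
            logger.info("call_significant: no delta reaches FDR 0; "
                        "no genes called")
            result.delta = math.inf
            result.cut_up, result.cut_low = math.inf, -math.inf
            result.called_up, result.called_down = [], []
            result.median_false = 0.0
            return result
        while lo < hi:
            mid = (lo + hi) // 2
            if false_at(*_cutoffs(result, candidates[mid])) <= 0:
                hi = mid
            else:
                lo = mid + 1
        chosen = float(candidates[lo])
    else:
        raise ValueError(f"unknown policy {policy!r}")

    cut_up, cut_low = _cutoffs(result, chosen)
    genes = np.asarray(result.genes)
    result.delta = chosen
    result.cut_up, result.cut_low = cut_up, cut_low
    result.called_up = list(genes[result.d >= cut_up])
    result.called_down = list(genes[result.d <= cut_low])
    result.median_false = float(np.median(_false_counts(result, cut_up,
                                                        cut_low)))
    if not result.called:
        logger.info("call_significant: empty call set at delta=%.4g", chosen)
    return result


def stage_transition_de(matrix: ExpressionMatrix, stagemap: StageMap,
                        strains: str | list = "all", n_perm: int = 300,
                        seed: int | None = 17, include_we: bool = False,
                        policy: str = "median_fdr_zero",
                        delta: float | None = None
                        ) -> dict[tuple[str, str], SAMResult]:
    """SAM between each pair of successive stages.

    Strains are pooled by default (``strains="all"``); pass a list to
    restrict.  Transitions in stage-map order; a stage with fewer than two
    samples skips its transitions with a warning.  Whole-embryo (WE)
    samples are excluded unless ``include_we``.
    """
    meta = matrix.sample_meta
    if strains != "all":
        keep = meta.index[meta["strain"].isin(set(strains))]
        matrix = matrix.subset_samples(keep)
        meta = matrix.sample_meta
    tp2stage = stagemap.timepoint_to_stage()
    stage_of = meta["timepoint"].map(tp2stage)
    results: dict[tuple[str, str], SAMResult] = {}
    for a, b in stagemap.transitions():
        if not include_we and WE_STAGE in (a, b):
            continue
        ids_a = list(meta.index[stage_of == a])
        ids_b = list(meta.index[stage_of == b])
        if len(ids_a) < 2 or len(ids_b) < 2:
            logger.warning("stage_transition_de: %s->%s skipped "
                           "(%d vs %d samples)", a, b, len(ids_a), len(ids_b))
            continue
        sub = matrix.values[ids_a + ids_b]
        labels = [0] * len(ids_a) + [1] * len(ids_b)
        res = sam_two_class(sub, labels, n_perm=n_perm, seed=seed)
        results[(a, b)] = call_significant(res, policy=policy, delta=delta)
        logger.info("SAM %s->%s: %d up, %d down (delta=%.3g, s0=%.3g)",
                    a, b, len(res.called_up), len(res.called_down),
                    res.delta, res.s0)
    return results
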