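"""Strain-dependence classification via Tukey-Kramer HSD.

For each gene (or component) the expression values are grouped by strain
and all pairwise mean comparisons are made with the Tukey-Kramer honestly
significant difference procedure (studentized-range distribution, valid
for unequal group sizes).  Groups are summarized by a connecting-letters
diagram: groups sharing a letter are statistically indistinguishable.

With three strains the pairwise outcomes map onto four classes of
strain-dependent expression: one outlier strain against an
indistinguishable pair (three classes) or all strains different; genes
with no significant pair are class "none".  The direction pattern records
the outlier's level relative to the pair, e.g. "B6 > C3H ~ AJ".
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import studentized_range

from .containers import ExpressionMatrix
from .simdata import CLASS_AJ, CLASS_ALL, CLASS_B6, CLASS_C3H, CLASS_NONE

logger = logging.getLogger("lungdev")


@dataclass
class HSDResult:
    """All-pairs Tukey-Kramer comparison of group means."""

    means: pd.Series                       # per group
    counts: pd.Series
    mse: float
    df_error: int
    table: pd.DataFrame                    # pair rows: diff, q, pvalue, significant
    letters: dict[str, str]                # group -> connecting letters
    alpha: float

    def significant_pairs(self) -> set[frozenset]:
        sig = self.table.loc[self.table["significant"]]
        return {frozenset((a, b)) for a, b in zip(sig["group_a"], sig["group_b"])}


def tukey_hsd(groups: dict[str, np.ndarray], alpha: float = 0.05) -> HSDResult:
    """Tukey-Kramer HSD over named groups of observations.

    Groups with fewer than two observations are excluded with a warning.
    The adjusted p-value for a pair is the studentized-range tail
    probability of q = |mean_a - mean_b| / sqrt(MSE/2 * (1/n_a + 1/n_b)).
    """
    clean = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if len(v) < 2:
            logger.warning("tukey_hsd: group %s has n<2; excluded", name)
            continue
        clean[name] = v
    if len(clean) < 2:
        raise ValueError("need at least two groups with n >= 2")
    names = sorted(clean)
    k = len(names)
    counts = pd.Series({n: len(clean[n]) for n in names})
    means = pd.Series({n: float(np.mean(clean[n])) for n in names})
    N = int(counts.sum())
    df_error = N - k
    sse = sum(float(np.sum((clean[n] - means[n]) ** 2)) for n in names)
    mse = sse / df_error

    rows = []
    qs = []
    for a, b in itertools.combinations(names, 2):
        diff = means[a] - means[b]
        se = np.sqrt(mse / 2.0 * (1.0 / counts[a] + 1.0 / counts[b]))
        q = np.abs(diff) / se if se > 0 else np.inf
        rows.append((a, b, diff, q))
        qs.append(q)
    if mse == 0:
        pvals = np.where(np.asarray(qs) > 0, 0.0, 1.0)
    else:
        pvals = studentized_range.sf(np.asarray(qs), k, df_error)
        pvals = np.clip(np.nan_to_num(pvals, nan=1.0), 0.0, 1.0)
    table = pd.DataFrame(rows, columns=["group_a", "group_b", "diff", "q"])
    table["pvalue"] = pvals
    table["significant"] = table["pvalue"] < alpha

    letters = connecting_letters(
        names, means,
        {frozenset((a, b)) for a, b, s in
         zip(table["group_a"], table["group_b"], table["significant"]) if s},
    )
    return HSDResult(means=means, counts=counts, mse=mse, df_error=df_error,
                     table=table, letters=letters, alpha=alpha)


def connecting_letters(names, means: pd.Series, sig_pairs: set[frozenset]
                       ) -> dict[str, str]:
    """Assign letters so that two groups share a letter iff they are not
    significantly different from every other member of that letter's set.

    Letters correspond to the maximal cliques of the "not significantly
    different" graph, ordered by descending group mean.
    """
    order = sorted(names, key=lambda n: -means[n])
    k = len(order)

    def compatible(subset):
        return all(frozenset((a, b)) not in sig_pairs
                   for a, b in itertools.combinations(subset, 2))

    cliques = []
    for size in range(k, 0, -1):
        for subset in itertools.combinations(order, size):
            if compatible(subset) and not any(
                    set(subset) <= set(c) for c in cliques):
                cliques.append(subset)
    cliques.sort(key=lambda c: -max(means[n] for n in c))
    letters = {n: "" for n in names}
    for i, clique in enumerate(cliques):
        ch = chr(ord("A") + i)
        for n in clique:
            letters[n] += ch
    return letters


@dataclass
class PatternCall:
    """Classification of one gene/component into the four-class scheme."""

    cls: str
    pattern: str
    letters: dict[str, str]
    qvalues: dict[frozenset, float]
    diagnostics: str = ""


def classify_strain_pattern(hsd: HSDResult) -> PatternCall:
    """Map a three-strain HSD outcome to one of the four classes (or none).

    Conflicting pairwise triples (a significant pair inside an otherwise
    connected letter group) are resolved by the connecting letters: the
    outlier must share no letter with either member of a pair that shares
    one.  The diagnostics string records the full ordering-with-ties
    pattern (the 19-pattern space for three groups).
    """
    names = list(hsd.means.index)
    if len(names) != 3:
        raise ValueError("classification is defined over exactly three strains")
    letters = hsd.letters
    means = hsd.means
    qvals = {frozenset((a, b)): p for a, b, p in
             zip(hsd.table["group_a"], hsd.table["group_b"], hsd.table["pvalue"])}

    def share(a, b):
        return bool(set(letters[a]) & set(letters[b]))

    order = sorted(names, key=lambda n: -means[n])
    # diagnostics: full ordering with ~ for letter-sharing neighbours
    diag = order[0]
    for prev, cur in zip(order, order[1:]):
        diag += (" ~ " if share(prev, cur) else " > ") + cur

    sep = [n for n in names if not any(share(n, m) for m in names if m != n)]
    linked_pairs = [(a, b) for a, b in itertools.combinations(names, 2)
                    if share(a, b)]
    if not any(share(a, b) for a, b in itertools.combinations(names, 2)):
        cls = CLASS_ALL
        pattern = " > ".join(order)
    elif len(sep) == 1 and len(linked_pairs) == 1:
        outlier = sep[0]
        pair = [n for n in names if n != outlier]
        cls = {"C3H": CLASS_C3H, "B6": CLASS_B6, "AJ": CLASS_AJ}.get(
            outlier, f"{outlier}!=" + "~".join(sorted(pair)))
        op = ">" if means[outlier] > means[pair].mean() else "<"
        pair_sorted = sorted(pair)  # fixed order: the pair is indistinguishable
        pattern = f"{outlier} {op} {pair_sorted[0]} ~ {pair_sorted[1]}"
    else:
        cls = CLASS_NONE
        pattern = ""
    return PatternCall(cls=cls, pattern=pattern, letters=letters,
                       qvalues=qvals, diagnostics=diag)


@dataclass
class StrainPatternResult:
    """Per-gene strain-pattern classification table."""

    calls: pd.DataFrame   # index gene; columns cls, pattern, diagnostics, q_*

    def to_tsv(self, path) -> None:
        self.calls.to_csv(path, sep="\t", index_label="gene_id")


def classify_genes(matrix: ExpressionMatrix, alpha: float = 0.05,
                   timepoints=None) -> StrainPatternResult:
    """Classify every gene by pooling samples across stages.

    The dominant strain-specific expression patterns are stage-independent,
    so each gene's samples are grouped by strain only (optionally after
    restricting to a time-point window) before Tukey-Kramer HSD.
    """
    if timepoints is not None:
        matrix = matrix.subset_timepoints(timepoints)
    strain_of = matrix.sample_meta["strain"]
    strains = sorted(strain_of.unique())
    cols = {s: matrix.sample_meta.index[strain_of == s] for s in strains}
    rows = []
    for gene in matrix.gene_ids:
        groups = {s: matrix.values.loc[gene, cols[s]].to_numpy() for s in strains}
        hsd = tukey_hsd(groups, alpha=alpha)
        call = classify_strain_pattern(hsd)
        row = {"cls": call.cls, "pattern": call.pattern,
               "diagnostics": call.diagnostics}
        for pair, p in call.qvalues.items():
            a, b = sorted(pair)
            row[f"q_{a}_{b}"] = p
        rows.append(row)
    calls = pd.DataFrame(rows, index=matrix.gene_ids)
    logger.info("classify_genes: %d/%d genes strain-dependent",
                int((calls["cls"] != CLASS_NONE).sum()), len(calls))
    return StrainPatternResult(calls)


def summarize_classes(result: StrainPatternResult) -> pd.DataFrame:
    """Class counts and within-class direction-pattern percentages.

    Percentages of classes are over all classified (non-"none") genes;
    pattern percentages are within their parent class.
    """
    calls = result.calls
    classified = calls.loc[calls["cls"] != CLASS_NONE]
    rows = []
    total = len(classified)
    for cls, sub in classified.groupby("cls"):
        rows.append({"cls": cls, "pattern": "", "n_genes": len(sub),
                     "percent": 100.0 * len(sub) / total if total else np.nan})
        if cls != CLASS_ALL:
            for pattern, psub in sub.groupby("pattern"):
                rows.append({"cls": cls, "pattern": pattern,
                             "n_genes": len(psub),
                             "percent": 100.0 * len(psub) / len(sub)})
    return pd.DataFrame(rows, columns=["cls", "pattern", "n_genes", "percent"])
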