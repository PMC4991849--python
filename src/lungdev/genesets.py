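"""Gene-set statistics: hypergeometric term enrichment, homolog mapping,
and a qPCR relative-expression utility.

Enrichment is the classical one-sided hypergeometric (equivalently Fisher
exact) upper tail: the probability, drawing ``|query|`` genes from a
``|universe|``-gene urn containing ``|term|`` successes, of at least the
observed overlap.  Tails are computed in log space so that extreme
significances (p ~ 1e-100 and beyond) are exact.  Term collections are
consumed pre-propagated in the standard GMT tab format; no ontology-graph
expansion is performed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .staging import benjamini_hochberg

logger = logging.getLogger("lungdev")


# --------------------------------------------------------------------------- #
# Core hypergeometric tail (shared by enrichment and set-overlap statistics)
# --------------------------------------------------------------------------- #

def hypergeom_upper_tail(overlap: int, universe: int, set_a: int, set_b: int
                         ) -> float:
    """P(X >= overlap) for X ~ Hypergeom(N=universe, K=set_a, n=set_b).

    Exact log-space summation over the support, robust for tails far below
    float underflow of the naive survival function.
    """
    if overlap <= 0:
        return 1.0
    upper = min(set_a, set_b)
    if overlap > upper:
        return 0.0
    ks = np.arange(overlap, upper + 1)
    logp = hypergeom.logpmf(ks, universe, set_a, set_b)
    return float(min(1.0, math.exp(logsumexp(logp))))


def log10_hypergeom_upper_tail(overlap: int, universe: int, set_a: int,
                               set_b: int) -> float:
    """log10 of the upper-tail probability (for reporting extreme tails)."""
    if overlap <= 0:
        return 0.0
    upper = min(set_a, set_b)
    if overlap > upper:
        return -math.inf
    ks = np.arange(overlap, upper + 1)
    logp = hypergeom.logpmf(ks, universe, set_a, set_b)
    return float(min(0.0, logsumexp(logp) / math.log(10)))


# --------------------------------------------------------------------------- #
# Term collections (GMT)
# --------------------------------------------------------------------------- #

@dataclass
class TermCollection:
    """Named gene sets: term id -> (description, member gene ids)."""

    terms: dict[str, tuple[str, set[str]]]
    namespace: str = ""

    def __post_init__(self) -> None:
        for tid, (_, members) in self.terms.items():
            if not members:
                raise ValueError(f"term {tid} has no members")

    def __len__(self) -> int:
        return len(self.terms)

    @classmethod
    def from_gmt(cls, path, namespace: str = "") -> "TermCollection":
        terms = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"malformed GMT line: {line[:60]!r}")
                tid, desc, members = fields[0], fields[1], fields[2:]
                if tid in terms:
                    raise ValueError(f"duplicate term id {tid}")
                terms[tid] = (desc, {m for m in members if m})
        return cls(terms, namespace)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for tid, (desc, members) in self.terms.items():
                fh.write("\t".join([tid, desc] + sorted(members)) + "\n")


def hypergeometric_enrichment(query, terms: TermCollection, universe,
                              q: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in each term.

    Term members are intersected with the universe first; the query must be
    a subset of the universe.  Returns a frame sorted by p-value with BH
    adjusted p-values and rejection flags at ``q``.
    """
    query = set(query)
    universe = set(universe)
    if not universe or not query:
        raise ValueError("query and universe must be nonempty")
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(query)
    rows = []
    for tid, (desc, members) in terms.terms.items():
        term = members & universe
        if not term:
            continue
        k = len(term & query)
        expected = len(term) * n / N
        p = hypergeom_upper_tail(k, N, len(term), n)
        rows.append(dict(term=tid, description=desc, overlap=k,
                         term_size=len(term), query_size=n, universe_size=N,
                         fold_enrichment=(k / expected) if expected else np.nan,
                         pvalue=p))
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    rej, adj = benjamini_hochberg(df["pvalue"].to_numpy(), q)
    df["p_adjusted"] = np.maximum(adj, df["pvalue"])
    df["significant"] = rej
    return df.sort_values(["pvalue", "term"]).reset_index(drop=True)


# --------------------------------------------------------------------------- #
# Homology mapping
# --------------------------------------------------------------------------- #

@dataclass
class HomologyTable:
    """Source gene -> set of target-species homolog gene ids (many-to-many)."""

    mapping: dict[str, set[str]]

    def __post_init__(self) -> None:
        self.mapping = {s: set(t) for s, t in self.mapping.items() if t}

    @classmethod
    def from_tsv(cls, path) -> "HomologyTable":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["source", "target"], dtype=str)
        mapping: dict[str, set[str]] = {}
        for s, t in zip(df["source"], df["target"]):
            mapping.setdefault(s, set()).add(t)
        return cls(mapping)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for s in sorted(self.mapping):
                for t in sorted(self.mapping[s]):
                    fh.write(f"{s}\t{t}\n")


def map_homologs(genes, table: HomologyTable):
    """Expand genes through the homology table, one-to-many included.

    A source gene mapping to several homologs contributes every one of
    them; several sources mapping to one target collapse to a single
    output gene.  Returns ``(mapped_genes, unmapped_inputs)`` with the
    mapped list deduplicated and sorted.
    """
    mapped: set[str] = set()
    unmapped = []
    for g in genes:
        targets = table.mapping.get(g)
        if targets:
            mapped |= targets
        else:
            unmapped.append(g)
    if unmapped:
        logger.info("map_homologs: %d/%d inputs had no homolog",
                    len(unmapped), len(list(genes)) if not hasattr(genes, "__len__")
                    else len(genes))
    return sorted(mapped), unmapped


# --------------------------------------------------------------------------- #
# qPCR relative expression
# --------------------------------------------------------------------------- #

def qpcr_relative_expression(ct_table: pd.DataFrame, control_genes,
                             target_genes) -> pd.DataFrame:
    """Relative expression from qPCR cycle thresholds.

    Per biological replicate, the normalization value is the arithmetic
    mean of the control-gene Ct values (the log-domain geometric mean of
    control expression); delta-Ct = Ct_target - control mean and relative
    expression = 2^(-delta-Ct).  Replicates missing any control gene are
    skipped with a warning.

    ``ct_table`` columns: gene, replicate, Ct (extra grouping columns such
    as strain are carried through).
    """
    controls = set(control_genes)
    targets = set(target_genes)
    group_cols = [c for c in ct_table.columns if c not in ("gene", "Ct")]
    rows = []
    for key, sub in ct_table.groupby(group_cols, sort=True):
        present = set(sub["gene"])
        if not controls <= present:
            logger.warning("qpcr: replicate %s missing controls %s; skipped",
                           key, sorted(controls - present))
            continue
        ctrl_mean = float(sub.loc[sub["gene"].isin(controls), "Ct"].mean())
        for _, r in sub.loc[sub["gene"].isin(targets)].iterrows():
            dct = float(r["Ct"]) - ctrl_mean
            rec = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
            rec.update(gene=r["gene"], delta_ct=dct,
                       relative_expression=2.0 ** (-dct))
            rows.append(rec)
    return pd.DataFrame(rows)
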