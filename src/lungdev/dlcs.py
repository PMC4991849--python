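"""Characteristic subtranscriptome construction and gene-set comparison.

A developing-lung characteristic subtranscriptome (DLCS) is the union,
over the strain-independent principal components, of the genes with the
most extreme positive and negative loadings.  The selection is rank-based:
a fraction pair (pos, neg) per component takes the top ``pos`` fraction of
genes by loading (descending) and the bottom ``neg`` fraction (ascending).
The canonical recipe takes 25% from each tail of PC1 (whose loading
distribution is bimodal) and 10% from each tail of PC2 and PC3.

Set comparison uses the representation factor RF = observed overlap /
expected overlap under independence, with an exact hypergeometric tail
probability.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decompose import PCAResult
from .genesets import hypergeom_upper_tail, log10_hypergeom_upper_tail

logger = logging.getLogger("lungdev")

#: canonical per-tail selection fractions
DEFAULT_FRACTIONS: dict[str, tuple[float, float]] = {
    "PC1": (0.25, 0.25),
    "PC2": (0.10, 0.10),
    "PC3": (0.10, 0.10),
}


@dataclass
class DLCS:
    """A characteristic subtranscriptome with per-gene selection provenance.

    ``provenance`` rows: gene_id, component, loading, tail ('pos'/'neg').
    A gene selected by several components has one row per selection.
    """

    genes: set[str]
    provenance: pd.DataFrame
    fractions: dict[str, tuple[float, float]]
    counts_per_component: pd.DataFrame   # component x {pos, neg}

    def __len__(self) -> int:
        return len(self.genes)

    def write_genes(self, path) -> None:
        with open(path, "w") as fh:
            for g in sorted(self.genes):
                fh.write(g + "\n")

    def to_gmt_record(self, name="DLCS", desc="") -> str:
        return "\t".join([name, desc] + sorted(self.genes))


def build_dlcs(pca: PCAResult,
               fractions: dict[str, tuple[float, float]] | None = None,
               use_raw_loadings: bool = False) -> DLCS:
    """Select the extreme-loading genes of each component and union them.

    ``fractions`` maps component name to a (positive tail, negative tail)
    fraction pair, each in [0, 0.5]; per component, ceil(frac * G) genes
    are taken from each tail, rank ties broken by gene id.  The union is
    invariant to component sign flips (the two tails swap).
    """
    fractions = dict(DEFAULT_FRACTIONS) if fractions is None else fractions
    load = pca.raw_loadings if use_raw_loadings else pca.loadings
    G = load.shape[0]
    prov_rows = []
    counts = {}
    for comp, (fpos, fneg) in fractions.items():
        if comp not in load.columns:
            raise ValueError(f"component {comp} not in PCA result")
        if not (0 <= fpos <= 0.5 and 0 <= fneg <= 0.5):
            raise ValueError("tail fractions must lie in [0, 0.5]")
        n_pos = math.ceil(fpos * G)
        n_neg = math.ceil(fneg * G)
        ranked = pd.DataFrame({"loading": load[comp]})
        ranked["gene"] = ranked.index
        desc = ranked.sort_values(["loading", "gene"], ascending=[False, True])
        asc = ranked.sort_values(["loading", "gene"], ascending=[True, True])
        for _, r in desc.head(n_pos).iterrows():
            prov_rows.append((r["gene"], comp, float(r["loading"]), "pos"))
        for _, r in asc.head(n_neg).iterrows():
            prov_rows.append((r["gene"], comp, float(r["loading"]), "neg"))
        counts[comp] = {"pos": n_pos, "neg": n_neg}
    prov = pd.DataFrame(prov_rows,
                        columns=["gene_id", "component", "loading", "tail"])
    genes = set(prov["gene_id"])
    logger.info("build_dlcs: %d unique genes from %s",
                len(genes), {c: tuple(v.values()) for c, v in counts.items()})
    return DLCS(genes=genes, provenance=prov, fractions=dict(fractions),
                counts_per_component=pd.DataFrame(counts).T)


def bimodality_diagnostic(loadings) -> tuple[float, str]:
    """Sarle's bimodality coefficient with the conventional 5/9 threshold.

    BC = (skewness^2 + 1) / (excess kurtosis + 3 (n-1)^2 / ((n-2)(n-3))).
    Returns (coefficient, 'bimodal'|'unimodal'); advisory only — the tail
    fractions used for selection remain configuration.  Degenerate
    (constant) input is reported unimodal with a log entry.
    """
    x = np.asarray(loadings, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 loadings")
    if np.std(x) == 0:
        logger.info("bimodality_diagnostic: constant input; treated unimodal")
        return float("nan"), "unimodal"
    g1 = stats.skew(x, bias=False)
    g2 = stats.kurtosis(x, bias=False)  # excess kurtosis
    bc = (g1 ** 2 + 1) / (g2 + 3 * (n - 1) ** 2 / ((n - 2) * (n - 3)))
    verdict = "bimodal" if bc > 5.0 / 9.0 else "unimodal"
    return float(bc), verdict


@dataclass
class OverlapStats:
    """Overlap of two gene sets against a universe."""

    size_a: int
    size_b: int
    universe_size: int
    observed: int
    expected: float
    representation_factor: float
    pvalue: float
    log10_pvalue: float

    def rf_printed(self) -> float:
        """RF rounded to one decimal, the conventional reporting style."""
        return round(self.representation_factor, 1)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


def compare_gene_sets(a, b, universe) -> OverlapStats:
    """Observed vs expected overlap of two gene sets within a universe.

    Expected = |A| |B| / N; RF = observed / expected; the p-value is the
    exact hypergeometric upper tail for an overlap at least as large,
    computed in log space for extreme significance.
    """
    a, b, universe = set(a), set(b), set(universe)
    bad_a, bad_b = a - universe, b - universe
    if bad_a or bad_b:
        offenders = sorted(bad_a | bad_b)[:10]
        raise ValueError(f"sets are not subsets of the universe: {offenders}")
    N = len(universe)
    obs = len(a & b)
    expected = len(a) * len(b) / N if N else float("nan")
    rf = obs / expected if expected > 0 else 0.0
    return OverlapStats(
        size_a=len(a), size_b=len(b), universe_size=N, observed=obs,
        expected=expected, representation_factor=rf,
        pvalue=hypergeom_upper_tail(obs, N, len(a), len(b)),
        log10_pvalue=log10_hypergeom_upper_tail(obs, N, len(a), len(b)),
    )


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
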