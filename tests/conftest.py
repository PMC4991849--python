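import numpy as np
import pandas as pd
import pytest

from lungdev.containers import ExpressionMatrix, make_sample_meta
from lungdev.simdata import ClassSpec, SyntheticDesign


def small_class_spec():
    return {
        "C3H!=AJ~B6": [ClassSpec(3, outlier="C3H", direction="up"),
                       ClassSpec(3, outlier="C3H", direction="down")],
        "B6!=AJ~C3H": [ClassSpec(3, outlier="B6", direction="up"),
                       ClassSpec(3, outlier="B6", direction="down")],
        "AJ!=B6~C3H": [ClassSpec(3, outlier="AJ", direction="up")],
        "all-different": [ClassSpec(3, ordering=("B6", "AJ", "C3H"))],
    }


@pytest.fixture
def small_design():
    """A compact but structurally complete design: all stages, strains,
    missing E19.5 cells, characteristic and class genes."""
    return SyntheticDesign(n_genes=100, frac_characteristic=0.4,
                           strain_class_spec=small_class_spec(), seed=42)


@pytest.fixture
def small_matrix(small_design):
    from lungdev.simdata import simulate_gene_matrix
    return simulate_gene_matrix(small_design)


def toy_matrix(values, strains=None, timepoints=None, standardized=False):
    """Build an ExpressionMatrix from a plain array with minimal metadata."""
    values = np.asarray(values, dtype=float)
    G, S = values.shape
    strains = strains or ["AJ"] * S
    timepoints = timepoints or [f"P{i}" for i in range(S)]
    recs = [(f"s{i}", strains[i], timepoints[i], 1) for i in range(S)]
    meta = make_sample_meta(recs)
    genes = [f"g{i:03d}" for i in range(G)]
    df = pd.DataFrame(values, index=genes, columns=meta.index)
    pre = pd.Series(1.0, index=genes) if standardized else None
    return ExpressionMatrix(df, meta, pre_z_sd=pre, standardized=standardized)
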