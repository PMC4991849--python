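"""Shared in-memory containers for the lung-development expression pipeline.

The central object is :class:`ExpressionMatrix`, a gene x sample value grid
with per-sample metadata (strain, developmental time point, replicate).
Time points follow the E*/P* naming of mouse developmental days:
embryonic days ("E9.5" ... "E19.5") are prenatal, postnatal days
("P0" ... "P56") count from birth.  A single numeric axis (``day_value``)
orders them: embryonic day minus 20 (so E19.5 -> -0.5) and postnatal day
as-is (P0 -> 0.0), which places birth at zero.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

_TP_RE = re.compile(r"^([EP])(\d+(?:\.\d+)?)$")

#: gestation length (days) used to map embryonic days onto the birth-centred axis
GESTATION_DAYS = 20.0

META_COLUMNS = ["strain", "timepoint", "day_value", "prenatal", "replicate"]


def parse_timepoint(label: str) -> tuple[float, bool]:
    """Return ``(day_value, prenatal)`` for an E*/P* time-point label."""
    m = _TP_RE.match(label)
    if m is None:
        raise ValueError(f"unparseable time point label: {label!r}")
    kind, day = m.group(1), float(m.group(2))
    if kind == "E":
        return day - GESTATION_DAYS, True
    return day, False


def order_timepoints(labels) -> list[str]:
    """Unique time-point labels sorted along the developmental axis."""
    uniq = list(dict.fromkeys(labels))
    return sorted(uniq, key=lambda t: parse_timepoint(t)[0])


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values plus sample metadata.

    Parameters
    ----------
    values
        DataFrame of shape (genes, samples); index = gene ids, columns =
        sample ids.  Log2 units before standardization, z-units after.
    sample_meta
        DataFrame indexed by sample id with columns ``strain``,
        ``timepoint``, ``day_value``, ``prenatal``, ``replicate``.
    pre_z_sd
        Per-gene standard deviation recorded *before* row standardization;
        present iff ``standardized`` is True.
    standardized
        Whether each gene row has been z-scored (mean 0, SD 1).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    pre_z_sd: pd.Series | None = None
    standardized: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if missing:
            raise ValueError(f"sample_meta lacks columns: {missing}")
        if not self.values.columns.equals(self.sample_meta.index):
            # allow same set in different order; realign
            if set(self.values.columns) != set(self.sample_meta.index):
                raise ValueError("values columns and sample_meta index disagree")
            self.sample_meta = self.sample_meta.loc[self.values.columns]
        if self.values.isna().any().any():
            raise ValueError("expression values contain missing entries")
        if self.standardized and self.pre_z_sd is None:
            raise ValueError("standardized matrix must carry pre_z_sd")
        self.values.index.name = "gene_id"
        self.sample_meta.index.name = "sample_id"
        # the columns may share the metadata's Index object; detach the name
        self.values.columns = self.values.columns.rename(None)

    # ---- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def timepoints(self) -> list[str]:
        return order_timepoints(self.sample_meta["timepoint"])

    def subset_genes(self, genes) -> "ExpressionMatrix":
        sub = self.values.loc[list(genes)]
        pre = self.pre_z_sd.loc[list(genes)] if self.pre_z_sd is not None else None
        return ExpressionMatrix(sub, self.sample_meta.copy(), pre, self.standardized)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(
            self.values[ids], self.sample_meta.loc[ids], self.pre_z_sd, self.standardized
        )

    def subset_timepoints(self, timepoints) -> "ExpressionMatrix":
        keep = self.sample_meta.index[self.sample_meta["timepoint"].isin(set(timepoints))]
        return self.subset_samples(keep)

    # ---- I/O --------------------------------------------------------------------

    def to_tsv(self, matrix_path, meta_path) -> None:
        df = self.values.copy()
        df.index.name = "gene_id"
        df.to_csv(matrix_path, sep="\t")
        meta = self.sample_meta.copy()
        meta.index.name = "sample_id"
        meta.to_csv(meta_path, sep="\t")

    @classmethod
    def from_tsv(cls, matrix_path, meta_path, standardized: bool | None = None,
                 pre_z_sd: pd.Series | None = None) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        meta["timepoint"] = meta["timepoint"].astype(str)
        if standardized is None:
            # auto-detect: rows already mean ~0 / SD ~1
            mu = values.mean(axis=1)
            sd = values.std(axis=1, ddof=1)
            standardized = bool(
                np.allclose(mu, 0.0, atol=1e-6) and np.allclose(sd, 1.0, atol=1e-6)
            )
        if standardized and pre_z_sd is None:
            pre_z_sd = pd.Series(1.0, index=values.index, name="pre_z_sd")
        return cls(values, meta, pre_z_sd, standardized)


def make_sample_meta(records) -> pd.DataFrame:
    """Build a sample-metadata frame from (sample_id, strain, timepoint, replicate)."""
    rows = []
    for sample_id, strain, timepoint, replicate in records:
        day, prenatal = parse_timepoint(timepoint)
        rows.append(
            dict(sample_id=sample_id, strain=strain, timepoint=timepoint,
                 day_value=day, prenatal=prenatal, replicate=replicate)
        )
    meta = pd.DataFrame(rows).set_index("sample_id")
    return meta[META_COLUMNS]


@dataclass
class ProbeIntensityTable:
    """Long-format probe-level hybridization intensities.

    ``table`` columns: probe_id, gene_id, sample_id, intensity, snp_flag.
    Intensities are linear scale and strictly positive; (probe_id, sample_id)
    pairs are unique.
    """

    table: pd.DataFrame
    sample_meta: pd.DataFrame

    REQUIRED = ["probe_id", "gene_id", "sample_id", "intensity", "snp_flag"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"probe table lacks columns: {missing}")
        if self.table.duplicated(["probe_id", "sample_id"]).any():
            raise ValueError("(probe_id, sample_id) pairs must be unique")
        if (self.table["intensity"] <= 0).any():
            raise ValueError("intensities must be strictly positive")

    @property
    def probe_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["probe_id"]))

    @property
    def gene_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["gene_id"]))

    def probe_gene_map(self) -> dict[str, str]:
        sub = self.table.drop_duplicates("probe_id")
        return dict(zip(sub["probe_id"], sub["gene_id"]))

    def to_tsv(self, table_path, meta_path) -> None:
        self.table.to_csv(table_path, sep="\t", index=False)
        meta = self.sample_meta.copy()
        meta.index.name = "sample_id"
        meta.to_csv(meta_path, sep="\t")

    @classmethod
    def from_tsv(cls, table_path, meta_path) -> "ProbeIntensityTable":
        table = pd.read_csv(table_path, sep="\t")
        table["snp_flag"] = table["snp_flag"].astype(bool)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        meta["timepoint"] = meta["timepoint"].astype(str)
        return cls(table, meta)
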