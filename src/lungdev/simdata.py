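"""Synthetic developmental lung expression data with planted ground truth.

The generator emulates the design of the mouse lung development time
course: three inbred strains (A/J, C57BL/6J, C3H/HeJ), 26 pre- and
post-natal time points (E9.5-P56) with replicate animals per cell, an
E19.5 cell sampled in A/J only, and whole-embryo samples at E9.5.

Genes fall into three planted groups:

* **characteristic genes** share stage-wise step trajectories (one of
  three planted component shapes mimicking the dominant strain-independent
  expression programs), each gene with its own signed amplitude;
* **strain-class genes** carry a constant strain offset in one of the four
  canonical classes (one outlier strain vs an indistinguishable pair, or
  all three strains different);
* the remainder are pure noise.

Values are in z-units; i.i.d. Gaussian noise is added everywhere.  All
randomness flows from a single seeded generator, so runs are byte
reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (ExpressionMatrix, ProbeIntensityTable,
                         make_sample_meta, order_timepoints)
from .staging import CANONICAL_STAGES, WE_STAGE, StageMap

logger = logging.getLogger("lungdev")

DEFAULT_STRAINS = ["AJ", "B6", "C3H"]

DEFAULT_TIMEPOINTS = [
    "E9.5", "E11.5", "E12.5", "E13.5", "E14.5", "E15.5", "E16.5", "E17.5",
    "E18.5", "E19.5",
    "P0", "P2", "P3", "P4", "P5", "P7", "P9", "P11", "P12", "P13", "P14",
    "P18", "P21", "P24", "P30", "P56",
]

#: planted stage partition: WE + the nine canonical lung stages
DEFAULT_STAGE_BOUNDARIES: list[tuple[str, list[str]]] = [
    (WE_STAGE, ["E9.5"]),
    ("EMB", ["E11.5", "E12.5"]),
    ("PSG", ["E13.5", "E14.5", "E15.5"]),
    ("CAN", ["E16.5", "E17.5"]),
    ("SAC", ["E18.5", "E19.5"]),
    ("ALV1", ["P0", "P2", "P3"]),
    ("ALV2", ["P4", "P5", "P7"]),
    ("ALV3", ["P9", "P11", "P12", "P13", "P14"]),
    ("ALV4", ["P18"]),
    ("MAT", ["P21", "P24", "P30", "P56"]),
]

#: stage-level values of the three planted shared trajectories, in z-units.
#: Shapes mimic the dominant components: an overall prenatal-to-postnatal
#: switch, an EMB/PSG + ALV3/ALV4 two-shift pattern, and a higher-frequency
#: pattern with shifts at PSG/CAN, SAC/ALV1, ALV1/ALV2 and ALV4/MAT.
DEFAULT_TRAJECTORIES: dict[str, dict[str, float]] = {
    "traj1": dict(zip([WE_STAGE] + CANONICAL_STAGES,
                      [1.3, 1.1, 0.9, 0.7, -0.5, -0.7, -0.9, 0.3, -1.0, -1.2])),
    "traj2": dict(zip([WE_STAGE] + CANONICAL_STAGES,
                      [-1.0, -1.0, 0.6, 0.7, 0.8, 0.9, 1.0, 0.9, -0.8, -1.0])),
    "traj3": dict(zip([WE_STAGE] + CANONICAL_STAGES,
                      [0.8, 0.9, 1.0, -0.8, -0.9, 0.9, -0.9, -0.8, -0.9, 0.9])),
}

CLASS_C3H = "C3H!=AJ~B6"
CLASS_B6 = "B6!=AJ~C3H"
CLASS_AJ = "AJ!=B6~C3H"
CLASS_ALL = "all-different"
CLASS_NONE = "none"


@dataclass
class ClassSpec:
    """Planted strain-effect class: ``n_genes`` genes where ``outlier``
    deviates by ``offset`` z-units in ``direction`` ('up'/'down') from the
    two indistinguishable strains; for the all-different class ``ordering``
    lists the strains from highest to lowest (offsets +offset, 0, -offset).
    """

    n_genes: int
    outlier: str | None = None
    direction: str = "up"
    offset: float = 2.0
    ordering: tuple[str, ...] | None = None

    def strain_offsets(self, strains) -> dict[str, float]:
        if self.ordering is not None:
            hi, mid, lo = self.ordering
            return {hi: self.offset, mid: 0.0, lo: -self.offset}
        sign = 1.0 if self.direction == "up" else -1.0
        return {s: sign * self.offset if s == self.outlier else 0.0
                for s in strains}

    def pattern_label(self) -> str:
        if self.ordering is not None:
            return " > ".join(self.ordering)
        others = " ~ ".join(s for s in DEFAULT_STRAINS if s != self.outlier)
        op = ">" if self.direction == "up" else "<"
        return f"{self.outlier} {op} {others}"


def default_class_spec() -> dict[str, list[ClassSpec]]:
    """Planted class gene counts, a one-tenth scale of the observed
    four-class census (223/349/152/57 with roughly 40/60 up-down splits)."""
    return {
        CLASS_C3H: [ClassSpec(9, outlier="C3H", direction="up"),
                    ClassSpec(13, outlier="C3H", direction="down")],
        CLASS_B6: [ClassSpec(14, outlier="B6", direction="up"),
                   ClassSpec(21, outlier="B6", direction="down")],
        CLASS_AJ: [ClassSpec(9, outlier="AJ", direction="up"),
                   ClassSpec(7, outlier="AJ", direction="down")],
        CLASS_ALL: [ClassSpec(6, ordering=("B6", "AJ", "C3H"))],
    }


@dataclass
class SyntheticDesign:
    """Design of a synthetic developmental expression data set.

    Defaults reproduce the study conditions: 3 strains x 26 time points x 3
    replicates, E19.5 in A/J only, whole-embryo E9.5 samples, half the
    genes characteristic, planted strain classes at one-tenth of the
    observed census with 2.0 z-unit offsets, and 0.5 z-units of noise.
    """

    strains: list[str] = field(default_factory=lambda: list(DEFAULT_STRAINS))
    timepoints: list[str] = field(default_factory=lambda: list(DEFAULT_TIMEPOINTS))
    replicates_per_cell: int = 3
    stage_boundaries: list[tuple[str, list[str]]] = field(
        default_factory=lambda: [(n, list(t)) for n, t in DEFAULT_STAGE_BOUNDARIES])
    n_genes: int = 2000
    frac_characteristic: float = 0.5
    strain_class_spec: dict[str, list[ClassSpec]] = field(
        default_factory=default_class_spec)
    trajectories: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRAJECTORIES.items()})
    noise_sd: float = 0.5
    amplitude_sd: float = 0.3
    probes_per_gene: int = 4
    snp_probe_fraction: float = 0.05
    snp_bias: float = 1.5
    probe_affinity_sd: float = 0.5
    aj_only_e19: bool = True
    whole_embryo_e9: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_cell < 1:
            raise ValueError("replicates_per_cell must be >= 1")
        for frac, name in [(self.frac_characteristic, "frac_characteristic"),
                           (self.snp_probe_fraction, "snp_probe_fraction")]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_genes < 0 or self.probes_per_gene < 1:
            raise ValueError("n_genes must be >= 0 and probes_per_gene >= 1")
        smap = StageMap(self.stage_boundaries)
        if set(smap.timepoints()) != set(self.timepoints):
            raise ValueError("stage_boundaries must partition the time points")
        if smap.timepoints() != order_timepoints(self.timepoints):
            raise ValueError("stage_boundaries must be contiguous in time order")
        n_class = sum(cs.n_genes for specs in self.strain_class_spec.values()
                      for cs in specs)
        n_char = int(round(self.frac_characteristic * self.n_genes))
        if n_class + n_char > self.n_genes:
            raise ValueError(
                f"{n_char} characteristic + {n_class} class genes exceed "
                f"n_genes={self.n_genes}"
            )

    def stage_map(self) -> StageMap:
        return StageMap([(n, list(t)) for n, t in self.stage_boundaries])

    def sample_records(self):
        """(sample_id, strain, timepoint, replicate) for all present cells."""
        recs = []
        for strain in self.strains:
            for tp in order_timepoints(self.timepoints):
                if self.aj_only_e19 and tp == "E19.5" and strain != "AJ":
                    continue
                for rep in range(1, self.replicates_per_cell + 1):
                    recs.append((f"{strain}_{tp}_r{rep}", strain, tp, rep))
        return recs


@dataclass
class GroundTruth:
    """Planted labels for every synthetic gene (the test oracle)."""

    characteristic_genes: dict[str, list[str]]   # trajectory -> gene ids
    strain_class_labels: dict[str, tuple[str, str]]  # gene -> (class, pattern)
    stage_map_true: StageMap

    def all_characteristic(self) -> set[str]:
        return {g for genes in self.characteristic_genes.values() for g in genes}

    def to_json(self, path) -> None:
        obj = {
            "characteristic_genes": self.characteristic_genes,
            "strain_class_labels": {g: list(v) for g, v in
                                    self.strain_class_labels.items()},
            "stage_map_true": [[n, tps] for n, tps in self.stage_map_true.stages],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            characteristic_genes=obj["characteristic_genes"],
            strain_class_labels={g: tuple(v) for g, v in
                                 obj["strain_class_labels"].items()},
            stage_map_true=StageMap([(n, list(t)) for n, t in obj["stage_map_true"]]),
        )


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(max(n - 1, 0))))
    return [f"g{i:0{width}d}" for i in range(n)]


def simulate_gene_matrix(design: SyntheticDesign) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate a gene x sample z-unit matrix with planted structure.

    Each gene's expected value in a (strain, timepoint) cell is the shared
    stage trajectory (characteristic genes, with per-gene signed amplitude)
    plus the class strain offset (class genes), with N(0, noise_sd^2) noise
    on every measurement.  Characteristic and class gene sets are disjoint.
    """
    rng = np.random.default_rng(design.seed)
    genes = _gene_ids(design.n_genes)
    recs = design.sample_records()
    meta = make_sample_meta(recs)
    smap = design.stage_map()
    tp2stage = smap.timepoint_to_stage()

    n_char = int(round(design.frac_characteristic * design.n_genes))
    traj_names = list(design.trajectories)
    char_assign: dict[str, list[str]] = {t: [] for t in traj_names}
    cursor = 0
    char_genes = genes[cursor:cursor + n_char]
    cursor += n_char
    for i, g in enumerate(char_genes):
        char_assign[traj_names[i % len(traj_names)]].append(g)

    class_labels: dict[str, tuple[str, str]] = {}
    gene_strain_offset: dict[str, dict[str, float]] = {}
    for cls, specs in design.strain_class_spec.items():
        for spec in specs:
            for g in genes[cursor:cursor + spec.n_genes]:
                class_labels[g] = (cls, spec.pattern_label())
                gene_strain_offset[g] = spec.strain_offsets(design.strains)
            cursor += spec.n_genes

    # per-gene signed amplitudes for characteristic genes
    amp = {}
    for t in traj_names:
        for g in char_assign[t]:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            amp[g] = sign * max(0.2, rng.normal(1.0, design.amplitude_sd))

    strain_of = meta["strain"].to_numpy()
    stage_of = meta["timepoint"].map(tp2stage).to_numpy()
    values = np.zeros((design.n_genes, len(meta)))
    gene_traj = {g: t for t in traj_names for g in char_assign[t]}
    for gi, g in enumerate(genes):
        row = np.zeros(len(meta))
        t = gene_traj.get(g)
        if t is not None:
            levels = design.trajectories[t]
            row += amp[g] * np.array([levels[s] for s in stage_of])
        off = gene_strain_offset.get(g)
        if off is not None:
            row += np.array([off[s] for s in strain_of])
        values[gi] = row
    if design.noise_sd > 0:
        values = values + rng.normal(0.0, design.noise_sd, size=values.shape)

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=meta.index), meta,
        pre_z_sd=None, standardized=False,
    )
    truth = GroundTruth(
        characteristic_genes=char_assign,
        strain_class_labels=class_labels,
        stage_map_true=smap,
    )
    logger.info("simulated %d genes x %d samples (%d characteristic, %d class)",
                design.n_genes, len(meta), n_char, len(class_labels))
    return matrix, truth


def simulate_probe_level(design: SyntheticDesign
                         ) -> tuple[ProbeIntensityTable, GroundTruth]:
    """Expand the gene-level simulation into linear-scale probe intensities.

    Intensity = 2^(baseline + gene signal + probe affinity [+ SNP bias]);
    probe affinities are fixed per probe, and a ``snp_probe_fraction`` of
    probes is flagged and given a strain-specific negative bias (emulating
    hybridization loss on a mismatched probe).
    """
    matrix, truth = simulate_gene_matrix(design)
    rng = np.random.default_rng(design.seed + 1)
    genes = matrix.gene_ids
    n_probes = design.n_genes * design.probes_per_gene
    probe_ids, probe_gene = [], []
    for g in genes:
        for k in range(design.probes_per_gene):
            probe_ids.append(f"{g}_p{k}")
            probe_gene.append(g)
    affinity = rng.normal(0.0, design.probe_affinity_sd, size=n_probes)
    snp_flag = rng.random(n_probes) < design.snp_probe_fraction
    biased_strain = rng.choice(design.strains, size=n_probes)

    baseline = 8.0
    sig = matrix.values.to_numpy()  # gene x sample, z-units
    strains = matrix.sample_meta["strain"].to_numpy()
    rows = []
    gene_index = {g: i for i, g in enumerate(genes)}
    for p in range(n_probes):
        gi = gene_index[probe_gene[p]]
        log2 = baseline + sig[gi] + affinity[p]
        if snp_flag[p] and design.snp_bias != 0:
            log2 = log2 - design.snp_bias * (strains == biased_strain[p])
        rows.append(log2)
    log2_mat = np.vstack(rows)
    long = pd.DataFrame({
        "probe_id": np.repeat(probe_ids, sig.shape[1]),
        "gene_id": np.repeat(probe_gene, sig.shape[1]),
        "sample_id": np.tile(matrix.sample_ids, n_probes),
        "intensity": np.power(2.0, log2_mat).ravel(),
        "snp_flag": np.repeat(snp_flag, sig.shape[1]),
    })
    table = ProbeIntensityTable(long, matrix.sample_meta)
    logger.info("simulated %d probes (%d SNP-flagged) for %d genes",
                n_probes, int(snp_flag.sum()), design.n_genes)
    return table, truth
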