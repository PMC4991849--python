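# Methods

This note documents the models, conventions and numerical choices behind
`lungdev`, in the order the pipeline runs. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic study design

The generator (`lungdev.simdata`) emulates a dense developmental
expression time course in three inbred mouse strains: A/J (AJ), C57BL/6J
(B6) and C3H/HeJ (C3H), sampled at 26 time points from embryonic day E9.5
to postnatal day P56 with 3 replicate animals per strain × time point
cell. Two quirks of such designs are reproduced as defaults because the
downstream code must handle them: E19.5 exists only in A/J (that strain
gestates about one day longer), and E9.5 samples are whole embryos rather
than dissected lung (labelled WE and excluded from lung-stage inference).

Genes come in three planted groups, all in z-units:

* **Characteristic genes** (default 50 % of genes) follow one of three
  stage-wise step trajectories — chosen to mimic the dominant
  strain-independent programs: a global prenatal→postnatal switch, a
  two-shift pattern (EMB/PSG and ALV3/ALV4), and a higher-frequency
  pattern (shifts at PSG/CAN, SAC/ALV1, ALV1/ALV2, ALV4/MAT). Each gene
  gets its own signed amplitude (|N(1, 0.3²)|, floor 0.2, random sign),
  so both loading tails of each component are populated. The trajectory
  level sets are scaled so every adjacent lung-stage boundary carries a
  step of at least 1.0 z-units in at least one trajectory; segmentation
  recovery is therefore governed by the step-to-noise ratio.
* **Strain-class genes** carry a constant offset in one strain (or a
  ±offset ordering for the all-different class). Default counts are a
  one-tenth scale of the four-class census observed in this kind of data
  (22/35/16/6 genes with roughly 40/60 up-down splits), with offset 2.0
  z-units.
* The remainder is pure N(0, noise_sd²) noise; noise_sd defaults to 0.5,
  placing the class offsets at 4× noise.

Step trajectories (rather than smooth curves) are the default because they
make the planted segmentation unambiguous — the zero-noise optimum is
unique. The probe-level generator expands gene signals into
`2^(8 + signal + probe affinity)` with per-probe affinities N(0, 0.5²),
and gives a configurable fraction of probes (default 5 %) a SNP flag plus
a strain-specific −1.5 log2 hybridization bias, emulating the artifact the
SNP-probe filter exists to remove.

What the generator does **not** emulate: array batch effects (handled
manually in real studies of this kind), optical noise or saturation,
probe-sequence effects beyond a single affinity constant, and
heteroskedasticity across genes. Passing tests therefore demonstrate
algorithmic correctness and calibration under an idealized noise model,
not robustness to real microarray artifacts.

## Preprocessing

Fixed order: SNP-probe removal → log2 → quantile normalization →
median-polish summarization → per-gene z-score → variance filter.

* Quantile normalization maps every sample column onto the cross-column
  rank-mean reference; ties within a column receive the mean of the
  reference values at their rank positions (deterministic). Missing
  values are an error — imputation is out of scope.
* Median polish runs row-then-column median sweeps, folding the medians of
  the effect vectors into the grand term each pass; tol = 1e-6 on the
  maximum absolute effect change, max_iter = 100, with a warning and the
  current estimate on non-convergence. The gene value per sample is
  grand + column effect. The decomposition reconstructs its input
  exactly by construction.
* Standard deviations use the n−1 denominator throughout. Constant gene
  rows are dropped (logged), not an error.
* The variance filter keeps ceil(f·G) genes by pre-z-score SD, ties broken
  lexicographically by gene id; f defaults to 0.30.

A caveat the tests encode: quantile normalization *assumes* all columns
share a distribution. On zero-noise synthetic data whose planted signal
makes column distributions genuinely differ, it distorts the signal — so
exact chain identifiability is asserted on a circulant fixture where every
column holds the same value multiset, and median-polish identifiability is
asserted separately.

## PCA

Samples are observations, genes (already row-standardized) variables; the
SVD of the sample × gene matrix is used without further centering, since
the z-score already centres every gene. Variance fractions are
σ²ₖ/Σσ². Two loading variants are exposed: raw unit singular vectors and
correlation-scaled loadings Vₖσₖ/√(S−1), which for z-scored genes equal
each gene's Pearson correlation with the component score profile.
Downstream selections are rank-based, so the choice does not affect DLCS
membership. Signs are arbitrary in principle; the deterministic
convention is that each component's largest-magnitude gene loading is
positive, and all selection/union operations are sign-invariant.

Strain score-profile correlations average replicates per (strain, time
point), restrict to time points present in both strains of a pair, and
report Pearson R²; pairs with fewer than three shared points (after the
optional integer lag shift) are NaN rather than an error.

## Staging

Both regression models are ordinary least squares under sum-to-zero
(effects) coding, fitted per component; term p-values are
extra-sum-of-squares F tests. Missing design cells are handled by fitting
on available cells; a confounded design raises an error naming the rank
deficiency. BH FDR control at q = 0.1 is applied across the
(component × term) p-value family by default; the family definition is an
explicit method argument, not hidden state.

Segmentation replaces the visual binning a human would do with exact
dynamic programming over contiguous partitions of the ordered time-point
effect vectors (default components PC1–PC3), minimizing within-stage sum
of squared deviations. For a fixed stage count the optimum is exact;
without one, a BIC-like penalty `n ln(SSE/n) + k ln(n)` chooses k.
`must_link` / `must_split` pins reproduce manual grouping choices (e.g.
forcing P3 into the same stage as P0/P2). Nine lung stages get the
canonical names EMB, PSG, CAN, SAC, ALV1–ALV4, MAT; whole-embryo time
points are prepended as WE without entering the optimization.

## Strain patterns

Tukey-Kramer HSD (valid for unequal group sizes) computes pairwise
q = |Δmean| / √(MSE/2 · (1/nᵢ + 1/nⱼ)) against the studentized-range
distribution with N − k error degrees of freedom; Q defaults to 0.05.
Connecting letters are the maximal cliques of the
"not-significantly-different" graph, lettered in descending-mean order.
Classification into the four classes uses the letters, which resolves
intransitive pairwise triples (e.g. A≠C but A≈B≈C chains) conservatively
to "none"; the full ordering-with-ties pattern is kept in a diagnostics
field. Per-gene classification pools samples across stages by default —
the strain patterns this targets are stage-independent — with a time-point
window argument for stage-restricted follow-up.

## DLCS

Selection is by loading rank, not value threshold: fraction pairs
(pos, neg) per component, each in [0, 0.5], take ceil(f·G) genes per tail,
ties broken by gene id. The canonical fractions are 25 %/25 % for PC1 and
10 %/10 % for PC2 and PC3, read **per tail** (so PC1 contributes up to
half the genes); the per-component-total reading is available by halving
the configured fractions. Sarle's bimodality coefficient with the 5/9
threshold is provided as an advisory diagnostic for the "wide tails on
PC1" choice; it never changes the configuration by itself. The prenatal
variant is the same operation after subsetting samples to E12.5–E16.5,
re-z-scoring and re-running PCA.

Set comparison reports RF = observed/expected overlap (expected =
|A||B|/N) and an exact hypergeometric upper tail computed by log-space
summation of log-pmf terms, so tails far below float underflow (p ~
1e-300 and beyond) remain meaningful via the log10 p field. The universe
is always an explicit argument.

## SAM

The two-class statistic is d = (x̄₂ − x̄₁)/(s + s₀) with the pooled
standard error `s = √((1/n₁ + 1/n₂)(ss₁ + ss₂)/(n₁ + n₂ − 2))`. The fudge
constant s₀ is selected on the 0, 5, …, 100 percentile grid of s,
minimizing the coefficient of variation of the windowed scaled median
absolute deviation of d across s-quantile windows (window count
min(100, G/2)); exact ties go to the smallest grid value, and all-equal s
degenerates to s₀ = 0 with a warning.

The permutation null enumerates all C(n, n₁) label splits when that count
is at most n_perm (default 300) — making the result exact and
seed-independent — and otherwise samples distinct informative splits
without replacement, seeded. Expected order statistics d̄ are the mean of
the sorted permuted d. Band cut-offs at offset δ scan outward from the
origin of the d vs d̄ plot: the upper cut-off is the smallest d among
right-half genes with d − d̄ ≥ δ, mirrored on the left.

**Calling convention.** The "FDR = 0" delta is the smallest δ at which the
*mean* number of genes beyond the cut-offs across the informative label
splits is zero. Splits that reproduce the original grouping (the identity
assignment and, for equal group sizes, its complement) are excluded from
this estimate: they carry the signal itself, not the null. The mean is
preferred over the per-split median as the default summary because a zero
mean implies every informative split shows zero false calls (and hence the
median — the conventionally reported figure — is also zero), whereas
requiring only a zero median lets a handful of genes through on fully null
data in a large fraction of runs: with the original labeling exchangeable
among splits, the smallest median-zero δ undercuts the most extreme null
gene about half the time. Under the mean rule the pipeline's null
behaviour is clean (the test suite checks ≥ 95 % zero-call runs on null
data) while planted signals are still called exactly. The median summary
remains available via `call_significant(..., false_summary="median")`, and
a fixed-δ policy is provided for band exploration.

Stage-transition analysis runs this SAM between each successive stage
pair in stage-map order, pooling strains by default (a strain filter is
exposed), skipping transitions whose stages have fewer than two samples.

## Gene-set statistics

Enrichment is the one-sided hypergeometric (= Fisher exact) upper tail per
term, with term members intersected with the explicit universe and BH
adjustment across terms (same implementation as the staging module).
Term collections are consumed pre-propagated as GMT; ontology-graph
propagation is out of scope. Homolog mapping expands one-to-many
relations (every homolog represented) and collapses many-to-one; unmapped
inputs are returned, not dropped silently. qPCR relative expression uses
ΔCt against the arithmetic mean of control-gene Ct values — the log-domain
equivalent of the geometric mean of control expression — and reports
2^(−ΔCt).

## Problem sizes

The test suite and acceptance script run everything on synthetic data
sized for desk-scale verification: 100–500 genes for unit and property
tests, 2 000 genes × 228 samples for the end-to-end acceptance run,
100-simulation batches for boundary-recovery and SAM null calibration,
2 000 simulations for the HSD family-wise error check, and exhaustive
permutation enumeration (≤ 300 splits) wherever the design allows. These
sizes make the statistical claims testable in minutes while leaving the
algorithms identical at full scale.

## Known limitations

* No batch-effect modelling or correction anywhere in the chain; the
  manual array-exclusion step of real studies has no automated analogue.
* The additive staging model deliberately omits a time-point × strain
  interaction (such designs rarely support one); only the stage-level
  model carries an interaction term.
* SAM here is the two-class unpaired flavour only.
* The four-class strain-pattern scheme is defined for exactly three
  strains; for other designs the connecting-letters output is still
  produced but no class labels are assigned.
* Quantile normalization's shared-distribution assumption is taken as
  given, as in the source workflow; data violating it (e.g. globally
  shifted conditions) will be distorted, not flagged.
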