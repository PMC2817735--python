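# Methods

`qtlci` implements and evaluates three positional confidence-interval (CI)
procedures for quantitative trait loci (QTL) located by composite interval
mapping (CIM) in recombinant inbred line (RIL) populations. This note
records the statistical models, the numerical choices, and the places where
the design was genuinely open.

## Population model and simulator

The simulated population is a selfed RIL panel (RI1): every line is fully
inbred, so each locus carries one of two homozygote classes, coded +1/−1.
Map distance is converted to a single-meiosis recombination fraction with
Haldane's function (no crossover interference), `r = (1 − e^(−2d))/2` with
`d` in Morgans, and expanded to the terminal-generation RIL fraction with
the Haldane–Waddington formula `R = 2r/(1 + 2r)`. Kosambi's function is
available behind a flag but is not used anywhere in the shipped studies.

Genotypes along a chromosome are simulated as a first-order Markov chain:
the first locus is ±1 with probability ½, and each subsequent locus flips
relative to its left neighbour with probability `R(d)` for their distance
`d`. The exact multilocus RI1 process is not Markov — under the true
process the correlation between loci at distance `d` is `1 − 2R(d)`
regardless of intervening loci, whereas the chain composes per-interval
correlations multiplicatively, slightly underestimating long-range
association (at 40 cM: chain ≈ 0.24 vs exact ≈ 0.29 on the benchmark
marker grid). This is the standard approximation used by mainstream
simulators and is accurate at the marker densities studied here; it is
also exactly the model the CIM engine's conditional probabilities assume,
so simulator and analysis are mutually consistent.

Traits are purely additive (appropriate for a fully inbred panel, where no
heterozygotes exist to express dominance): `y = a Σ_k q_k + e` with
`e ~ N(0, σ²_e)` and `σ²_e = K a² (1 − h²)/h²` for `K` QTL. Because a ±1
locus with class frequency ½ has variance 1, this makes the *expected*
genetic variance fraction equal `h²`; the realized per-dataset heritability
fluctuates around it (scaling by realized variance instead was considered
and rejected — expected-variance scaling is what standard simulators do,
and the fluctuation is part of the sampling variability the study is
meant to capture). All four QTL share the same sign of effect; only
"equivalent" magnitudes are specified, and with symmetric ±1 coding and
independent chromosomes the sign choice does not affect any statistic
computed here.

### Benchmark design

The benchmark map has four identical 165-cM chromosomes with 23 markers
each, graded dense → sparse with distance from the position-0 telomere.
The reserved QTL intervals — (11,12), (23,26), (69,84), (114,134) cM, i.e.
1, 3, 15 and 20 cM wide — are consecutive-marker intervals on every
chromosome, and markers exist at 0, 134, 154 and 165 cM (the last three
are needed by the chromosome-end control experiment). Only those
constraints are externally fixed; the full default position list
(0, 2, 4, 6, 8, 10, 11, 12, 14, 17, 20, 23, 26, 33, 43, 55, 69, 84, 99,
114, 134, 154, 165) is this package's choice of filler positions
satisfying them, with whole-cM positions and a smooth density gradient.
Quantities tied to the reserved intervals are insensitive to the fillers;
interval *spill* beyond sparse flanking markers does depend mildly on the
neighbouring gaps.

Study conditions: n = 200 lines, heritability 0.6, four equal additive
effects `a = 1` (each QTL thus accounts for 15% of phenotypic variance on
average), QTL placed at fraction D ∈ {0, 0.10, 0.30, 0.50} of their
flanking interval from the left marker. The end-effect control relocates
Q1 to 154 − 20·D cM (154, 152, 148, 144), mirroring the dense-region
geometry at the far chromosome end.

## CIM engine

The engine is a Haley–Knott-style regression CIM. At each test position
(1-cM grid covering [0, 165] inclusive — 166 positions per chromosome) the
trait is regressed on the expected QTL code given the flanking markers,
plus an intercept and up to five background markers (cofactors), and

    LOD = (n/2) · log10(RSS0 / RSS1)

compares the covariate-only model (RSS0) with the model including the
position predictor (RSS1). A perfect fit is capped at a large finite LOD
(1e6); a predictor that is collinear with the covariates scores 0.

The conditional expectation uses the two-interval Markov chain on
RIL-expanded fractions `R1` (left), `R2` (right):

    P(Q = mL class | mL = mR)  = (1−R1)(1−R2) / (1−R12)
    P(Q = mL class | mL ≠ mR)  = (1−R1)·R2 / R12,   R12 = R1 + R2 − 2·R1·R2

`R12` is the chain composition of the two intervals, which makes the
probabilities sum correctly over the QTL states and agree exactly with
brute-force enumeration of the chain (RIL expansion does not commute with
distance composition, so expanding the summed distance instead would be
internally inconsistent by a few parts per thousand). For a two-class ±1
population the expectation is *linear* in the marker codes,
`E[q|mL,mR] = α·mL + β·mR`, which the scan exploits: the whole predictor
grid is a two-term linear map of the genotype matrix, computed once per
dataset and re-indexed (not recomputed) for bootstrap resamples.

### Cofactor selection

Background markers are chosen by stepwise regression of the trait on all
markers: forward steps add the marker with the smallest partial-F p-value
while it is below 0.05 (ties broken by leftmost genome position), each
addition is followed by backward elimination of any included marker whose
partial-F p-value exceeds 0.05, and selection stops after at most 10
forward additions. The scan uses at most the first five selected markers
in entry order. Entry order stands in for the ranking of the original
CIM software's selector, which is not fully documented; a variant ranking
the selected set by final-model partial F was evaluated and behaved
indistinguishably on the benchmark.

### Covariate blocking

At a test position, a cofactor is excluded from the model if

1. it lies on the same chromosome within 10 cM (boundary inclusive) of the
   test position (the blockout window), or
2. it is one of the two flanking markers of the test position, at any
   distance.

Rule 2 is required by the regression formulation: the position predictor
is a linear combination of exactly those two markers, so leaving either in
the covariate set absorbs the signal being tested. Without it the LOD
collapses in the interior of intervals wider than the window (the
20-cM interval can hold positions >10 cM from a flanking marker),
producing single-point LOD spikes and catastrophic under-coverage of
support intervals in sparse regions. Cofactors on other chromosomes are
never blocked. A variant anchoring the window at the interval ends
instead of the test position was also implemented and produced identical
study results.

### Numerical implementation

Scans group grid positions by their active covariate set (a handful of
groups per cofactor configuration). Per group, an orthonormal basis of the
covariate block is built by SVD (rank-revealing, so duplicate genotype
columns are projected out rather than inverted), the trait and all of the
group's predictors are residualized once, and each position's RSS1 follows
from a rank-one update. This is algebraically identical to per-position
OLS and is verified against a brute-force least-squares oracle to 1e−8 in
the tests. Stepwise selection keeps the candidate pool residualized by
rank-one Gram–Schmidt updates and re-residualizes from scratch whenever
backward elimination removes a marker.

## Confidence-interval procedures

**Support interval (SI).** From the leftmost LOD maximum, extend in both
directions while the curve stays within 2.0 LOD of the peak; truncate at
the chromosome ends. Endpoints are reported on the 1-cM scan grid (no
sub-grid interpolation — the walking speed is the resolution at which the
curve exists). A 2.0-LOD drop is the conservative end of the 1.5–2.0
range conventionally used for ~95% coverage.

**Permutation threshold.** The trait is shuffled against the genotypes P
times; each permuted dataset is analyzed by the complete CIM (cofactor
re-selection included — CIM without its selection step is a different
procedure, and the permuted-data analysis should match the real one; a
flag allows freezing instead), and the genome-wide maximum LOD is
recorded. The threshold is the ⌈P(1−α)⌉-th order statistic of the null
maxima, at α = 0.05 experiment-wise. The genome-wide maximum is the
standard experiment-wise statistic; per-chromosome thresholds were not
used.

**Bootstrap percentile intervals.** Each of B replicates resamples the n
individuals with replacement (trait stays paired with its genotypes) and
is rescanned; the per-chromosome LOD argmax (leftmost on ties) is
recorded. NPCI reuses the cofactor set selected on the original data for
every replicate; CIM-NPCI re-runs stepwise selection on each replicate.
The interval is the central 95% of the peak positions by order statistics
(⌈B·α/2⌉-th and ⌈B(1−α/2)⌉-th). The *selective* variants first discard
replicate peaks not exceeding the original data's permutation threshold;
if fewer than 0.2·B peaks survive, the non-selective interval is reported
and flagged. Chromosomes whose original-data peak does not exceed the
threshold yield no interval and are reported as non-significant; the
study driver counts them both ways (excluded from the denominator, and as
non-covering), since either accounting is defensible.

Within the study driver the NPCI and CIM-NPCI analyses share each
replicate's resampled rows, pairing the two methods on identical
resamples; this halves the simulation cost and only reduces the variance
of their comparison.

## Study driver and replication

For each sub-simulation the driver simulates N datasets, runs selection +
scan, extracts SIs, computes the permutation threshold, runs the
bootstrap for both methods, and records width and containment
(inclusive, on closed intervals) per QTL, summarized as binomial coverage
proportions and mean widths with standard errors. Per-dataset random
streams are spawned by counter from a single master seed
(`SeedSequence(seed, spawn_key=(condition, dataset, stage))`), so any
dataset is reproducible in isolation, results are invariant to execution
order, and a dataset keeps its identity when a condition is re-run at a
different N.

Default replication is desk-scale: N = 100 datasets per sub-simulation for
SI-only studies, N = 25–50 with B = 200 bootstrap replicates and P = 100
permutations for bootstrap studies (the full design is N = B = P = 1000;
all counts are plain configuration fields). At these sizes the complete
acceptance computation is a few hundred thousand scans. Tolerances used
when comparing against full-replication reference values inflate the
reference standard errors by √(1000/N), times three, plus a fixed 10%
engine allowance (below).

## Known limitations

- **Engine class.** The reference results for this design were produced
  by a maximum-likelihood mixture CIM; this package uses Haley–Knott
  regression throughout (the spec-level choice). On complete two-class
  data at h² = 0.6 the two give nearly identical LOD curves — an
  exploratory EM mixture implementation reproduced the regression
  engine's support-interval widths to within sampling noise — but the
  10% allowance above acknowledges residual engine differences.
- **Sparse-region widths.** Support intervals around QTL in the 15–20 cM
  intervals at D ≥ 0.3 come out near the top of, and for the Q4 midpoint
  case above, the reference band: with the flanking markers excluded from
  the covariates the LOD stays within 2 of its peak across most of a wide
  interval, and the 2.0-LOD drop then lands in the neighbouring
  intervals. Coverage remains conservative (≥0.95), matching the
  qualitative reference behaviour.
- **Re-selection instability.** With cofactor re-selection on resampled
  data, a replicate occasionally selects a chance-correlated marker
  30–60 cM from a sparse-region QTL; that cofactor absorbs the QTL signal
  at its true location while exposing a ghost LOD peak inside its own
  blockout zone, so the chromosome argmax jumps and the percentile
  interval widens. This inflates mean CIM-NPCI widths for Q3/Q4 at
  D ≥ 0.3 relative to the reference values (coverage stays ≥0.95). The
  mechanism is intrinsic to CIM-with-re-selection in this engine; the
  original selector's internal ranking, which evidently damps it, is not
  documented and is out of scope.
- The simulator draws complete, error-free genotypes; real datasets have
  missing data, genotyping error and outlier phenotypes, none of which
  are modelled. Passing tests therefore demonstrate correctness of the
  procedures under the stated model, not robustness to real-data
  artifacts.
- Single-QTL-per-chromosome truth: peak extraction takes one argmax per
  chromosome, so linked QTL on one chromosome are outside the model.
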