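# Methods

`econets` implements an end-to-end analysis of economical small-world
properties of functional cortical networks estimated from multichannel
EEG-like recordings, together with a synthetic-cohort generator that makes
every stage testable without access to clinical recordings.

## The analysis model

### From signal to association matrix

A recording is a channels × samples matrix with sampling rate `fs` and
channel labels. Preprocessing follows standard scalp-EEG practice:

1. **Linked-earlobe re-reference.** With A2 as the implicit zero reference,
   referencing to the digital average (A1+A2)/2 subtracts half of the
   recorded A1 channel from every scalp channel; A1 is then dropped.
2. **Downsampling** (optional) with a zero-phase FIR anti-alias filter,
   e.g. 1 kHz acquisition → 500 Hz analysis rate.
3. **Epoching** into consecutive non-overlapping fixed-length windows
   (default 5 × 10 s) and **per-epoch linear detrending** (least-squares
   line removed per channel).
4. **Morlet band decomposition.** A continuous Morlet wavelet transform
   (dimensionless center frequency ω₀ = 6, 4 voices per octave) is
   evaluated at log-spaced center frequencies covering each band —
   alpha 7.97–15.05 Hz, beta 15.05–31.25 Hz, gamma 31.25–50.78 Hz; the
   band edges are stored as exact constants and partition the axis
   (alpha.high = beta.low, beta.high = gamma.low). The band series is the
   sum of the real parts of the in-band coefficients, i.e. a band-limited
   reconstruction of the signal (coefficient magnitudes are available by a
   config switch). Edge effects are mitigated by symmetric padding of five
   Gaussian standard deviations of the longest wavelet, cropped after the
   transform. Because a wavelet filter bank has finite Q, the band series
   rolls off smoothly at the edges: out-of-band rejection reaches 20 dB
   roughly half an octave outside the band, which is where the test suite
   measures it.

Functional connectivity between channels i and j is the **mutual
information** of their band series: the plug-in histogram estimator on 16
equiprobable rank-based marginal bins, in bits, clipped at zero. Rank
binning makes the estimate invariant to monotone rescaling; ties are broken
by first occurrence, so results are deterministic. MI is estimated per
epoch and averaged (concatenation available by config). Zero-lag MI on
real-valued series yields a symmetric nonnegative association matrix with
zero diagonal. Note the plug-in estimator has a positive bias of order
(B−1)²/(2N ln 2) bits; the bias is common to all pairs and therefore
cancels in the rank-based thresholding below.

### Graphs and the efficiency family

The association matrix is thresholded at a network **cost** C — the
fraction of the N(N−1)/2 possible edges retained — by keeping the
K = round(C·N(N−1)/2) strongest pairs (ties at the cutoff broken by
ascending row/column index). At the sparse operating point C ≈ 0.16 a
58-channel matrix yields exactly 264 edges and mean degree ≈ 9.

On each binary graph, with the convention 1/∞ = 0 for disconnected pairs:

- global efficiency `Eglob = mean_{i≠j} 1/L(i,j)`
- nodal efficiency `Enodal(i) = (1/(N−1)) Σ_{j≠i} 1/L(i,j)`
  (its mean over nodes equals Eglob identically)
- local efficiency `Elocal = mean_i Eglob(G_i)`, where `G_i` is the
  subgraph induced by i's neighbors; nodes with fewer than two neighbors
  contribute 0
- clustering `Cp` (Watts–Strogatz mean triangle density) and
  characteristic path length `Lp` (mean finite shortest path)
- cost-efficiency `CE(C) = Eglob(C) − C`, positive for an economical
  network, and its maximum `maxCE` over the cost grid (ties resolve to the
  lowest cost).

The default cost grid is 0.16–0.50 in steps of 0.02 (extensible to 1.0).
Eglob is provably non-decreasing along the nested thresholded graphs;
Elocal rises only as a trend, because an added edge can dilute a
neighbor-induced subgraph.

### Null models, sigma, and the small-world regime

At every cost, 20 **random** nulls (uniform G(n, m) with matched node and
edge counts) and 20 **regular** nulls are generated. The regular null is a
deterministic ring lattice: each node is connected to its k/2 nearest
neighbors per side with k = floor(2m/n) rounded down to even, and the
remaining edges are placed at the next ring distance in node-index order,
so the edge count matches exactly. Small-worldness is

    sigma = (Cp / ⟨Cp_random⟩) / (Lp / ⟨Lp_random⟩)  > 1 for small worlds,

and the **small-world regime** is the contiguous cost interval, starting at
the lowest qualifying grid cost, on which the empirical curves satisfy
strictly `⟨Eglob_regular⟩ < Eglob < ⟨Eglob_random⟩` and
`⟨Elocal_random⟩ < Elocal < ⟨Elocal_regular⟩`. A band with no qualifying
cost is marked invalid and excluded from the cohort statistics (the rule
under which gamma-band networks are dropped).

### Cohort statistics

- **Per-cost 2×2 ANOVA** (group × condition) on Eglob, Elocal, CE and
  maxCE. The default `crossed` mode treats the 60 observations
  (15+15 subjects × 2 conditions) as a fully-crossed layout, giving error
  df = 56 per effect — the degrees of freedom under which the study-scale
  F statistics are conventionally reported. The `mixed` mode (condition
  within-subject, group between; error df = 28 at study scale) is the
  statistically conventional alternative and is available by config;
  neither is asserted to be "the" correct analysis, both are documented.
- **Post-hoc t-tests**: paired rest-vs-task within each group, two-sample
  between groups within each condition. Degenerate inputs (zero variance)
  are flagged: zero mean difference → p = 1, nonzero shift with zero
  variance → p = 0.
- **Nodal maps.** Degree and Enodal at the analysis cost (default 0.28)
  are Z-scored per participant map across nodes (population SD, so the
  unit-variance invariant is exact; sample SD by flag); Z-scoring preserves
  each map's topography. Each node then gets the 2×2 ANOVA, with effects
  flagged at three tiers: uncorrected p < 0.05, false-positive correction
  p < 1/N (= 0.017 for N = 58), and p < 0.05/N (= 0.00086). The strictest
  threshold is arithmetically a Bonferroni bound; it is labeled
  `fdr_label` to match the reporting convention without asserting a
  step-up FDR procedure.
- **Duration correlations.** Pearson R (two-sided p) between each patient
  metric and duration of disease, per condition and cost, plus maxCE; an
  age correlation is available as a negative control.

## The synthetic cohort generator

The generator emulates the study design — two groups × two conditions,
15 subjects per group, 58 channels at 500 Hz, five 10-s epochs per
recording — with a known coupling structure:

- **Sources.** Each channel is a unit-variance narrowband AR(2) oscillator
  whose spectral peak sits at the band center; the pole radius is tied to
  the band half-width so the oscillation decorrelates on the band's own
  timescale. One independent source set per band.
- **Coupling.** Channel i receives its own source plus a degree-normalized
  weighted sum of its neighbors' sources along a planted coupling graph
  (Watts–Strogatz by default: ring lattice at cost 0.16 with 20% of edges
  rewired), then white sensor noise of SD 1.
- **Planted effects.** The WS graph is split into its lattice backbone
  (fixed coupling 1.2) and its rewired long-range *shortcut* edges, whose
  coupling carries the effects in the beta band: under the
  planted-interaction preset the cell strengths are control rest/task
  0.7/1.3 and patient rest/task 1.3/0.7 (a pure crossover), and for
  patients the strength additionally changes by −0.04 per year of disease
  duration (durations drawn uniform on 2–25 y), floored at zero with a log
  message. Alpha-band coupling is uniform (1.0) in all cells; gamma-band
  coupling is zero.

  Modulating the *long-range* edges is what gives the planted effects the
  integration direction observed empirically: stronger shortcut coupling
  lifts the true shortcuts above the lattice's indirect (two-hop)
  correlations in the MI ranking, so the thresholded graph gains long-range
  edges and Eglob rises. A negative duration slope therefore produces a
  negative duration–Eglob correlation. Modulating all edges uniformly
  would produce the opposite (disintegration) direction, because weak
  coupling degenerates the ranking toward a uniformly random graph — the
  most integrated graph at fixed cost.
- **Seeding.** One master seed expands to per-subject/condition streams via
  `numpy.random.SeedSequence` spawn keys, so cohorts are bit-reproducible
  subject by subject and any subject can be regenerated in isolation.

The generator is a stand-in, not a forward model: it produces no volume
conduction, no 1/f background, no ocular or muscle artifacts, and its
coupling is linear and zero-lag by construction. Passing tests therefore
demonstrate that the pipeline recovers planted band-limited dependence and
its group structure under these idealized conditions — not that it would
behave identically on recorded EEG, where artifact removal and
volume-conduction leakage matter.

## Numerical choices and degenerate inputs

- 1/∞ = 0 for disconnected pairs everywhere; a graph with no connected
  pair has undefined Lp (NaN with a warning), and sigma is NaN when the
  random-null clustering is zero or a path length is undefined.
- Thresholding, the regular lattice, and rank binning all have
  deterministic tie-breaking (ascending index / first occurrence).
- MI of a constant series is 0 by convention (degenerate marginal,
  warning); the estimator requires ≥ 10·n_bins samples per series.
- All-equal ANOVA inputs give F = 0, p = 1 rather than 0/0; zero-variance
  contrasts and constant correlations are flagged `degenerate` instead of
  raising. Degeneracy detection is relative (1e-9 of the data scale).
- Z-scoring a zero-variance map returns zeros with a warning.
- Identical seed + configuration reproduces every pipeline output byte for
  byte; output files carry the config hash and seed, and the `connect`
  stage verifies checksums before skipping work on resume.

## Problem sizes in the test suite

The statistical validation runs the full pipeline on reduced cohorts
chosen to keep the suite fast while preserving the study's subject counts
where power claims are made: 16 channels, a single beta band, one or two
8-s epochs at 125 Hz, WS topology at cost 0.30 with 30% rewiring, a single
threshold cost 0.30; 15 subjects/group for the power and duration-recovery
checks, 5/group across 200 cohorts for the type-I calibration, and 50
single-recording 58-channel simulations for the small-world-regime check.
Small graphs (< 16 nodes) are avoided in the calibration checks because
graph metrics there are so discrete that null p-values are visibly
non-uniform.

## Known limitations

- MI is zero-lag and undirected; no directed or lagged dependence measures.
- Binary graphs only; no weighted or modular analyses beyond degree and
  Enodal.
- The regular-null ring lattice is one deterministic construction among
  several possible edge-remainder placements.
- The histogram MI estimator's bin count (16) is a documented default, not
  a fitted choice; very short epochs need fewer bins.
- The crossed/mixed ANOVA duality reflects a genuine ambiguity in how
  repeated-measures designs of this shape are reported; both modes are
  exposed rather than resolved.
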