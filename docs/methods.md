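# Methods

## The assay and its calculus

The package quantifies cellular metabolic dependencies from protein-synthesis
readouts under metabolic inhibition. A sample is split over four conditions —
vehicle (DMSO), 2-deoxy-D-glucose (2-DG), oligomycin, and both inhibitors —
then protein synthesis is measured per cell as the fluorescence of a
click-labelled noncanonical amino acid (ncAA) incorporated into nascent
proteins during a fixed incubation (default 30 min). For a gated population
with geometric MFIs `D, G, O, B` under the four conditions:

```
ΔMFI = D − B
glucose dependence       = 100 (D − G) / ΔMFI
mitochondrial dependence = 100 (D − O) / ΔMFI
glycolytic capacity      = 100 − mitochondrial dependence
FAO/AAO capacity         = 100 − glucose dependence
```

The two capacities are stored as exact complements of the dependences, so the
conservation identities hold bit-exactly. Both dependence metrics are ratios
of MFI differences, hence invariant under any common affine transform of the
four MFIs (detector gain, additive background) — the property the whole assay
rests on.

### Choice of MFI statistic

The geometric mean is the default: cytometric fluorescence is approximately
lognormal, and the geometric mean is the natural location estimate (and is
what acquisition software reports as gMFI). Non-positive values cannot enter
a log mean; they are dropped and counted, and fewer than `min_events_error`
(default 25) remaining events is an error, fewer than `min_events` (default
100) a LOW_N flag. An arithmetic mean is available by configuration.

### QC semantics

Metrics are reported raw, never clamped (an optional clamp exists only at the
reporting layer and preserves the complement identities):

* **MITA** — mitochondrial dependence < 0. Oligomycin can paradoxically
  *increase* translation in some cell states; hiding the negative value would
  hide the phenomenon.
* **NEGATIVE_GLUCOSE_DEP** — the analogous case for 2-DG.
* **OUT_OF_RANGE** — any metric outside [0, 100].
* **LOW_RESOLUTION** — ΔMFI below a resolution floor. Default floor: 3x the
  pooled within-condition standard error of the gMFI (delta method:
  `gMFI · sd(log)/√n`, pooled in quadrature over the four conditions); an
  absolute floor can be configured instead. When ΔMFI ≤ 0 the formulas'
  shared denominator vanishes: the library raises a dedicated error
  (report, never divide), and the pipeline records that population as an
  undefined, LOW_RESOLUTION-flagged row rather than aborting the whole run —
  a deliberate choice so one quiescent population cannot destroy a panel.

### Replicate aggregation

Technical replicates can be aggregated two ways: average replicate gMFIs per
condition and evaluate the formulas once (default; a ratio of averaged
differences is less unstable than an average of noisy ratios), or compute one
profile per replicate and average the metrics. Both are implemented and agree
exactly on identical replicates; the difference on heteroscedastic replicates
is itself a useful sensitivity diagnostic.

## Barcode demultiplexing

Pooled runs label the four conditions with two amine-reactive dyes, each
applied at a high or a low dilution (~100-fold intensity separation), giving
a 2x2 hi/lo grid across two channels. Per channel the split is a
deterministic two-class partition of log10 intensity minimizing within-class
variance — the 1-D analogue of 2-means/Otsu, found exhaustively over sorted
split points via prefix sums (no random initialization; the demultiplexer is
seedless). The threshold is the midpoint of the two class centers; a fit with
center separation ≤ 2·guard fails ("no hi/lo structure"). Events strictly
inside a guard band (default ±0.1 log10) around either threshold are left
unassigned, mimicking the conservative cluster gates an operator would draw
by hand; a tie exactly at the threshold goes to hi (fixed convention).
Widening the guard can only discard borderline events, so the misassignment
rate among *assigned* events is monotone non-increasing in the guard — tested
empirically. Demultiplexing depends on intensities only through log-ratios,
hence is invariant under positive rescaling of the barcode channels.
Unpooled designs (one file per condition, e.g. unbarcoded mouse tissue runs)
bypass demultiplexing via a per-file condition label.

## Gating

Populations are defined by axis-aligned threshold predicates on marker
channels, composable into rectangles, with optional parent gates forming a
forest. This deliberately replaces interactive 2-D polygon gating, which is
out of scope: the simulator's populations are log-separated on marker
channels, so rectangles suffice to validate the quantification chain.
Cutoffs are in raw a.u. (no transform), consistent with taking intensities
as stored everywhere.

## The forward simulator

The simulator exists so that every downstream number can be checked by
parameter recovery. Its model is the simplest one consistent with the
dependence formulas:

* translation factors linear in the truth: `f = 1`, `1 − g/100`, `1 − m/100`,
  `0` for control / 2-DG / oligomycin / both; `m < 0` produces `f > 1`
  (MITA). The formulas applied to the four expected signals return (g, m)
  exactly, so recovery is well-posed by construction.
* incorporation kinetics `I(t) = T0 · f · τ(1 − e^(−t/τ))`, τ = 120 min by
  default — saturating accumulation that is near-linear over the default
  30 min incubation. A translation-block flag (homoharringtonine-style)
  forces `f = 0`, flattening the series at background.
* fluorescence `B + k·I(t)` with multiplicative lognormal noise of zero mean
  log, so the geometric MFI is a consistent estimator of the model signal.
* barcode channels lognormal around hi/lo centers (defaults 1e4/1e2, i.e.
  100x separation; spread 0.15 log10); marker channels lognormal around
  per-population centers (spread 0.1 log10, 10x-separated defaults).
* a more efficiently incorporated ncAA analog or a stimulation is modelled
  as a single multiplicative factor on `T0`.

Default study conditions: 5,000 events per condition, lognormal shape 0.25,
background ≈ 10% of the control signal. Under these, recovered (g, m) sit
within well under 3 percentage points of truth, and the error scales as
n^(−1/2).

What the simulator does **not** emulate: spillover/compensation structure,
doublets, debris, dead-cell autofluorescence, acquisition-time drift,
non-lognormal heavy tails, or cytokine cross-talk between populations.
Passing recovery tests therefore validates the computation, not instrument
artifacts; real data still need the usual upstream QC.

Preset scenarios ship for the regimes that matter: classically vs
alternatively activated macrophages (glycolytic vs mitochondrial
polarization), a quiescent naive-T population (exercises LOW_RESOLUTION),
a MITA T-cell population, and a 4-tissue × 4-sample × 5-population panel in
which macrophages and cDC2s carry the largest between-tissue (g, m) spread —
so tissue identity, not population identity, dominates the profile variance.

## Statistics

* **Paired t** (`paired_difference_test`): classical two-sided t on
  within-donor differences; all-zero differences return t = 0, p = 1; ≥ 3
  complete pairs required.
* **Vs-control comparisons** (`compare_to_control`): the repeated-measures
  many-to-one design is reduced to paired t statistics of each group against
  the shared control. Because all statistics share the control donor values
  they are equicorrelated; the family-wise adjustment is Dunnett-style,
  estimating `P(max_j |T_j| ≥ |t_j|)` under the joint null by seeded
  Monte-Carlo (default 20,000 draws; add-one estimator, floored at the raw
  p so adjusted ≥ raw always). A family of size one reduces exactly to the
  raw paired t. Monte-Carlo was chosen over multivariate-t quadrature
  deliberately: its calibration is itself a test (measured family-wise error
  ≈ 5% over 2,000 null simulations).
* **Sidak** (`sidak_adjust`): closed form `1 − (1 − p)^k` for pre-declared
  pairwise contrasts in two-factor layouts.
* **PCA** (`pca_profiles`): complete-case rows of the samples × 
  `population:metric` matrix, features centered and (by default) scaled to
  unit variance — scaling is a flag since dependence features already share
  a percent scale. Only glucose and mitochondrial dependence enter the
  matrix: the capacities are affine complements and would exactly duplicate
  every axis of variance. Computed by SVD; explained fractions are squared
  singular values over their total; the sign of each component is fixed so
  its largest-|loading| feature loads positively, and top-loading ranking
  breaks ties by feature name — both so that results are reproducible across
  BLAS implementations. Zero-variance features are dropped with a warning.

## Numerical and degenerate-input choices

* CSV I/O round-trips float64 exactly (shortest-repr formatting); the FCS
  writer emits float32, so round-trip error is ≤ 1e-6 relative — both are
  asserted in tests. The FCS reader is intentionally minimal: FCS 3.0/3.1
  list mode, float32 or uniform 16/32-bit integer data, no log-amplified
  parameters, no multi-dataset files; anything else is rejected loudly
  rather than guessed at.
* All simulator randomness flows from one integer seed through a single
  generator; fixed seed ⇒ byte-identical tables and therefore byte-identical
  pipeline outputs.
* Event accounting is closed: per input table,
  assigned + unassigned + ungated = read, recorded in `report.json`.

## Problem sizes

Validation runs use 300 events/condition for exactness checks (noise-free),
5,000 for default-noise recovery (grid of 25 ground-truth pairs), 500–50,000
for the error-scaling check, 2,000 simulations for test calibration, and a
16-sample tissue panel at 1,500 events/condition/population for the PCA —
sizes chosen so each property is measured well inside its Monte-Carlo error.

## Known limitations

* Dependence metrics are *relative* (shares of translation-supporting
  metabolism), not absolute flux; a highly glycolytic population with low
  translation can show the same profile as an active one.
* Secreted-protein loss biases the readout low; the package does not model
  or correct it.
* The incorporation-kinetics form (saturating exponential) is a modelling
  convention; only its near-linearity over the incubation matters for the
  metrics, and τ is exposed in the simulation spec.
* Compensation/spillover handling is out of scope; inputs are quantified as
  stored.
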