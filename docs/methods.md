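# Methods

This note documents the models, estimators and numerical choices behind
`kinmeth`, and what the synthetic-data experiments do and do not
demonstrate.

## Preprocessing model

Raw aligned subreads pass four stages, in this order:

1. **Subread filters.** A subread is kept iff MapQV ≥ 240, aligned
   identity ≥ 0.80 and aligned length ≥ 100 bases.  All three are
   "fail if strictly below" gates; identity is recomputed from the
   alignment (matches / aligned read bases) rather than trusted from
   producer tags.
2. **Error-adjacent masking.** IPDs are unreliable at and around
   alignment errors.  Every event whose read-order index lies within
   `error_mask_radius` (default 1) of a mismatch, insertion or deletion
   loses its IPD; the error event's own IPD is always dropped, so with
   radius 0 exactly the error events are masked.  Mismatches, insertions
   and deletions are treated identically.  A consequence is that every
   surviving observation comes from a match event — insertions (no
   reference position) and deletions (no IPD) can never contribute.
3. **Edge trimming.** The first 10 and last 15 events of each subread
   (read order) are dropped; kinetics near the template/adapter
   transitions are biased.  A subread of ≤ 25 events yields nothing.
4. **Per-molecule normalization.** All surviving IPDs of a molecule
   (pooled over its subreads) are natural-log transformed and their mean
   subtracted.  This removes per-molecule polymerase-speed differences
   and any slow drift over the read, makes every downstream statistic
   exactly invariant to molecule-wise rescaling of raw IPDs (hence to the
   IPD unit), and gives the testable invariant that each molecule's
   emitted observations average to zero (± float rounding).

The centring mean is computed over the *final* retained set (after
masking and trimming), which is what makes the zero-mean invariant exact;
the variant that centres on the pre-trim set is available as
`PreprocessConfig(center_pre_trim=True)`.  IPDs ≤ 0 (log-undefined) are
dropped by default and counted; a floor policy is available.  Mixed IPD
units between native and control inputs are rejected, never converted.

## Scores

With per-(strand *s*, position *p*) WGA control means
`c(s, p) = mean(log IPD_WGA)` aggregated over all control molecules:

* `SM_SN(m, s, p) = mean(log IPD_native at m, s, p) − c(s, p)`, emitted
  when the molecule has cov_SM ≥ `min_cov` surviving observations there
  (default 10) and the control covers (s, p).  cov_SM counts surviving
  observations after masking/trimming, not nominal passes — that is the
  quantity that actually powers the score.
* `Agg_SN(s, p)` pools native observations across molecules first; it
  equals the cov_SM-weighted mean of the SM_SN scores of the covering
  molecules (an identity the tests verify to 1e-9).
* `SM_P(m, s)` pools the molecule's surviving observations over every
  motif site it covers on strand *s*, and subtracts the *unweighted* mean
  of the control's per-site means over the same sites.  Averaging
  per-site control means (rather than pooling raw control observations)
  makes the statistic independent of uneven control depth across sites.
  Sites without a control entry are excluded from both sides and counted;
  molecules with fewer than `min_sites` (default 10) eligible sites are
  skipped.  Strands are scored separately.
* The approximate SM_SN (no WGA sample available) is the native mean
  alone; it inherits sequence-context bias but preserves the
  methylated/non-methylated bimodality, and is flagged `approximate`.

The kinetic signal is read at exactly the modified base's position on the
scored strand; multi-position kinetic signatures are out of scope.

## Mixture model and methylated fraction

The SM_SN (or SM_P) distribution of a motif is modelled as a
two-component 1-D Gaussian mixture fitted by a self-contained EM:

* Initialization: median split of the sorted scores, plus one seeded
  random-responsibility restart; the higher-likelihood solution is kept,
  so the fit is deterministic given (data, seed).
* Convergence: per-observation log-likelihood gain < `tol` (default
  1e-7), or `max_iter` (1000).  Component standard deviations are floored
  at 1e-3 to prevent collapse onto single points.
* Components are reported ordered by mean; the fit also records whether
  BIC prefers one component (2 parameters) or two (5 parameters).

The methylated fraction is the weight of the higher-mean component, with
no posterior thresholding.  Two edge cases need care.  When the data are
effectively unimodal (a fully methylated or fully unmethylated motif),
EM splits the single mode into two overlapping components whose weight
ratio is arbitrary — so when BIC prefers one component, a location rule
applies instead: fraction 1.0 if the pooled mean sits more than 2 pooled
standard deviations above zero, else 0.0.  A two-component fit whose
means coincide exactly carries no usable split and raises.  All-identical
input degenerates to a point mass whose weight is assigned by mean sign.
`MixtureFit.is_bimodal()` (both weights ≥ 0.1, mean separation ≥ 2 of the
wider sd, BIC preferring two components) is the package's operational
definition of genuine bimodality.

Known behaviour: on real mixtures the EM estimate of the native fraction
is expected to run slightly low wherever a minority of motif sites is
stably unmethylated in the native sample itself; no correction is
applied.

## Negative controls and empirical FDR

Two control constructions support molecule-level calls:

* the **WGA control**, for calling methylated molecules (direction
  `greater`); and
* the **IPD-shuffled control**, for calling non-methylated molecules
  (direction `less`): motif-site observations are permuted across
  (molecule, strand, site) slots, preserving each slot's observation
  count and each molecule's covered-site structure, which disperses any
  minority population into a unimodal distribution near the population
  mean.

`FDR(t) = min(1, control tail fraction / native tail fraction)` at each
candidate threshold (the distinct native scores), then a running minimum
from the least extreme threshold outward enforces monotonicity.  Running
the minimum in that direction (rather than from the extreme tail inward)
matters: at the most extreme thresholds the control tail count is 0 or 1
and the raw ratio is noise, and must not drag down the stable central
estimates — a pure-null construction stays near FDR 1 at central
thresholds while fully separated distributions reach FDR 0.  Default
molecule calls use FDR ≤ 1%.

## Synthetic kinetics generator

For each molecule: an insert position and length are drawn (Gaussian
length, default 250 ± 25 bp short-insert or 5000 ± 800 bp long-insert);
the pass count is `read_length // (insert + 2 * adapter)` (adapter 50 bp),
so ~250 bp inserts under an 8 kb polymerase read give ~22 passes
alternating strands, while multi-kilobase inserts give a single pass.
Each emitted base's log IPD is

```
context(s, p) + molecule_offset + delta * methylated(m, s, p) + Normal(0, noise_sd)
```

* `context(s, p) ~ Normal(0, 0.4)` is **fixed per (strand, position) and
  shared between a native sample and its WGA twin** (same context seed) —
  this is precisely the bias the WGA subtraction removes, so the control
  mechanism is exercised, not assumed.
* `molecule_offset ~ Normal(0, 0.3)` emulates per-molecule polymerase
  speed; per-read normalization must (and does) remove it.
* `delta` defaults to 2.0 natural-log units, the observed location of the
  methylated 6mA component; `noise_sd` defaults to 1.2, which puts the
  SM_SN standard deviation near 0.5 at cov_SM ≈ 10–15, matching the
  canonical simulated-mixture design (components at 0 and 2, sd 0.5).
* WGA samples force `delta = 0` and all truth flags false.

Methylation regimes: `constitutive` (all sites), `phase_variable`
(molecule-level Bernoulli(`f_active`) — an MTase switched on/off between
cells), `stochastic` (site-level Bernoulli(`p_site`) — a universally
active but processivity-limited MTase).  `methylate_strands` restricts
marks to one strand for hemi-methylation scenarios.  Alignment errors are
injected per event at `error_rate` (default 0.08, equal shares
mismatch/insertion/deletion) from a dedicated RNG stream, so truth is
never perturbed and a rate of 0 reproduces the error-free dataset
bit-for-bit under the same seed.

What the generator does **not** emulate: pulse-width signal, polymerase
pausing, chemistry-version kinetics differences, context-*dependent*
methylation effect sizes, mapping ambiguity (alignments are given), and
extended kinetic footprints around a modified base.  Passing tests
therefore demonstrate the statistical machinery — normalization, control
subtraction, mixture estimation, FDR logic — under a faithful structural
model, not robustness to every artefact of real chemistry.

## Validation experiment designs (`kinmeth.validation`)

Problem sizes are chosen to run the whole battery in minutes on one CPU
while keeping each estimate's sampling error well inside the band it is
checked against.

* **EM recovery**: mixtures of Normal(2, 0.5²) and Normal(0, 0.5²) at
  true methylated fractions 5% and 100%, n = 10,000.
* **Null centring**: 800 short-insert native molecules with `delta = 0`
  on a 100 kb reference against a 25x-footprint control; ~1,200–1,400
  SM_SN scores whose mean is compared with 0 at 3 standard errors.
* **Regime discrimination**: 500 long reads per regime on a 20 kb
  reference (≈ 460 SM_P scores after the ≥ 10-site filter);
  phase-variable `f_active = 0.2` is read off as the EM high-mode mass,
  stochastic `p_site = 0.6` as mean SM_P / delta; shuffled controls must
  be unimodal.
* **FDR sanity**: SM_P scores of one WGA long-read sample split into
  relabeled halves (pure null), and constitutive native versus WGA
  (separated).
* **Coverage stability**: a 60% native / 40% WGA molecule mixture at
  ~x20 aligned coverage of a 4 Mb reference (~9,400 short-insert
  molecules, cov_SM centred near 12 under a 12 kb read length), scored
  against an independent 25x-footprint WGA control, then downsampled to
  ~x1 (~470 molecules, ~800 scores) and re-estimated.  The control uses
  a long-insert single-pass library: the per-position baseline needs
  footprint coverage, not passes, and this keeps its cost linear in the
  genome.  At x1 the estimate carries ≈ ±2.5 percentage points of
  sampling noise, dominated by the binomial composition of the molecule
  subsample — the same noise a real x1 experiment would face; the 4 Mb
  genome is the smallest that keeps this comfortably inside the 5-point
  stability band.

The validation experiments use a 12 kb polymerase read length over
short inserts (current-chemistry territory) so that the cov_SM
distribution lands mostly above the default `min_cov = 10` after masking
and trimming; with the historical 8 kb default, cov_SM centres near 8
and most sites would be filtered rather than scored.

## Numerical choices and degenerate inputs

* Scores and kinetics are written with 9 significant digits; reading a
  written table reproduces values to ~1e-9 (relative), and
  write(read(file)) is byte-identical for canonically written files.
* The BAM adapter stores per-base IPDs as float32 array tags; TSV/BAM
  twins agree to 1e-6 relative.
* Coordinates are 0-based everywhere; strands are 0 (forward) / 1
  (reverse); reverse-strand subreads keep events in polymerase temporal
  order (descending reference positions) with bases recorded in
  reference orientation.
* Empty inputs (no rows, no sites, no surviving observations, empty
  score lists) flow through as empty outputs; genuinely unusable inputs
  (malformed rows, unknown ops/strands, mixed score kinds, mixed IPD
  units, missing IPD tags) fail fast with located error messages.
* All stochastic operations take explicit seeds; independent RNG streams
  (structure / noise / errors / shuffling) are derived via
  `numpy.random.SeedSequence`, so runs are bit-reproducible and
  bit-insensitive to toggling error injection.

## Limitations

5mC is out of scope (signal-to-noise too low for this score family).
De novo motif discovery is out of scope; motifs are user inputs, and for
bipartite motifs the modified-base index must be supplied since it is
not inferable from the motif string.  Scores at a site reflect only that
site's position; modifications whose kinetic footprint is strongest at
neighbouring offsets would need a multi-position extension.  The SM_P
statistic keeps strands separate; pooling palindromic-motif strand pairs
into one molecule-level score is a possible variant not implemented.
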