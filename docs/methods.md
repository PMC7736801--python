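# Methods

This package models a droplet-ordered single-molecule DNA sequencing assay:
single dNTPs are cleaved from a trapped template strand in sequence order
(pyrophosphorolysis) and captured by a stream of microdroplets passing over
the strand at a fixed rate, each droplet's contents then being read out as
per-colour fluorescence.  Droplet order carries sequence order; everything
else about the read must be inferred from noisy intensities.  The package
contains (i) a stochastic simulator of such runs, (ii) the analysis chain
that turns droplet intensities into base calls and an aligned read, and
(iii) the two side analyses the assay supports: two-channel
5-methylcytosine classification and local GC profiling.

## Generative model of a run

Per droplet, independently:

1. **Capture.** The number of template bases released into the droplet is
   `k ~ Poisson(lambda)` with `lambda = capture_rate` (default 0.455,
   dimensionless), truncated so the cumulative release never exceeds the
   template length.  The captured bases are the next `k` consecutive
   template bases; their within-droplet order is discarded (stored as a
   multiset).  Poisson is the natural law for rate-limited enzymatic
   release sampled by droplets at fixed frequency; no distribution is
   imposed by the assay itself.  The default rate is the root of the
   truncated-Poisson multi-occupancy equation
   `(1 - e^-l(1+l)) / (1 - e^-l) = 0.21`, i.e. the operating point at which
   21 % of occupied droplets hold more than one base
   (`simulate.solve_capture_rate`, root 0.4543; the default is quoted to
   three figures as 0.455).
2. **Contamination.** Independently per colour, a contaminant dNTP of that
   colour appears with probability `contamination_rate` (default 0.031 per
   droplet per colour; 0.040 is a representative run-to-run alternative).
   Contamination is modelled colour-uniform because only a pooled
   per-colour rate is identifiable; contaminants and genuine captures may
   co-occur (the less restrictive choice).
3. **Reporting.** Every dNTP present reports its mapped channel, except
   with probability `misidentify_rate` (default 0.001, i.e. capture
   specificity 99.9 %) it reports a uniformly chosen wrong channel.
4. **Intensity.** Per channel, the measured intensity is drawn from the
   channel's "occupied" component if the channel was reported, else from
   the "unoccupied" component.  Both components are log-normal on linear
   intensity — Gaussian on log10 intensity — the simplest heavy-tailed
   location-scale family consistent with the assay's two-peak intensity
   histograms; a location-scale Student-t on log10 intensity (`family:
   "log-t"`) can be rendered instead to stress-test the fitting.  A channel
   flagged by several same-colour dNTPs draws once from the single occupied
   component: intensity does **not** count same-colour multiplicity
   ("one or more" is one population).
5. **Diameter.** Cosmetic only: normal(10 um, 1.5 um) truncated to
   (4, 15) um; droplets above 15 um are removed upstream in the physical
   workflow.

Default channel map: A -> 532 nm, G -> 655 nm (the two colours shown in the
assay's example images), C -> 594 nm and T -> 701 nm by convention; all
configurable.

### Calibrated intensity defaults

The default intensity model is *solved*, not hand-picked
(`simulate.calibrate_intensity_model`).  Fixing the unoccupied component at
N(2.0, 0.10) on log10 intensity and the occupied prior weight at 0.30, the
occupied component is determined in closed form by two overlap targets at
the crossing point of the weighted densities: false positive 0.08 % per
droplet per colour (strictly inside the assay's < 0.1 % bound) and false
negative 1.6 % per base per colour.  The solution is occupied
N(3.6568, 0.6255), crossing point 2.3156 (log10 units), verified unique
between the component locations.

### What the simulator does not emulate

Enzyme kinetics and their temperature/buffer dependence, droplet merging
mechanics, raw micrographs, spatial or temporal drift in detection
chemistry, and diameter-dependent intensity normalization.  Passing tests
therefore demonstrate the correctness and calibration of the *analysis*
under the stated statistical model, not the behaviour of a physical device:
in particular, real runs show droplet-to-droplet environmental variability
that widens the occupied component in ways the i.i.d. model cannot produce.

## Occupancy calling

Per channel, a two-component Gaussian mixture is fitted to log10 intensity
by EM.  Initialisation is a deterministic quantile split (lower 60 % /
upper 40 % of log intensities), robust over the 3-40 % occupancy range met
in practice; convergence when the relative log-likelihood change drops
below 1e-8, cap 500 iterations (then flagged unconverged).  A component
weight collapsing below 1e-4, or data without spread, raises a
degenerate-fit error: occupancy is indeterminate on single-population data,
and callers (e.g. blank arrays with zero contamination) must handle it.

A droplet is called occupied in a channel iff its occupancy posterior
strictly exceeds 1/2 — equivalently, for a unimodal crossing, iff intensity
exceeds the crossing point of the weighted component densities.  A
posterior of exactly 1/2 is called unoccupied: the conservative tie-break
against insertion errors.  The crossing point is found by bisection between
the component locations; if several roots exist (possible with very unequal
scales) the one nearest the location midpoint is used and a warning logged.

Overlap error rates are component tail masses beyond the crossing point —
false positive: unoccupied mass above; false negative: occupied mass below
— reported *per component mass*, and computed in closed form (Gaussian
tails on the log scale), cross-checked against adaptive quadrature in the
tests to 1e-8.  The stochastic false-positive rate is estimated separately,
as the per-colour occupied fraction of arrays never passed over the DNA,
with a 99 % Wilson interval.

## Read reconstruction and alignment

Occupancy calls collapse to a `SetRead`: an acquisition-ordered list of
non-empty base multisets.  Two resolutions of multi-base droplet order are
computed:

* **Permutation-averaged identity** — 20 independent uniform draws over
  each multiset's distinct arrangements (a uniform random permutation is
  uniform over distinct arrangements), each aligned to the reference; the
  mean identity is the fair headline accuracy when order is unknown.
* **Best-order identity** — the identity reached if every multi-base
  droplet order is chosen to fit the reference.  Exact exhaustive
  enumeration whenever the joint arrangement space has at most 1e4
  elements; otherwise restart hill-climbing (default 20 random starts,
  sweeping droplets and accepting strict identity improvements until a
  full sweep is quiet) seeded additionally with reference-guided greedy
  starts that arrange each droplet to match the reference window at its
  cumulative offset.  The greedy starts make the search exact in the
  error-free limit and measurably better under load; the result always
  dominates every ordering it evaluated.

Alignment is Smith-Waterman with affine gaps (Gotoh three-state DP,
numba-compiled), scoring match +2, mismatch -2, gap open -3, gap extend -1
by default.  Conventions, fixed and recorded in output metadata because
several are genuinely open choices:

* a gap of length L costs `|open| + (L-1)|extend|` (first gap symbol pays
  the opening penalty); schemes with `|extend| > |open|` are rejected since
  the affine decomposition is then ill-defined;
* identity = matches / alignment columns, gap columns included, over the
  local alignment span;
* N scores as a mismatch against everything, including N, and never counts
  as a match;
* traceback is deterministic: tie order diagonal > up > left, gap states
  prefer closing over extending, and the start cell is the first maximum in
  row-major order — repeated runs are byte-identical.

### An inherent deletion channel

Because intensity does not count same-colour multiplicity, a droplet
capturing the same base twice reports it once: same-base co-captures are
deletions no caller can recover.  At the default capture rate about 21 % of
occupied droplets are multi-base and roughly a quarter of the pairs
collide, so even an otherwise error-free run does not reach identity 1.0.
The error-free limit (identity exactly 1.0) additionally requires a
collision-free capture stream, which the tests assert explicitly rather
than assume.

## Methylation plate

Two detection channels: channel 1 fluoresces for any captured cytosine;
channel 2 relies on a modification-sensitive restriction step blocked by
5-methylcytosine, so it fluoresces for unmethylated dCTP only.
Classification is per-channel occupancy thresholding — not 2-D clustering —
because the channels report independent chemical events:
(-,-) empty, (+,+) dCTP, (+,-) 5mdCTP, and (-,+) inconsistent.
Inconsistent calls are retained and reported, never merged: their rate
estimates the modification-call error of the assay.

## GC profiles

Local GC content is the G/C indicator convolved with a discrete Gaussian
kernel (sigma in bases, default 20; truncated at 4 sigma and renormalized —
mass loss < 1e-4 — reflecting at the ends, which avoids edge bias).
Positions holding N are excluded from both the numerator and the
normalizing weight.  The region mean is the plain unweighted GC fraction,
N excluded.  Whether the published smoothing width denotes a standard
deviation is not stated; standard deviation is assumed here.

## Problem sizes and numerical choices

Statistical checks run at n = 1e5 droplets (binomial standard errors
~5e-4 at the rates of interest) with fixed seeds; end-to-end runs use a
300-base reference and 2,000 droplets, enough for every rate to be
estimated while keeping a full pipeline run in seconds.  Stage seeds are
spawned deterministically from the run seed (`numpy` SeedSequence), so
identical configuration implies byte-identical artifacts.  Monte-Carlo
tolerances are 3 standard errors unless a tighter closed form exists.

## Known limitations

* The mixture family is fixed to log-normal for *fitting*; the log-t
  renderer exists for robustness experiments only.
* Consensus across repeated reads, assembly, and integration of
  methylation calls into sequencing reads are out of scope.
* The loader for externally deposited droplet tables is a thin
  column-mapping path over the CSV reader and is not exercised by tests.
* Identity of real runs depends on droplet-environment variability the
  i.i.d. intensity model cannot reproduce; simulated identities are
  calibrated to the assay's published operating point, not to any specific
  physical run.
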