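# Methods

`cawave` models a calcium-imaging screening workflow for neural stem
cell cultures: cells loaded with a calcium-sensitive dye respond to an
ATP challenge with intracellular calcium transients, the responses are
recorded as a time-lapse fluorescence movie, reduced to per-region
waveforms, rasterized as images, and classified into treatment groups.
This note documents the generative model, the extraction and detection
procedures, the rendering and compositing conventions, the classifier
contract, and the numerical choices behind each — together with what the
synthetic benchmark does and does not establish about real recordings.

## Synthetic trace model

One trace is

F(t) = F0 · (1 + s(t) + w(t) + ε(t)),

where `s` sums spark templates, `w` sums slow-wave templates, and ε is
i.i.d. Gaussian sensor noise in ΔF/F units. All components are functions
of an explicit seed; there is no global random state anywhere in the
package.

**Sparks** (ionotropic, P2X7-type responses) are brief and tapered:
difference-of-exponentials templates
`exp(−u/τ_d) − exp(−u/τ_r)` normalised to unit peak, with fast rise
τ_r = 1 s and decay τ_d = 4 s by default. Event times are Poisson with
rate 0.04 events/s over a 300 s recording sampled at 1 frame/s
(512×512 px when rendered as a movie; recording starts after the
initial global ATP transient has decayed, which the simulator simply
does not generate). Peak ΔF/F amplitudes are lognormal
(median 1.0, shape 0.5). Published recordings of this preparation state
the frame geometry and timing but not the spark kinetics or rate; the
kinetic constants and the rate are this package's own stated
assumptions, chosen to give clearly resolvable yet frequently
overlapping events at 1 Hz sampling.

**Waves** (slower, metabotropic-type responses) are half-sine bumps of
40 s duration, amplitude 0.5 ΔF/F, at 0.008 events/s.

**Per-cell variability.** Every trace carries one lognormal scale
factor (shape 0.35) multiplying all of its event amplitudes. This is
the "wide dynamic-range deviation" that makes single-waveform
classification hard and is the specific nuisance the composite method
is designed to dilute.

**The treatment effect** is a pure kinetic-shape shift controlled by
`effect_knob ∈ [0, 1]`: the positive group's spark decay is lengthened
by `effect_decay_frac·knob` (default +45% at the default knob 0.45) and
its rise shortened by `effect_rise_frac·knob` (−22.5%). Event counts
and drawn amplitudes are byte-identical functions of the seed in both
groups, so spike frequency and dynamic range are matched *by
construction* and the discriminating signal is not a classical waveform
parameter. The default knob of 0.45 is the calibration anchor of the
benchmark: it places a single-waveform classifier at ≈ 0.80 average
precision under the default conditions, the regime in which the
composite comparison is interesting.

## Extraction

**Preprocessing** is a global linear contrast stretch between two
intensity percentiles followed by per-frame spatial Gaussian smoothing
(σ = 1 px). The default percentiles are (0, 100) — i.e. no stretch: in
sparse-cell fields the cells occupy a few percent of pixels, so an
aggressive stretch clips exactly the spark peaks. The stretch is there
for dim 8-bit inputs and is opt-in.

**Hexagonal segmentation.** ROIs are a regular tiling of flat-top
hexagons whose across-corners diameter is 20 μm (cell-sized);
"diameter" is interpreted as the circumdiameter, recorded in output
metadata. Only hexagons whose six vertices lie inside the frame are
kept. Pixel membership is nearest-lattice-center assignment, which for
a regular hexagonal lattice is exactly point-in-hexagon membership;
boundary ties go to the first hexagon in (row, col) center order. The
test suite checks the tiling pixel-for-pixel against a brute-force
point-in-hexagon oracle.

**Traces** are the mean ROI pixel intensity per frame, kept in raw
fluorescence units so the noise model sees the original scale.

**Baseline and noise.** F0 is the median of a running 10th-percentile
filter (60 s window) — a low baseline robust to one-sided positive
excursions. The Gaussian noise scale σ is fitted from second
differences: for i.i.d. noise, Var(F[i+1] − 2F[i] + F[i−1]) = 6σ², and
the scaled median absolute deviation of the second differences is
insensitive to sparks and waves because events are locally smooth. A
second pass drops curvature outliers (event rises/peaks) before
refitting; without it the estimate inherits a small dependence on event
*kinetics*, which would make detection thresholds differ between
treatment groups whose only difference is kinetic — precisely the
contamination the benchmark must exclude. On pure noise the estimator
is accurate to ~5% (median), and to ~13% on event-dense benchmark
traces.

**Spike detection** converts to ΔF/F, subtracts a slow baseline
(centred 30 s moving median — the stand-in for a "smooth slow
dynamics" threshold mode), and marks local maxima of the residual that
exceed k·σ (k = 4) with prominence ≥ k·σ, merging maxima closer than a
3 s refractory gap. The prominence condition suppresses noise bumps
riding on a decay tail, which would otherwise double-count ~4% of
large events. All three constants are configurable.

**Resolution limit.** At 1 frame/s with ~9-sample-wide events, two
events closer than roughly the refractory gap plus one decay constant
(≈ 6 s) are indistinguishable by any threshold detector. At the default
rate (12 events/trace) that merges ~1.5 events per trace: the detector
recovers event *clusters* (6 s linkage) essentially unbiased, and
recovers the raw Poisson rate only in the low-rate regime. Tests assert
exactly those two statements rather than pretending sub-sampling-rate
resolution.

## Rendering and composites

Waveform images are bare polylines (no axes, ticks or labels — any
decoration is classifier-exploitable) on a fixed canvas, default
224×224 px (96×96 in the benchmark for speed). Time maps linearly to
the full width; ΔF/F maps through a **global fixed y-range**, default
[−0.5, 4.0]. No per-trace autoscaling: the across-cell dynamic-range
spread must survive into the images, because diluting it is the entire
point of the composite method and autoscaling would erase it. Values
outside the range are clipped and the clipped fraction recorded (a
warning above 1%). The lossless raster is the unit all tests assert
on; JPEG (quality 90) exists only at the file I/O boundary.

A composite is a 3×3 grid of nine *distinct* same-group waveform
images, drawn uniformly without replacement, tile order randomly
permuted per composite (seeded). Reuse of a waveform across different
composites is permitted and is the default — a pool of N waveforms
yields N composites; the no-reuse mode (every waveform used at most
once overall) exists for the equal-waveform-count control.

## Classifier

The classifier is deliberately a contract, not an architecture: it
must be deterministic given a seed, reach ≥ 0.99 average precision on
linearly separable toy images, and sit at chance on label-shuffled
data. The shipped backend extracts translation-invariant global image
features — intensity moments, the row-occupancy profile (fraction of
foreground per image row, rebinned to 48 bins; invariant to where
events fall in time, sensitive to how much time the trace spends at
each ΔF/F level), and a 12-bin gradient-orientation histogram (slope
statistics of the drawn line, which is where kinetic-shape changes
live) — and fits an L2 logistic regression on standardised features.
Nothing in the feature extractor knows about traces or the 3×3 grid.

Why composites help under this model: each feature of a composite
image aggregates nine independent waveforms, shrinking the per-example
nuisance variance (per-cell amplitude scale, Poisson event count) by
roughly √9 while the group signal is preserved, so the two classes
separate at a distance ~3× the single-image distance.

**Metrics.** "Average precision" is the unweighted mean of the two
per-class precisions at argmax decisions (a class never predicted
contributes precision 0 and is flagged); the threshold-free PR-curve
area for the positive class is reported alongside. Splits are
stratified 90/10 with `round(0.10·n)` test items per class. Voting
segregation of an untrained substance is the fraction of its images
assigned to the positive class, one vote per image, no calibration.

**Equal-count control.** In `composite_matched` mode the composite arm
consumes exactly the single arm's budget of distinct waveforms, in
one-ninth as many images. With this feature-based linear backend the
matched arm still reaches ≈ 0.99 AP — the per-image evidence
aggregation dominates, and a 65-dimensional linear model is not
data-hungry enough to be hurt by 9× fewer examples. A deep-network
backend, which buys its accuracy with sample size, can show the
opposite (near-parity of matched-count arms); the divergence is a
property of classifier families, not of the compositing operation.

## Classical statistics

Per-trace spike frequency (detected events / duration) and dynamic
range (max − min of ΔF/F; the package's documented convention, since no
standard definition exists) are compared between groups with the
unpaired equal-variance Student's t test, two-sided, α = 0.05, no
multiple-testing correction. On the default benchmark (n = 100/group)
the significance rates measured over 400 seeds are 6.0% (frequency)
and 4.3% (dynamic range) — indistinguishable from the nominal false
positive rate, i.e. the kinetic effect is invisible to both parameters
while the composite classifier separates the groups at ≈ 0.99 AP.
That joint property is the package's headline check.

## Problem sizes and runtimes

The default benchmark uses 800 traces/group, 96×96 px tiles and the
logistic backend; one full experiment (simulate → render → composite →
train → evaluate) takes ~10–15 s on one CPU, so the 10-repeat
composite-advantage property and its controls run in a few minutes.
Movie-based tests use small frames (≤ 128×128) with a handful of cells.

## Limitations

* The generator is phenomenological: no receptor or calcium-induced
  calcium-release kinetics, no photobleaching, no drift or motion, no
  correlated (shot) noise, no overlapping cells. Passing benchmarks
  demonstrates that the pipeline recovers what this model generates —
  not that a real screening campaign would reach the same numbers.
* The treatment effect is a single known kinetic dimension; real
  compound effects are unknown mixtures, and a classifier may key on
  artifacts (lot effects, plate position) that the simulator does not
  model. The cell-lot dependence reported for real data is out of the
  synthetic model's reach.
* Spike detection is threshold-based and cannot resolve events closer
  than ~6 s at 1 Hz sampling; detected frequencies are cluster rates.
* JPEG artefacts are not modelled in training (rasters are used
  directly); at quality 90 their effect on the features is negligible
  but untested below that.
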