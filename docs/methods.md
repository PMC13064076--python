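# Methods

## Forward model of the synthetic recordings

The generator (`astroca.synthetic`) produces two-channel movies whose every
quantity is known in closed form, so downstream stages can be checked
against analytic truth rather than against themselves.

**Morphology.** A cell is a soma disc (relative occupied volume vf = 1.0)
with `n_processes` thin radiating processes drawn as 1-px random walks whose
vf decays linearly from 0.6 at the soma edge to 0.05 at the tip. This
construction guarantees pixels across the whole volume-fraction range,
including the ≤ 12.5 % peripheral band the basal-Ca²⁺ analysis operates on.
Soma centers are snapped to integer pixels so that square event footprints
placed around them provably stay inside the cell mask. Somata are placed by
rejection sampling with a minimum separation of two soma diameters;
placement failure raises rather than silently overlapping cells.

**Kinetics.** A planted event holds a per-frame footprint (uniform
concentration across the footprint) and rises linearly to `peak_ca` over
`rise_frames` frames, then decays exponentially toward basal with time
constant `decay_tau` (default 1.5 s, a generic astrocyte transient; the
exact-recovery scenarios use 30 s, see below). Outside the event window the
concentration is exactly `basal_ca`.

**Rendering.** With 1:1 sensor stoichiometry, red = gain·vf·c and
green = gain·vf·B(ca), where B(ca) = 1 + (R−1)·θ(ca) is the Hill brightness
(Kd = 144 nM, n = 2.45) and R the sensor dynamic range. Optional 2×2
spectral crosstalk mixes the channels; optional Poisson shot noise (on
photon-scaled intensities) and Gaussian read noise degrade them. The
noiseless render is bit-deterministic; noise is seeded. Because R for
GCaMP6s in situ is not well constrained, it is an explicit parameter
(default 50) and no analysis result is reported in nM without stating the
assumed R; the dimensionless basal ratio is the primary basal readout for
exactly this reason.

## Normalization chain

`unmix` applies the inverse mixing matrix pixelwise, clipping negative
results to zero with a logged count. `estimate_f0` computes the per-pixel
baseline as the temporal minimum of a smoothed sliding-window low-percentile
envelope (defaults: 100-frame window, 8th percentile, 5-sample moving
average). This returns the constant for constant traces and ignores
transients occupying less than the percentile fraction of some window; the
exact estimator of the original event-detection work is not public, so this
percentile filter is this package's documented choice. The scale factor
`k = median(F₀g/F₀r)/B(basal)` is calibrated once on designated control
recordings and reused (per-recording recalibration is available by simply
calling `process_recording` without a `scale_k`). Pixels whose reference
falls below twice the red-channel background sigma (median absolute
deviation of the sub-median baseline pixels) are excluded from the analysis
mask to avoid ratio instability near zero.

## Event detection

Default threshold ladder {0.5, 1, 2, 3, 4, 5, 7, 10, 15, 20}: it spans the
conventional 0.5–20 range and contains the levels analyzed individually
(2, 5, 10). Connectivity is 26-neighborhood in (x, y, t) by default (6 and
18 selectable); a 26-connected component necessarily spans a contiguous
frame interval, which the feature code relies on. Noise filters: a
component must reach `min_area` = 4 px in at least one frame and span
`min_frames` = 2 frames; these reject single-voxel speckle while keeping
plausible microdomain events, and are configurable since no canonical values
exist. `distance` is the maximum displacement of the intensity-weighted
centroid from its first-frame position (not path length); `max_slope` is
computed on the footprint-mean ΔF/F_R rather than a single-pixel maximum,
for robustness to pixel noise — the ground-truth generator uses the same
definition so oracle comparisons are exact. A single-frame component has no
slope; it is reported as 0 and flagged.

## Feature statistics

Histograms use 32 log-spaced bins per feature (max_size 1–10⁴ µm², duration
0.2–600 s, distance 0.1–100 µm, max_slope 10⁻³–10² s⁻¹); the axes ranges are
this package's choice, as published figures do not pin them numerically.
Counts are divided by the cell count of the field of view and rescaled to a
600-s equivalent recording, then averaged across the recordings of a group
(unweighted; the recording is the statistical unit). Pooling all events
before scaling is the alternative reading and can be obtained by passing a
single concatenated table. Out-of-range feature values are clamped into the
edge bins with a logged count. Inferential statistics (ANOVA etc.) are out
of scope; the module exports tidy tables.

## Volume fraction and basal Ca²⁺

VF normalizes the reference per cell to that cell's 99th-percentile
reference value (expression varies between cells, so a global anchor would
confound expression with morphology). The basal ratio over the VF ≤ 12.5 %
band equals B(basal) for an exactly calibrated reference, hence is strictly
increasing in resting Ca²⁺ and equals 1 at zero Ca²⁺. The optional nM
estimate inverts θ = (ratio − 1)/(R − 1); pixels implying θ outside [0, 1)
are excluded and counted.

## Decomposition

The feature matrix concatenates the four per-recording (level × bin)
histograms; per-block max normalization (default) prevents any feature from
dominating by magnitude; all-zero columns are pruned and all-zero rows
(event-free recordings) retained with a warning. NMF uses scikit-learn's
coordinate-descent solver with one deterministic nndsvda initialization plus
seeded random restarts (default 10), keeping the fit with the lowest
Frobenius error; the k-sweep additionally warm-starts each k from the
previous solution padded with a tiny extra component, which makes the error
non-increasing in k up to solver tolerance. Recovery of planted components
is judged after Hungarian matching on cosine similarity, since NMF is
identifiable only up to permutation and scale — and only when the planted
mixture contains (near-)pure rows, which the mixture fixture therefore
includes. LDA uses the eigen solver with automatic within-class covariance
shrinkage because the histogram space is far wider than the number of
recordings; the separation statistic is the minimum pairwise centroid
distance over the RMS within-class spread in the discriminant space.

## Validation scenarios and problem sizes

Scenario builders in `astroca.scenarios` fix the study conditions:

* `validation_movie` — 128×128 px, 600 frames at 5 fps (a 2-min desk-scale
  stand-in for the nominal 10-min acquisition), 2 cells, 10 planted events,
  20 %/10 % spectral crosstalk, no noise. Event-detection scenarios use
  dynamic range R = 8: with 50 nM resting Ca²⁺ the resting ΔF/F_R is
  7·θ(50) ≈ 0.488, just below the lowest ladder level, so planted events
  are the only suprathreshold structure and recovery statements are exact.
  Events rise over 2 frames and decay with τ = 30 s so the whole planted
  window stays above ΔF/F_R = 2; ground-truth max_slope is defined over
  consecutive frames inside the event window.
* `basal_movie` — event-free 64×64×120-frame recordings at uniform resting
  Ca²⁺ (0/50/55 nM), default R = 50; no thresholding is involved, so the
  resting offset is irrelevant here.
* `small_scene` — 48×48×80-frame single-cell scenes used for batched
  property checks (threshold containment, flood-fill parity).
* `cohort_tables` — a statistical sampler producing condition-labeled event
  tables directly (no imaging), used to exercise the histogram/decomposition
  bookkeeping at realistic table sizes. It emulates more and smaller events
  at 3 h with partial recovery at 24 h, but it is a demonstration cohort,
  not a tissue model: passing tests show the bookkeeping is correct, not
  that any biological effect size is reproduced.

## Limitations

The generator omits motion, photobleaching, focus drift and overlapping
events with heterogeneous within-footprint concentration; the pipeline
accordingly contains no motion or bleaching correction (cultured
preparations with a thermally stabilized stage are the intended regime).
Cell counts are supplied metadata, not automated segmentation. Real
recordings violate the exact-calibration assumptions (unknown R, imperfect
unmixing), so nM basal estimates should be read as relative, not absolute.
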