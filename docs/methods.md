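# Methods

This note documents the models and procedures implemented in `spinesync`,
the parameters that matter, the numerical choices made where the workflow
it automates was manual or unspecified, and what the synthetic-data tests
do and do not demonstrate about real recordings.

## Signal model and synthetic data

### Traces

A fluorescence trace is modeled in ΔF/F-like units as

F(t) = Σᵢ A·k(t − tᵢ) + s(t) + ε(t),

where events tᵢ come from Poisson processes, k is a peak-normalized
difference of exponentials k(τ) ∝ e^(−τ/τ_d) − e^(−τ/τ_r) with fast-indicator
kinetics (rise τ_r = 0.07 s, decay τ_d = 0.6 s by default; an alpha kernel
is substituted when τ_r = τ_d and a single exponential when τ_r = 0),
ε is white Gaussian noise (SD 0.05 by default), and s is a slow sinusoidal
drift (amplitude 0.12 = 0.3 × the default event amplitude 0.4, period
120 s, random phase) included specifically so the detrending stage does
real work. The default event amplitude is 8× the noise SD, the regime in
which single-spine transients are unambiguous by eye and in which the
detection benchmarks are run.

Acquisition constants follow the two imaging geometries the package
targets: spine/dendrite recordings use 0.242-s frames and 3000 frames
(~12 min); population recordings use 0.390-s frames, a 424.27-µm square
field, and 0.830 µm pixels.

### Spine + dendrite recordings

Back-propagating action potentials (rate 0.074 Hz) inject identical event
times into the spine and parent-dendrite traces; local synaptic events
(rate 0.010 Hz) go to the spine only. The local process is inhomogeneous:
inside microglia-contact epochs its rate is multiplied by
`contact_rate_multiplier` (default 2, i.e. 0.010 → 0.020 Hz). Contact
epochs default to a single 5-min interval mid-recording; contact duration
is configurable and should not be read as a measured constant — reported
contact durations are only approximate ("brief, ≈5 min" scale).

### Population recordings

Neuron positions are uniform in the square field. Synchrony is generated
by "assembly" events (rate 0.10 Hz): each event has a uniform random 2D
center, and neuron *i* joins with probability p₀·exp(−dᵢ/λ) with
p₀ = 0.9 and decay length λ = 50 µm, matching the spatial scale of a
single microglial surveillance domain. Joined neurons receive the shared
event time; every neuron additionally fires independent background events
(0.04 Hz). These three numbers are implementation choices — no generative
model for the distance-dependence is published — and were fixed once by a
small calibration grid (20 seeds per point) chosen so that (a) per-neuron
event rates land near observed cortical values (~0.05 Hz) and (b) a single
60-neuron, 3000-frame field yields a clearly negative C.C.–distance
correlation (mean fitted r ≈ −0.28, the same order as published control
cohorts). Exponential decay is the simplest mechanism producing the
qualitative effect; it is not a claim about the true circuit mechanism.

### Contact stacks

Two-channel T×Z×Y×X movies: the red channel holds a static Gaussian spine
blob (σ = 1.2, 1.5, 1.5 voxels in z, y, x) plus a dendrite shaft; the green
channel holds a microglial-process blob (σ = 1.2, 2, 2) that rests 14
voxels away, ramps toward the spine over the 8 frames before a programmed
epoch, sits on the spine during it, and retreats after. Masks are defined
as the half-peak super-level sets; the geometry guarantees ≥ 2 overlapping
Z sections exactly during epochs and ≤ 1 otherwise, with interior voxels at
every overlapping section so photon noise cannot drop a section. A
`single_z` variant shifts the process axially so overlap is confined to
exactly one section — a contact the ≥ 2-Z rule must reject. Photon noise is
Poisson on counts `background + scale × intensity` (defaults 2 and 100,
peak SNR ≈ 10). Per-frame ground-truth Z-overlap counts are computed from
the noiseless masks by direct voxel intersection.

The generator does not model optics (no PSF, no bleaching), microglial
morphology beyond one moving process, motion artifacts (registration is
assumed done upstream), neuropil contamination, or behavioral-state
modulation. Passing tests therefore demonstrate correctness of the
analysis given registered, neuropil-light data — not robustness to those
confounds.

## Analysis pipeline

### ROI segmentation

The correlation image assigns each pixel the mean temporal Pearson
correlation with its existing 4-neighbors (border pixels use fewer);
constant pixels contribute 0, never NaN. Somata are connected components
(4-connectivity) of the thresholded image within plausible area bounds.
Two deviations from the manual workflow are deliberate: the correlation
threshold (default 0.3) replaces visual edge confirmation, and the area
gate (default 30–300 µm²) replaces manual rejection of non-somatic
components; both travel with the output metadata. Like the original
procedure, this only finds neurons that actually fluoresce — silent cells
are expected misses. Spine and dendrite ROIs are user-supplied masks; no
spine auto-segmentation is attempted.

### Detrending

Output[t] = input[t] − P₈(window of ±15 s around t), with truncated edge
windows (no padding — padding would invent data). The implementation uses
a strided sliding window for interior frames and per-frame recomputation
at the edges; it is required (and tested) to equal the naive O(T·W)
recomputation *exactly*, not approximately.

### Baseline and detection

Quiet-region selection is automated by iterative one-sided sigma clipping
(drop frames above μ + 3σ, recompute, ≤ 10 iterations), replacing manual
selection of transient-free stretches for reproducibility. Estimation
fails (rather than returning garbage) if fewer than 10% of frames remain.
Detection runs on the *detrended* trace — the σ-threshold rule is applied
after drift removal, matching the order of the processing chain — with
threshold μ + 4σ. Degenerate σ = 0 (noiseless traces) falls back to
μ + ε so any frame above baseline is flagged. Runs separated by fewer than
`merge_gap` sub-threshold frames (default 1, i.e. no merging) are joined;
the peak is the earliest maximum of a run (determinism under ties). No
minimum event duration is imposed; both knobs are CLI flags since no
published value exists for them.

Note one subtlety: raising the threshold multiplier always shrinks the set
of supra-threshold frames, but can *split* one run into two, so event
counts are not strictly monotone in k_sigma; the tested invariant is frame
shrinkage and event nesting.

### Event classification and epoch frequencies

Spine events are labeled BP when an unused dendrite event peak lies within
±1 frame (242 ms) of their peak — the window matches one acquisition
frame; matching is greedy in spine-peak order, nearest-first,
earlier-dendrite-first on ties, and each dendrite event supports at most
one spine event. All dendrite-trace events are counted as BPs for
dendritic frequency, not only spine-coincident ones. Before/after windows
for epoch frequencies default to the duration of the contact epoch,
abutting it and truncated at recording edges (symmetry; no published
window lengths exist).

### Contact detection

Channels are binarized either at a per-frame percentile (default 99th,
robust to bleaching) or a fixed level; for the synthetic stacks the fixed
half-peak level (background + scale/2 = 52 photons) is the reference
setting, and the per-frame percentile default suits larger fields where
foreground is ≪ 1% of voxels. A frame is a contact when the red ∧ green ∧
spine-ROI intersection spans ≥ 2 Z sections. Restricting to the spine ROI
mirrors the spine-specific screening of the manual workflow; whole-field
overlap is available as a diagnostic. Flagged frames are merged across
gaps of ≤ 2 frames (flicker tolerance — the manual screen has no
equivalent rule) into epochs; contacts/hour = epochs × 3600 / duration.

### Synchrony

Peak times are stamped at frame centers and grouped into 242-ms bins —
retained even for 0.390-s population frames, following the stated bin
width. C.C. is the Pearson correlation of *binary* occupancy vectors
(binarization is the natural reading of grouping peak times into bins);
a count-valued mode exists behind a flag. Degenerate (constant) trains get
C.C. = 0 with a flag rather than NaN so pair tables stay rectangular.
Distance is the 2D within-plane centroid separation in µm (single-plane
imaging; depth ignored). The C.C.–distance relationship is summarized by
Pearson r, two-sided p, and the least-squares slope; per-animal analysis
averages one r per animal and applies a one-sample t test against zero
(needs ≥ 2 animals).

### Statistics

Paired/unpaired/one-sample t, Wilcoxon rank sum (normal approximation),
Pearson correlation, one-way ANOVA + Tukey HSD, and the
D'Agostino–Pearson normality gate (α = 0.05, requires n ≥ 8; smaller
samples are directed to the rank test). All tests are two-sided unless a
one-sided alternative is requested explicitly (the contact-modulation
power analysis uses the one-sided during > before form). Identical paired
samples return t = 0, p = 1 rather than NaN. Pair-level C.C. comparisons
treat neuron pairs as independent observations for fidelity to the
original analyses; this is anticonservative (pairs share neurons) and the
per-animal test is the defensible alternative.

## Validation studies and problem sizes

`spinesync.studies` packages the simulation studies run by the test suite
and by `scripts/acceptance.py`; sizes were chosen to give stable estimates
at interactive runtimes on one CPU:

- detrend oracle equivalence: 100 random 3000-frame traces, exact.
- detection: 50 seeds, 3000 frames, amplitude 8× noise, 0.01 Hz; matched
  within ±3 frames. Sensitivity ≥ 0.9, FP rate ≤ 0.005 Hz required.
- rate recovery: 200 replicates per rate {0.004, 0.010, 0.020, 0.071} Hz,
  truth counts through `event_frequency`, |z| ≤ 3 under the closed-form
  Poisson SE (a generator calibration; the detector's small sensitivity
  loss would be confounded at this precision).
- contact modulation: 20 fields per experiment, 10-min epochs; 40
  experiments for power at multiplier 2 (≥ 0.8 required), 300 for type-I
  at multiplier 1. Rejection-rate checks use a 3-SE binomial band around
  5%, the same 3-SE convention as every other stochastic check here (a
  2-SE band would fail ~1 run in 20 for a perfectly calibrated test).
- contact exactness: 8 seeds × {normal, single-Z} stacks, 300 frames;
  bounds within ±1 frame, zero single-Z epochs, exact agreement with a
  brute-force per-frame voxel-intersection scan.
- contacts/hour: Poisson onsets at 1.17/h, 100 recordings of 12 min.
- synchrony null: 45 independent 0.07-Hz trains × 1000 bins (990 pairs),
  200 replicates; |mean C.C.| < 0.02 and nominal type-I for the distance
  test.
- synchrony recovery: 50 single-field replicates (≥ 90% significant
  negative r required) and 25 seven-animal replicates (≥ 80% rejection).

## Known limitations

- The detector reports runs above threshold, not deconvolved spikes;
  overlapping events within a run are counted once.
- The sigma-clipped baseline assumes activity is sparse; traces that are
  mostly transient fail estimation by design.
- Segmentation merges touching active cells (no watershed split) and
  cannot see silent ones.
- The percentile channel threshold assumes foreground ≪ voxel count per
  frame; small fields with a large process in view should use the fixed
  threshold.
- Binary-bin C.C. saturates for very high event rates where most bins are
  occupied; the count mode is preferable there.
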