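# Methods

This note records the models, conventions, parameter choices and known
limitations behind `mocapkit`. Thresholds quoted without further comment are
the package defaults, all overridable through the functions' keyword
arguments or `PipelineConfig`.

## Data model and conventions

A trial is a set of labelled marker trajectories sampled at a common frame
rate (default 300 fps). Coordinates are right-handed with z up, in
millimetres; frame indices are 0-based; intervals are half-open
`[start, end)`; time in seconds is always `frame / frame_rate` — no hidden
resampling anywhere. A frame where a marker was not reconstructed is flagged
missing and carries NaN, never a zero position. Trajectories repaired by gap
interpolation additionally carry a `filled` mask: filled samples are valid
for continuity-needing computations (windowed speeds, spectra) but excluded
from per-event kinematic measures, where interpolated geometry would
masquerade as data.

The exchange format is a TSV dialect (`frame`, then `label_x/_y/_z` triplets
in sorted label order, empty cells for missing, 6 decimal places) with a
YAML/JSON metadata sidecar. Six decimals make write→read→write bit-stable;
0.000001 mm is far below any physical scale in the data.

## Trajectory repair

Interior gaps strictly shorter than 50 frames (~165 ms) are bridged per axis
by linear interpolation between the flanking observed frames; longer gaps
and gaps touching a trial boundary (no anchor on one side) stay missing.
The strictness (`< 50`, not `≤`) is deliberate and tested.

Jitter events are localized deviations exceeding 0.05 mm in peak prominence
and lasting at most 3 frames (~10 ms). Detection runs per axis:
`scipy.signal.find_peaks` proposes extrema with the prominence threshold,
the event span is the contiguous run around the peak whose deviation from
the base-to-base chord exceeds half the prominence, and spans wider than 3
frames or touching missing data are left alone (gap handling wins —
interpolating across missing data would fabricate structure). Event frames
plus one neighbour on each side are replaced by linear interpolation.
Detection and repair iterate to convergence (≤ 5 passes), which makes the
operation idempotent by construction; on the standard fixtures one pass
converges. Per-axis analysis was chosen over 3D-magnitude analysis because
it is the more sensitive reading and matches how single-axis glitches
present in real traces; the axis is reported per event.

## Quality metrics

Visibility is the per-frame fraction of visible markers and the per-marker
percentage of visible frames; the lower tail of tracking robustness is
summarized as the 5th percentile of the per-frame fraction ("in 95 % of
frames at least this fraction was tracked"). Known-distance accuracy uses
implanted marker pairs: the absolute difference between the measured
inter-marker distance and the implant spacing, per frame, with half
attributed to each marker under the equal-contribution assumption.
Triangulation residuals are consumed as input (they come from the capture
software), pooled over frames and markers, and summarized as median and 95th
percentile per behavioural state; absent residuals yield an explicit
"not available", not zeros. A gap belongs to the state (locomotory or
stationary) of its start frame — unambiguous and stable. Percentiles use
numpy's linear-interpolation definition. Spatial maps bin a per-frame metric
over the arena by the hip-midpoint position; the missing-marker-count map
first smooths counts with a 100-frame (~300 ms) moving average. Empty bins
are NaN, never zero.

## Locomotion

The reference point is the midpoint of the two hip markers. Windowed speed
is the displacement across a centred window divided by its duration,
`‖p(t+w/2) − p(t−w/2)‖ / (w/fs)`, undefined where an endpoint is missing.
Centred alignment keeps onset/offset latency symmetric. Two window scales
coexist: 100 frames (~300 ms) for locomotion-onset detection, 1 s for
reported speeds — the finer window for episode boundaries, the coarser for
stable trial summaries; both are configurable.

A locomotory episode is a maximal interval of speed > 40 mm/s lasting at
least 100 frames, tolerating interior sub-threshold runs of up to 50 frames.
Episodes begin and end on supra-threshold frames (dips are interior
tolerance only), the minimum length applies to the merged interval including
dips, and undefined speed counts as sub-threshold. The implementation is an
explicit run-merge scan, verified against a brute-force fixpoint oracle on
randomized traces.

On the treadmill, the belt axis is the principal horizontal direction of
belt-marker motion, and the belt displacement integrates the mean
frame-to-frame displacement over belt markers visible in consecutive frames
— a natural handoff as markers (20 cm apart on the loop) leave and re-enter
view. On the wheel, each rim marker's path is circle-fitted (plane by SVD,
in-plane centre by least squares); positions are rotated about the fitted
axis by minus the mean unwrapped rim angle. Frames with no visible surface
marker are flagged undefined rather than silently extrapolated. Zero surface
motion leaves the trial unchanged.

Head pose fits a plane per frame to ≥ 3 headplate corner markers (SVD),
orients the normal upward, takes the forward axis from back-pair to
front-pair midpoints projected into the plane, and reports intrinsic
z-y′-x″ (yaw-pitch-roll) Euler angles in degrees. Collinear or
under-observed frames are NaN.

## Motion index

MI at a frame is the mean of the 10-frame (~33 ms) windowed speeds of all
markers visible at that frame; a missing marker is excluded from the
average rather than invalidating the frame, so single-marker occlusion does
not punch holes in the series. A 2D (horizontal) variant is available via
`dims=2`; 3D is the default. The per-window displacement magnitudes feed
the noise-floor sweep: displacements below a floor f are clamped *to* f —
modelling a sensor that cannot resolve motion below its floor, rather than
discarding samples — and a two-sided Wilcoxon rank-sum test compares the
clamped groups at each floor. Groups rendered identical by clamping give
p = 1 by convention. The supporting identity: an isotropic 3D error of
magnitude r projects to r·√(2/3) in any coordinate plane, which converts a
0.35 mm mean triangulation residual into a ~0.28 mm planar noise floor.

## Swing detection and kinematics

**Treadmill.** Continuous running gives a quasi-periodic surface-relative
vertical ankle trajectory; swings are the intervals between consecutive
vertical minima, with the peak at the intervening z-maximum. Minima need
1 mm prominence (suppressing tremor-scale ripples without missing strides)
and a minimum separation of half the expected stride period (50 ms when no
stride-frequency estimate is given). Because the delimiting minimum at a
rest-to-run transition sits somewhere on the stance plateau, boundary
guarantees apply to chain-interior strides; detection is meant to run within
locomotory episodes, as the pipeline does.

**Open field and wheel.** Non-locomotor limb movements defeat vertical-only
detection, so swings are delimited dynamically: 3D ankle speed over 30-frame
(~100 ms) windows, candidate segments above an adaptive threshold (mean +
1 SD of the defined samples — the value is unstated in the source method and
exposed as a parameter), extended backward to the launching acceleration
peak and forward to the conclusion of the deceleration phase. Acceleration
is the gradient of the windowed speed, lightly smoothed (window/4 ≈ 7-frame
moving average) and peak-picked with a 1-SD prominence filter so noise
ripples never masquerade as launch or brake events; both searches anchor at
the segment's speed maximum. "Conclusion of deceleration" is the first frame
after the deceleration peak where braking has decayed to 10 % of its peak —
a threshold far above the noise floor, which keeps boundaries stable to
within a frame or two under 0.2 mm positional noise. Overlapping candidates
merge. These boundaries are definitional (an acceleration peak is a property
of the windowed-speed profile, sitting up to half a window inside the
airborne phase for gentle profiles), so the synthetic generator freezes its
boundary truth for these contexts as the detection on the noise-free
trajectory, while keeping the analytic arc truth for count, height, distance
and duration.

Per swing: duration `(end − start)/fs`; mean/max of instantaneous
frame-to-frame speeds; height as vertical extent (max z − min z) in
horizontal contexts, or the score range along the second principal axis of
the swing's own centred 3D point cloud on the wheel (per-swing PCA
accommodates the varying body angle around the wheel and is rotation
invariant); start-to-end Euclidean distance; 3D path length; and the signed
offset of the peak-speed frame from the vertical-peak frame. Any missing or
gap-filled frame inside a swing invalidates its metrics. On the wheel the
"vertical peak" frame is dominated by climb progression rather than the
radial arc, so peak-speed timing is most interpretable in the treadmill and
open-field contexts.

## Tremor

Per marker axis: Welch PSD (Hann window, 2 s segments, 50 % overlap, mean
removed) restricted to 6–18 Hz — averaging stabilizes the derivative used
for band finding; a smoothing spline with GCV-selected smoothing
(`scipy.interpolate.make_smoothing_spline`), clipped at zero; then band
boundaries by walking outward from the global peak until |dP/df| falls below
10 % of its maximum after having exceeded it. The walk is "unsuccessful"
(triggering the fallback to the local minima flanking the peak) when it
yields an empty, inverted or < 2-bin band; a spectrum whose maximum sits on
a band edge has no band at all.

The band-limited signal (zero-phase 4th-order Butterworth, forward–backward)
yields the analytic signal; amplitude is its modulus, phase its angle. The
first and last second are flagged edge-unreliable: the measured settling
transient of this filter on a few-hertz band spans about a second, and a
shorter margin leaves multi-percent amplitude error inside the "valid"
region. Windowed amplitude is a centred 150-frame (~500 ms) moving average,
truncated at the edges.

Amplitude correlations are Pearson; phase correlations use the Fisher–Lee
circular–circular coefficient, computed with the O(n) double-angle identity
equivalent to the pairwise definition (verified against the O(n²) form in
tests). Under this convention phase-locked series at *any* fixed offset —
including antiphase — score +1, and reflected phases score −1; a rank or
linear option is available for amplitudes only, since linear correlation of
wrapped phases is ill-defined. Matrices exclude frames flagged
edge-unreliable in any retained profile so all entries share one frame set;
constant series give NaN entries. Marker-level summaries average axes; the
movement split compares windowed amplitudes between frames with hip-midpoint
speed above and below 10 mm/s.

## Synthetic generator

The generator emulates the statistical structure the analyses assume, not
mouse biomechanics. Locomotion is an alternating renewal process of
exponential walk/pause segments (means 2 s / 2 s, clipped to [0.8, 10] /
[0.4, 10] s to avoid degenerate slivers) at 150 mm/s with 0.2 s
raised-cosine speed ramps — a plausible open-field walking speed well above
the 40 mm/s episode threshold. Gait tiles walking stretches at 3 Hz strides;
within a stride the ankle holds during stance and advances during a 0.18 s
swing along a raised-cosine vertical arc (default 10 mm) with a
Gaussian-bump horizontal speed profile whose peak sits a configurable offset
after the vertical peak (default +0.05 s), so all three context timing
regimes can be simulated. On the treadmill the arcs run back-to-back
(instantaneous stance), matching the fast-running regime where
minima-to-minima delimitation is exact. Open-field trials walk a circle of
100 mm radius (constant speed while staying inside a 30 cm arena); treadmill
trials put the advance into belt motion with three belt markers on a 600 mm
loop; wheel trials wrap the surface frame onto a 125 mm-radius wheel with
eight rim markers, the mouse anchored at a fixed station while the wheel
rotates underneath. Body markers are rigid offsets from the body frame, so
paired markers hold their exact spacing (14/14/14/18 mm) until noise is
added.

Tremor is an additive per-marker sinusoid (default 10 Hz, 0.5 mm) with
configurable per-marker phase offsets, zero by default — matching in-phase
whole-body oscillation and keeping pairs rigid. Breathing is a 0.2 mm, 8 Hz
vertical oscillation on the shoulder markers. White positional noise
defaults to 0.01 mm per axis: real marker-based trajectories are smooth at
frame scale, and the 0.05 mm jitter-prominence threshold is only meaningful
when baseline noise sits well below it. Gaps (Poisson counts per
marker-minute, geometric durations, mean 20 frames) and glitches
(rectangular ≤ 3-frame, ≤ 0.1 mm vertical offsets) are placed without
overlap; impossible placements raise a generation error rather than
silently truncating. All randomness flows from one seeded generator —
identical seeds give byte-identical trials.

Ground truth: episode intervals are computed from the noise-free
surface-frame reference point with the standard windowed-speed definition
(on the wheel the hip rides ~30 mm above the rim, so its surface-relative
speed is scaled by (r + 30)/r); swing truth is the analytic arc for
treadmill trials and the clean-trajectory detection for accel-based
contexts (see above); tremor truth is the injected frequency, amplitude and
phases; degradation truth is the exact injected event lists.

What passing recovery tests show: the pipeline's estimators are unbiased
and stable against the injected noise, occlusion and oscillation structure
at study-scale parameters. What they do not show: robustness to soft-tissue
artifact, marker mislabelling, non-stationary gait, non-sinusoidal tremor,
or camera-geometry-dependent occlusion patterns — none of which the
generator models.

## Problem sizes

Tests run on trials of 4–40 s at 300 fps (1,200–12,000 frames, 10 markers)
and oracle suites of 100 randomized instances of ≤ 2,000 frames each —
small enough to iterate quickly, large enough that spectral resolution
(0.5 Hz at 2 s Welch segments) and episode/swing statistics (≥ 10 strides,
several episodes) are meaningful. `scripts/acceptance.py` uses 15–40 s
trials and completes in seconds.

## Known limitations

- `read_trial` loads whole trials into memory; minutes-long recordings at
  300 fps are small (tens of MB), so streaming is not worth its complexity.
- The accel-based swing delimiter's boundaries are defined on the windowed
  speed profile; comparisons across window settings are not meaningful.
- The wheel correction assumes a rigid, circular wheel with ≥ 1 rim marker
  visible per frame; it does not model wheel wobble.
- Episode ground truth on synthetic wheel trials uses the hip-height speed
  scaling; other reference markers would need their own radius scaling.
- `noise_floor_sweep` is a within-package detectability analysis, not a
  cohort-level inference tool; group-level statistics are out of scope.
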