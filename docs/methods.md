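# Methods

`rotortrack` quantifies rotational activity in cardiac fibrillation
movies: optical-mapping (or simulated transmembrane-voltage) recordings
on a regular 2-D pixel grid are transformed to phase, phase
singularities (PSs) are detected and tracked, the number of full
rotations of each tracked PS is counted from wavefront-edge distances,
and trajectories are pooled into group statistics and incidence
heat-maps.  This note documents the model assumptions, the parameters
that matter, the numerical choices, and what the synthetic-data tests
do and do not demonstrate.

## Phase mapping

Each tissue pixel's conditioned trace `v(t)` is mean-subtracted and its
quadrature formed by the Hilbert transform; the instantaneous phase is
`atan2(H[v], v)`, wrapped to `[-pi, pi)`.  This maps every action
potential onto one phase cycle regardless of amplitude and period,
which is what makes fibrillation recordings comparable across pixels.
Assumptions: each pixel's trace is oscillatory with a single dominant
cycle (zero-variance pixels are dropped from the mask), and the
recording is long relative to the period.  Analytic-signal end effects
contaminate roughly one dominant period at each end of the trace; those
frames are flagged low-confidence (detections are kept but marked).

A PS is a point with no definite phase around which neighbouring phases
complete a full cycle.  Detection sums wrapped phase differences around
every 2x2 plaquette, visiting corners `(y,x) -> (y,x+1) -> (y+1,x+1) ->
(y+1,x)`; a loop sum beyond `±pi` (the natural floating-point midpoint
between 0 and `2 pi`) is a winding of `±2 pi`.  Chirality `+1` means
counter-clockwise phase increase in image coordinates (x right, y
down); the same convention is used throughout.  Adjacent same-sign
plaquettes (a "thick" singularity) are merged at their centroid; the
plaquette centre, which always lies on half-integer coordinates, rounds
to the nearest pixel with ties going to the plaquette's own top-left
corner (plain nearest-even rounding would bias detections toward even
pixels).  Phase frames are smoothed before detection with a 3x3
*circular* (vector) mean — unit vectors are averaged and the angle
taken — so values straddling the wrap average correctly.

## Pre-processing

Raw fluorescence movies are conditioned per pixel before phase
computation: optional polarity inversion, uniform spatial binning
(default 3x3, mask-aware with a renormalised kernel so tissue pixels
never receive signal from outside the mask), a zero-phase 4th-order
Butterworth low-pass (default 100 Hz cutoff), baseline removal
(default: per-pixel polynomial of order 4; a zero-phase high-pass is
available), and per-pixel min–max normalisation to [0, 1] (zero-range
pixels are dropped from the mask).  Polynomial detrending of a finite
record perturbs an in-band sinusoid by a few percent RMS near the
record edges; the tests bound this rather than pretend it is zero.

## PS tracking

A detection at frame `t` extends an existing trajectory when the
trajectory's last position lies within a box of half-width `d_gap`
pixels per axis (Chebyshev eligibility, matching the square spatial
allowance) within the last `t_gap` frames.  Look-back frames are
searched most-recent first; among candidates in the same frame the
smallest Euclidean distance wins, with residual ties broken by lower
trajectory id and detection order, so linking is deterministic and
independent of the within-frame input order.  When several detections
compete for one trajectory end, assignment is greedy by increasing
distance; losers fall through to older frames and finally start new
trajectories.  By default a detection only extends a trajectory of the
same chirality (opposite-chirality tips annihilate rather than
continue); this can be disabled.  `t_gap` given in ms converts to
frames as `round(ms * rate / 1000)`, never below 1.

Defaults follow the recommended profile for a ~0.13 mm inter-pixel
camera: `d_gap` = 5 px, `t_gap` = 5 ms, with `d_gap` in 2–5 px and L of
15 px suggested around 0.26 mm pitch; `scale_for_pitch` rescales the
pixel-denominated parameters when the inter-pixel distance differs.

## Rotation counting

The leading edge of the spiral wave is the locus where phase jumps from
`pi` to `-pi` — the wavefront of a new action potential — as opposed to
the smooth wavefront-to-wavetail progression.  Within an `L x L` box
centred on the tracked PS (default L = 11 px, clipped and flagged at
grid boundaries), the Sobel gradient magnitude of the wrapped phase is
thresholded: a smooth phase field stays well under ~1 rad/pixel while
crossing the wrap line costs ~`2 pi`, so pixels must exceed both an
absolute floor of `pi/2` rad/pixel and a relative threshold (default
0.5 of the box maximum).  The suprathreshold band is thinned to a
one-pixel skeleton, the connected component attached to the PS (within
a 2-px attachment radius) is retained, and its pixels are indexed by
distance to the PS *at integer radii* `1 .. L//2`: entry `k-1` is the
edge pixel nearest radius `k`.  Frames with no attached suprathreshold
pixel are recorded as missing-edge frames.

Indexing at integer radii, and capping at the box's inscribed radius,
are deliberate: a rasterised diagonal ray has radius steps of `sqrt 2`
and reaches `sqrt 2` times further inside a square box than an axial
ray, so raw pixel lists would make the distance metric swing over a
rotation for purely geometric reasons.

The edge distance between a frame's edge and the trajectory's reference
edge (its first non-empty edge) truncates both to the shorter length
`n_d`, forms the `n_d x 2` matrix of element-wise coordinate
differences of index-matched pixels, and takes its largest singular
value.  Alternate metrics are available: mean matched-pixel Euclidean
distance, and the symmetric Hausdorff distance of the full pixel sets.
Because the singular value of an ideal rotated ray grows as
`sqrt(sum k^2)` with `n_d`, the series is normalised by that factor
(`mean(k)` for the mean metric) before cycle counting; otherwise
frame-to-frame fluctuation of the detected edge length mimics partial
rotations and systematically inflates counts (roughly two-fold in our
synthetic benchmarks).  The normalisation can be switched off.

Rotations are the prominent local minima of the edge-distance series:
each full turn brings the edge back into alignment with the reference.
Minima must have prominence at least 0.2 of the series range; missing
runs longer than 5 frames split the series and minima may not bridge
them (incomplete cycles are not counted), shorter gaps are linearly
interpolated.  A centred moving average (5 frames, shrunk to at most a
tenth of the segment so short series are untouched) suppresses the
pixel-discretisation ripple that otherwise reaches prominence on the
flat top of the series.  A terminal value lower than its predecessor
counts as a completed final return; the reference frame's zero at the
start does not.  Trajectories with more than half their edges missing
are flagged unreliable.  Per trajectory the module reports `N_r`, the
start-to-end per-axis displacement `p_D = (|dx|, |dy|)`, and the full
tracked path.

Known limitation: the edge distance conflates rotation with
translation.  A rotor whose tip oscillates (meanders) with an amplitude
comparable to the edge length superimposes the meander period on the
series; with the default prominence this can add spurious counts when
meander amplitude approaches `L//2` pixels.  Monotone drift is
harmless.

## Statistics

Trajectories with `N_r >=` 2 (configurable) are classed rotational
drivers (RDs).  Pooled outputs: duration and rotation histograms split
by class (default bins 100 ms and 1 rotation); sliding-window counts of
active trajectories and distinct occupied pixels (default 20 ms window,
1-frame step), split into all PS vs RDs; recording-level summary
(counts, distinct locations over integer pixel positions, maxima); and
incidence heat-maps: the per-pixel fraction of recording frames during
which a qualifying trajectory occupied that pixel (simultaneous
occupancy counts once), at thresholds 1, 2, 10 and 20 by default.  The
accounting identity `sum(value) * recording duration = total qualifying
pixel-occupancy time` holds exactly and is asserted in the tests.
Occupancy uses the integer pixel positions of tracked detections, not
interpolated sub-pixel paths.

## Synthetic data

The generator provides ground truth for every stage.  A spiral's phase
field is

    theta(t, x, y) = wrap( c * (atan2(y - y_t, x - x_t) + r / pitch)
                           + 2 pi t / frames_per_rotation )

with chirality `c`, tip path `(x_t, y_t)` (stationary, circular meander,
or user-supplied), and an Archimedean arm of `pitch` pixels per radian.
The temporal term advances positively because an analytic signal's
phase always does; with a decreasing convention the Hilbert-computed
phase could never match the generator's.  The chirality factor
multiplies the whole spatial term so the two chiralities are exact
mirror images at t = 0.  Default pitch is 30 px/rad: at 0.13 mm
inter-pixel distance this is a ~24 mm wavelength, consistent with
~0.25 m/s conduction velocity at a 100 ms rotation period; a much
smaller pitch would wind the arm unphysically tightly.

Voltage is `amplitude * f(theta)` plus seeded Gaussian noise, with
`f(theta) = ((1 + cos(theta - 0.3 sin(theta))) / 2)^2` — a skewed
raised cosine whose upstroke is steeper than its repolarisation.  A
pure cosine would make Hilbert phase recovery trivially exact; with
this waveform the recovered phase still matches the generator phase to
under 0.1 rad circular RMS (the documented contract is 0.3), so the
pipeline is exercised honestly.  All generators are bit-reproducible
under a fixed seed.  A figure-of-eight generator places two
counter-rotating tips (total topological charge 0), a multi-episode
generator emulates disorganised activity by re-seeding short-lived
rotors at random positions, and `apply_dropout` blanks detection frames
to emulate missed detections.

What the synthetic movies do *not* emulate: amplitude decay and
conduction block near a real rotor core, wavefront curvature
heterogeneity, spatially correlated noise, motion artefacts, and
3-D-to-2-D projection of transmural activity.  Passing tests therefore
demonstrate correctness of the algorithms under idealised rotational
activity with additive noise, not performance on any particular
experimental preparation; parameters still need model-specific tuning
on real data.

## Problem sizes and defaults in the test suite

The validation suite uses 40x48-pixel grids, recordings of 0.25–4 s at
1 kHz, noise at 5% of signal amplitude, and 20 seeded replicates per
condition for the rotation-recovery benchmark (periods 50/100/200 ms,
durations 5/10/20 periods); PS localisation uses the full 128x80 camera
frame.  `scripts/acceptance.py` re-runs the same computations at
slightly reduced replication (10 seeds per condition) and reports the
measured quantities as JSON.
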