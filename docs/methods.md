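# Methods

This note documents the models, numerical choices and limitations behind
the `slowwave` pipeline, in the order the stages run.

## Signal model and units

A recording is an `n_channels × n_samples` matrix of extracellular
potentials in μV at a single sampling rate (the BDF reader rejects files
with mixed per-channel rates). All times are seconds from sample 0, all
distances mm. The electrode layout maps channels to sites of a rectangular
grid; grid indices are 0-based row-major with row 0 at the top, and the
layout's `orientation_deg` affects rendering only, never computation.
The BDF dialect is fixed to BioSemi (0xFF + `BIOSEMI` magic, 24-bit
little-endian two's complement); other EDF variants are rejected rather
than guessed, and writing uses the native BioSemi physical range
(±262 144 μV ≈ 0.03 μV/LSB) so round-trips are exact to one LSB.

## Pre-processing

Baseline wander (electrode drift, movement, respiration) sits well below
the slow-wave band; the default removal is subtraction of a 20 s moving
median. The median is blind to brief deflections, so a window of at least
5× the slow-wave period (~20 s for 3 cycles/min gastric rhythm) tracks the
baseline without eating the waves; shorter windows trigger a warning.
High-frequency noise is then removed with a Savitzky–Golay smoother (1 s
window, order 2), which preserves the deflection morphology far better
than a plain moving average. Butterworth filters are applied
forward–backward (zero phase) and wavelet filtering reconstructs only the
kept bands of a Daubechies-4 decomposition; the family and level are
parameters because no single published choice exists. All filters
replicate-pad (IIR: reflect-pad) so no spurious edge events are created,
and all are zero-phase in effect: a clean event's steepest-descent sample
moves by < 1 sample. Window parameters are given in seconds and converted
to odd sample counts, making parameter files sampling-rate independent.

Excluded channels pass through filters untouched, yield no detection
trace, and are treated as missing sites by all maps. Exclusion is
reversible.

## Event detection (FEVT)

Wavefront arrival shows as a sharp *negative* deflection, so the detector
rectifies the negative part of the centred first difference, raises it to
the power `p = 2` to emphasize high-energy edges, and averages it over a
`fevt_smooth_s = 1.0 s` window to form the detection signal D(t). The
smoothing span is deliberately the duration of the falling edge of a ~2 s
gastric deflection: it integrates the entire edge energy into one broad
lobe. With a short (sub-edge) smoother, D stays spiky and single noise
samples cross any reasonable threshold — at 5 dB SNR that costs two orders
of magnitude in false positives; with the 1 s smoother the default
threshold multiplier has wide margins on both sides (doubling η changes
sensitivity by < 10 percentage points).

The threshold θ(t) = max(ε, η · median(D, 15 s)) adapts to slowly varying
noise: a 15 s running median ignores events whose duty cycle is below half
the window, so sparse slow waves do not inflate their own threshold. The
floor ε is proportional to max(D) (10⁻¹²·scale), which keeps mark times
exactly invariant under amplitude scaling. Defaults: η = 5, refractory
T_r = 2 s (supra-threshold runs closer than this merge). Each surviving
run yields one mark at the steepest negative slope of the filtered signal;
for fractionated (multiphasic) runs the mark goes to the *first* descent
peak whose detection signal reaches 50% of the run maximum, implementing
the first-major-deflection convention. The detection score is max(D/θ)
over the run.

## Cycle clustering

Region growing with quadratic-surface stabilization. Seed: the earliest
unassigned mark on the channel with the most 8-connected neighbours
holding unassigned marks within Δt_seed = 10 s (ties to the smallest
channel id). Growth: every frontier site (8-adjacent to the group, channel
not yet in the group) proposes its unassigned mark nearest the predicted
time; proposals within τ = 3 s are accepted best-deviation-first. While
the group has < 6 members the prediction is the mean of assigned
8-neighbour times; afterwards it is the least-squares quadratic surface
T(x, y), refit every 5 acceptances. After each refit, members whose
residual exceeds max(τ, 2 × fit RMS) are ejected and re-queued; an ejected
mark cannot rejoin the same cycle attempt (this bounds the work per cycle
and guarantees termination) but may be adopted by a later cycle, else it
becomes an orphan. Cycles smaller than `min_cycle_size` (default 1)
dissolve into orphans. Cycles are renumbered 1-based by mean member time.
τ and Δt_seed scale with the gastric period (~20 s) and typical array
spans; all constants are exposed parameters.

The grower assumes each wavefront visits an electrode at most once;
re-entrant rhythms that revisit a site within one "cycle" are out of scope
and left to manual regrouping plus the animation view.

## Spatial products

**Interpolation (two stages, exactly).** Stage 1 fills each missing site
having ≥ K₁ = 5 *measured* 8-neighbours with their median; stage 2 repeats
with threshold K₂ = 3 counting measured and stage-1 sites, which fills in
missing borders. The procedure is deliberately not recursive — two stages,
then stop — and never alters measured values. Interpolated values may feed
isochronal rendering and (by default) velocity display, but are excluded
from amplitude, interval and statistical text exports.

**Velocity.** The activation-time gradient g = ∇T (s/mm) is estimated by
central differences (one-sided at borders and next to missing sites), each
component smoothed with a Gaussian kernel (σ = 1 electrode, truncated at
3σ) whose weights renormalize over defined sites. Smoothing the *gradient*
rather than the time map means a plane is a fixed point: for an exact
planar wave every defined speed equals spacing/delay to 1e−9. Velocity is
v = g/|g|², i.e. speed 1/|g| along increasing activation time. Sites with
|g| < 10⁻³ s/mm (speed above 1000 mm/s, effectively simultaneous
activation) are flagged undefined rather than clipped. Near a radial
source the vector-averaged gradient shrinks and speeds bias upward; the
bias is negligible a few electrodes away from the apex.

**Amplitude.** A 1.5 s window centred on the mark is analysed: the first
derivative is smoothed (Savitzky–Golay, 0.25 s, order 2), its
zero-crossings are classified into maxima/minima by the second
derivative's sign, and the amplitude is the highest maximum minus the
lowest minimum. This resists isolated noise extrema better than a raw
max−min (which is kept as the fallback, flagged low-confidence, when a
window lacks a maximum or minimum). The estimate is exactly invariant to
constant offsets. Note that amplitudes are measured on the *filtered*
signal; the default 1 s smoother attenuates a 2 s biphasic deflection by
roughly 5–7%.

**Intervals.** For each consecutive cycle pair, sites where both cycles
hold a *measured* mark get the interval Δt and frequency 60/Δt (cycles per
minute); a site is bradygastric below 2 cpm and tachygastric above 4 cpm
by default — bounds are configurable per species, since porcine rhythms
run far above human norms.

## Synthetic generator

Scenarios compose a propagation pattern (planar by direction/speed; radial
from an origin site; retrograde = planar + 180°; conduction block = a
rectangle either delayed or silenced; tachy patch = a subgrid with a
shorter local period), a waveform (biphasic = first derivative of a
Gaussian, triphasic = Ricker; peak-to-trough set exactly; total width 2 s
by default), and noise (white, mains sinusoid, and baseline wander as a
0.005 Hz sinusoid plus a seeded random walk). Arrival times follow the
closed forms (planar: projection/speed; radial: distance/speed) quantized
to the sample grid — where a deflection can actually be placed — so a
noise-free pipeline run recovers truth exactly. All randomness flows from
one scenario seed. SNR is defined as 20·log₁₀(A / 2σ) with A the
peak-to-trough amplitude and σ the white-noise RMS; the reference
low-SNR condition of 5 dB corresponds to σ ≈ 112 μV under 400 μV events.

Reference study conditions used by the validation suite and
`scripts/acceptance.py`: 8×8 grid at 4 mm, 32 Hz, 600 s of planar waves at
3 cycles/min and 6 mm/s, 400 μV biphasic events, 5 dB white noise plus
200 μV wander and a 0.5 μV/sample random walk, seeds 1–5 (1920 true events
per run). These sizes keep the whole suite under a minute while leaving
every rate estimate with thousands of events.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: electrode-to-electrode amplitude and morphology
variability, fractionated multiphasic events, spike (action-potential)
activity, movement artifacts with event-like edges, spatially correlated
noise, and re-entrant propagation. Detector performance on the synthetic
conditions is therefore an upper bound; the manual review tools exist
precisely because real recordings are harder.

## Visualization

Isochronal maps contour the (optionally interpolated) activation grid at
`isochrone_interval_s` spacing on a red→blue scale (early→late); the band
count over a span is ceil(span/interval). Patch plots bypass contouring.
The electrode overlay draws measured sites black and missing/interpolated
sites white. Contouring will happily interpolate across an activation
block and crowd isochrones there; map review against the velocity field
and animation is the intended guard. Animations light each site at its
activation time and fade it linearly over `tail_s` (the "refractory
tail"); clustered mode colors each cycle distinctly. Rendering is a pure
function of products and style — repeated renders are byte-identical (PNG
metadata is pinned) — and never mutates a product.

## Sessions and exports

A session (filtered recording, layout, parameters, marks, clustering,
provenance) serializes to a single versioned zip; reload reproduces every
downstream product bit for bit. Text exports are tab-delimited with one
header line; the marks table carries channel, grid site, time, cycle (or
`orphan`) and source. Statistical exports contain non-interpolated values
only; `include_interpolated` adds flagged interpolated rows to the
activation table. The layout and parameter files are versioned JSON.
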