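# slowwave

Spatiotemporal analysis of high-resolution (multi-electrode) gastrointestinal
slow-wave recordings.

Gastric peristalsis is coordinated by bioelectrical **slow waves** generated
by the interstitial cells of Cajal. High-resolution mapping places a dense
rectangular array of electrodes (typically 4 mm spacing) on the serosal
surface and records the extracellular deflection — roughly the second
derivative of the transmembrane potential — as each propagating wavefront
arrives. The analysis problem is to go from raw multi-channel signals to
quantitative descriptions of propagation: per-electrode **activation times**,
wavefronts partitioned into **cycles**, and per-cycle **isochronal activation
maps**, **conduction-velocity fields**, **amplitude maps** and
**time-interval (frequency) maps** that expose dysrhythmias such as
bradygastria, tachygastria, ectopic pacemaking and conduction block.

This package implements that pipeline as a scriptable library plus CLI, for
physiologists and bioengineers working with serosal mapping data:

* **Pre-processing** — moving-median baseline subtraction, Savitzky–Golay /
  moving-median / zero-phase Butterworth / wavelet filters, channel
  exclusion.
* **Event detection (FEVT)** — falling-edge, variable-threshold marking of
  activation times. The detection signal is
  `D(t) = ⟨max(0, −s′(t))^p⟩_w` (rectified negative slope to power `p = 2`,
  moving-averaged over `w = 1 s`) compared against the adaptive threshold
  `θ(t) = η · median₁₅ₛ(D)` with `η = 5`; each supra-threshold run yields one
  mark at the steepest negative slope, with a refractory period of 2 s and a
  first-major-deflection rule for fractionated events.
* **Cycle clustering (region growing with polynomial-surface
  stabilization)** — wavefronts grow across 8-connected neighbours from a
  well-supported seed; predicted activation times come from the mean of
  assigned neighbours, then from a continuously refit quadratic surface
  `T(x, y) = a₀ + a₁x + a₂y + a₃x² + a₄xy + a₅y²` once ≥ 6 members exist;
  members with outlying residuals are ejected back into the pool; unadopted
  marks become orphans.
* **Spatial products** — two-stage spatial interpolation of blank sites
  (median of ≥ K₁ = 5 measured neighbours, then ≥ K₂ = 3 measured-or-filled
  neighbours); velocity `v = ∇T / |∇T|²` from Gaussian-smoothed finite
  differences of the activation surface; peak-to-trough amplitude from
  zero-crossings of the smoothed signal derivative in a 1.5 s window;
  per-site intervals between consecutive cycles with brady/tachy
  classification (default bounds 2–4 cycles/min).
* **Visualization** — isochronal contour or patch maps with an electrode
  overlay (black = measured, white = missing/interpolated), velocity quiver
  maps, amplitude and interval maps, and propagation movies with a linear
  "refractory tail" fade.
* **Synthetic generator** — planar / radial / retrograde / conduction-block /
  tachy-patch scenarios with exact ground truth (event times, memberships,
  velocities, periods) for validating every stage; no public dataset
  accompanies this problem domain.

Recordings are read from BioSemi BDF (the 24-bit EDF variant, implemented
bit-exactly with read *and* write support) or plain delimited text; all
internal units are s, μV and mm.

## Worked example

Simulate three minutes of planar propagation at 6 mm/s and 3 cycles/min
(400 μV biphasic events, 10 dB SNR) on an 8×8 array, then run the full
pipeline:

```
$ slowwave simulate --pattern planar --speed 6 --duration 180 --snr-db 10 \
    --seed 42 --out rec.bdf --truth truth.tsv --layout-out layout.json
wrote rec.bdf: 64 channels, 180 s, 576 true events

$ slowwave all --in rec.bdf --layout layout.json --outdir results
wrote session results/session.zip
591 marks
20 cycles, 0 orphans
maps and exports written to results/maps
```

591 marks against 576 true events: at this noise level a handful of noise
deflections cross the threshold; they end up in small spurious cycles (or
orphans) that manual review would discard — real wavefronts carry 64 marks.
Summarizing the exported tables for one full wavefront (cycle 8):

| quantity | recovered | ground truth |
|---|---|---|
| speed (mean ± SD over sites) | 6.05 ± 0.30 mm/s | 6 mm/s |
| amplitude (mean ± SD) | 375 ± 21 μV | 400 μV |
| cycle interval (all pairs) | 19.9 s ≈ 3.02 cpm | 20 s = 3 cpm |

The ~6% amplitude attenuation is the cost of the 1 s Savitzky–Golay
smoothing pass; velocity and rhythm are recovered essentially exactly.
`results/maps/` also contains the rendered activation/velocity/amplitude/
interval PNGs, and

```
$ slowwave animate --session results/session.zip --out wave.gif \
    --t-start 5 --t-end 45
400 frames -> wave.gif
```

writes a propagation movie with per-cycle colors.

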