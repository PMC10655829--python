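# Methods

## The two measurement routes

The quantity of interest is the maximum horizontal rowing force of one
middle leg of an adult water strider (~36 mg).

**Direct route.** A transducer probe hooks the leg between femur and tibia
and records `F_MLBAP(t)` in μN while the insect's body is fixed (isometric
measurement). Modelling the leg as a rigid single beam with a constant
moment, the force at the tip — where the leg meets the water — is

    F_MLDir = (L / L_ML) · F_MLBAP

with `L` the body-to-hook distance and `L_ML` the full leg length. The study
never prints `L` or `L_ML`; it only states the full leg is over twice the
hook distance. The package's default geometry (`L = 11.0 mm`,
`L_ML = 25.0 mm`, ratio 0.44) is the ratio implied by the published mean
forces 955/2172 and is overridable in `BodyGeometry` / `RunConfig`.

**Indirect route.** A free insect is filmed at 1,000 fps; the painted
pronotum marker is tracked, the track is differentiated, and the peak
acceleration `a` enters Newton's law `F_PropImg = m · a`. The unit triple
μN / mg / m·s⁻² is used everywhere because it makes this equation
coefficient-free (1 mg·m/s² = 1 μN). An empirical 70% of the propellant
force is attributed to the two middle legs rowing simultaneously,
`2 · F_MLIndir = 0.7 · F_PropImg`. Both constants (`apportionment`,
`n_legs`) are configuration keys.

Derived reporting quantities: force per unit leg-water contact length
(default contact length 11.0 mm), and the resultant force, a fixed 1.2×
the horizontal force (the vertical component measured photogrammetrically
in the original study enters only through this factor). Rounding to the
precision used in published tables (integer μN and μN/mm, one decimal
elsewhere) happens only at report time, with half-up rounding on a short
decimal rendering so binary representation artefacts cannot flip a digit.

## Synthetic trials

No raw footage or transducer recordings are deposited, so the generator in
`striderforce.synthetic` produces fully ground-truthed stand-ins at the
published kinematic scale.

**Stroke model.** The thrust-phase acceleration is a half-sine,
`a(t) = A sin(π(t−t0)/T)` on `t0 ≤ t ≤ t0+T`, zero before, and linear-drag
coasting `a = −(c/m)·v` after. The half-sine is not claimed by the original
study (which does not state a pulse shape); it is the simplest
two-parameter profile consistent with the published peak acceleration, peak
speed and arrival-time relations, and it integrates in closed form:
`v_max = 2AT/π` at the end of the thrust, `a_max = A` at its midpoint.
Positions are exact piecewise integrals sampled at the frame rate, and the
ground-truth extrema are analytic, never read off sampled arrays. Defaults:
`m = 35.9 mg`, `A = 40.3 m/s²`, `T = 34 ms` (giving `v_max = 872 mm/s`,
inside the observed 864 ± 153 mm/s), `c = 0.2 μN·s/mm` (an initial
post-stroke deceleration of ≈5 m/s², consistent with the mild deceleration
visible after a stroke), onset at 20 ms with a 20 ms stationary baseline.
Motion is 1-D along +x; real insects yaw slightly, which is out of scope.

**Scene.** 256×256 px, 8-bit grayscale, top-left origin, x = column,
frame i ↦ t = i/fps with fps = 1,000 Hz, scale 0.2 mm/px. The marker is a
Gaussian blob (σ = 2 px, peak 180 DN over a 20 DN background) plus i.i.d.
Gaussian noise (σ = 2 DN), clipped and quantised. A filled calibration
square representing the 10 mm reference (50 px) is drawn in the corner of
frame 0, rendered dimmer than the marker (60 DN over background) so it
stays below the marker-detection threshold while remaining trivially
segmentable for scale calibration.

**Direct trace.** Zero baseline, raised-cosine rise to the peak over
`rise_ms` (default 160 ms, the published mean arrival time), then
exponential decay — the asymmetric long-tailed shape seen when the hooked
leg keeps pushing the probe. The noiseless peak is exactly at
`onset + rise`. Transducer sampling is taken as 1 kHz; the original study
names its DAQ hardware but not the rate.

**Angle series.** Linear rise from `θ0` (default 48°) at a set rate ω, so
the 90° crossing falls exactly at `(90−θ0)/ω` and the estimator recovers ω
exactly; after the peak angle the free-rowing profile descends
symmetrically while the hooked-leg profile plateaus.

What the generator does **not** emulate: capillary waves and meniscus
optics, motion blur, leg articulation, yaw, non-Gaussian sensor noise, and
illumination drift. Passing recovery tests therefore demonstrate the
pipeline's numerics, not robustness to every artefact of real footage.

## Tracking

Background is estimated per frame by the median (the blob occupies a tiny
fraction of the frame); the detection threshold is
`median + 0.5·(max − median)`, with an additional robust noise floor of
6 × the MAD-estimated noise sigma so that a marker-free frame is reported
as lost rather than segmenting noise clusters. Components are 8-connected;
those below 4 px are discarded; the largest area wins, with ties broken by
integrated intensity and then scan order. The subpixel centroid is weighted
by background-subtracted intensity over the winning component's mask
dilated by 4 px: a hard 50% cut truncates the blob skirt asymmetrically and
biases the centroid by up to ~0.1 px at half-integer positions, while the
dilated support brings the systematic error below 0.03 px (the tests
enforce 0.05 px). Runs of up to 3 lost frames are filled by linear
interpolation and counted; longer gaps, or a lost first/last frame, are
errors.

## Differentiation and events

Velocity and acceleration come from a centred least-squares quadratic over
a 7-sample window (7 ms at 1,000 fps), projected onto the propulsion axis
(the unit vector of net displacement — the study analyses straight forward
propulsion). Near the series ends the window shrinks one-sidedly but never
below 3 samples, so polynomials of degree ≤ 2 differentiate exactly
everywhere; the fit is taken relative to the centre sample so constant
tracks yield exactly zero. The 7-point window attenuates the half-sine
acceleration peak by under 1% while suppressing centroid noise enough that
20/20 noisy trials recover the peak within 5% (the acceptance bar is
19/20).

Stroke onset is the first sample of the first run of 3 consecutive samples
exceeding `baseline mean + 3·SD`; the criterion and its parameters are
exposed in configuration because the original study states none. A
threshold-crossing detector necessarily fires one sample after a ramp
leaves zero, so onset-dependent times are tested to within 2 samples. The
arrival time is the lag from onset to the global maximum after onset. The
90° crossing for angular velocity is located by linear interpolation
between bracketing samples to avoid frame-rate-dependent bias.

The closed-form speed check (`v_max = 2AT/π` within 0.5%) is run on the
drag-free stroke, the regime in which that expression is the exact truth;
with post-stroke drag the velocity peak sits on a curvature kink that the
7-point window clips by ≈0.6%, which is a property of the smoother, not an
error of the integrator.

## Energy ledger and statistics

The energy identity `E_p = E_l − (E_c + E_v + E_d + E_b + E_a)` is exposed
as bookkeeping: no term-level formulas exist for the losses, so the module
records terms, enforces nonnegativity of losses, completes the identity
exactly, and flags deficits. The force-based loss fraction
`1 − F_MLIndir/F_MLDir` (0.484 with the published means — "about half") is
the quantitative proxy.

Summaries use the sample SD (n−1): it, and not the population SD,
reproduces the published 35.9 ± 3.5 mg from the six printed insect weights.
Pooling defaults to all-trials-pooled with a per-individual mode (average
within individual first) for sensitivity, since the original study's exact
pooling is not recoverable from its main text.

## Problem sizes

Synthetic trials are 81 frames of 256×256 px; the recovery study uses 20
seeded trials, which completes in seconds and already gives a tight
binomial check on the 19/20 acceptance bar. The direct-trace and angle
series are 601 and 121–151 samples at 1 kHz.

## Known limitations

- The hook-ratio default 0.44 is inferred from published means, not
  measured geometry; per-insect leg lengths should be supplied when known.
- The 70% apportionment and 1.2 resultant factor are treated as exact
  constants; their experimental uncertainty is not propagated.
- Tracking assumes a single marker on a dark arena; occlusions longer than
  the gap limit abort rather than re-acquire.
- The onset detector is threshold-based and will sit late on very slowly
  rising signals relative to their noise floor.
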