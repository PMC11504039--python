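# Methods

This note records the models implemented by valvekit, the design of the
synthetic data generators that stand in for instrument output, and the
numerical choices a maintainer would otherwise have to reverse-engineer.

## Hydrodynamic metrics

A pulse-duplicator recording holds ventricular pressure, aortic pressure and
transaortic flow on a uniform time grid over several cardiac cycles. The
pipeline is: ensemble-average (default 10 cycles, phase-aligned on the first
forward-flow upstroke, cycles tiled by the known period), locate the
forward-flow window, then compute the four functionality metrics.

- **Forward-flow window.** Entry threshold 2% of peak |q| with a two-sample
  bridging hysteresis, then the window edges are extended down to the zero
  crossings. The entry threshold rejects noise chatter at the crossings; the
  extension makes the window match the systolic support rather than the
  threshold's chord (on a half-sine pulse the 2% chord is ~4 samples short at
  1 kHz).
- **ΔP** is the mean of p_vent − p_ao over that window (the peak is available
  via `mode="peak"`); **Q_RMS** is the RMS of q over the window; **RF** is
  100 × retrograde volume / forward volume with volumes from trapezoidal
  integration of q split by sign over the whole cycle, so closing and leakage
  flow are lumped together.
- **EOA** uses the Gorlin-type pulse-duplicator convention
  EOA = Q_RMS/(51.6·√(ΔP/ρ)), ρ in g/cm³. With saline at 1.007 g/cm³ this
  expression closes on bench readings of the kind the package targets
  (e.g. 127.35 mL/s and 6.38 mmHg → 0.98 cm²). One known caveat: for one
  group of published readings (137.14 mL/s, 9.84 mmHg) the formula yields
  0.850 cm² where 0.84 was reported — an artifact of rounding/averaging order
  in the source numbers, not of the formula; the acceptance test asserts the
  formula's actual output.
- All quadrature is trapezoidal. Reynolds number is the plain definition
  ρvD/μ with μ converted from cP; the characteristic velocity is the
  caller's choice, deliberately, because conventions differ.

## Synthetic waveforms

No waveform equations are standard for pulse duplicators, so the generator
uses the simplest closed forms that reproduce the study-level conditions
(70 bpm, MAP 100 mmHg, 35% systolic flow):

- flow: half-sine over the systolic window scaled to the stroke volume, then
  a negative half-sine closing spike (5% of the cycle) carrying
  `closing_volume_fraction`·SV, then constant leakage for the rest of
  diastole. RF truth is therefore exactly
  100·(closing + leakage volume)/SV.
- aortic pressure: a systolic bump de-meaned **on the sample grid** and added
  to MAP, so the discrete time average equals MAP exactly before noise;
- ventricular pressure: aortic + half-sine differential (peak
  `systolic_dp_peak`) during systole, a constant 10 mmHg filling pressure in
  diastole, making the differential positive during exactly the systolic
  fraction.

The cycle period is snapped to the sample grid (857 samples at 1 kHz for
70 bpm) so cycles tile exactly. Defaults were chosen once to sit at the
healthy-valve bench magnitudes the package targets: stroke volume 34.4 mL
gives Q_RMS ≈ 127 mL/s for a half-sine over a 0.30 s systole; ΔP peak
10.02 mmHg gives a 6.38 mmHg window mean (2A/π); closing fraction 0.07 plus
2.57 mL/s leakage gives RF ≈ 10.8%. Noise is additive Gaussian per channel
(0.5 mmHg, 2 mL/s defaults), seeded; a fixed seed is bit-reproducible.

What the generator does **not** emulate: transducer drift, beat-to-beat
variability, reflected pressure waves, and valve-motion artifacts on the flow
signal. Passing recovery tests therefore demonstrates correctness of the
metric definitions and averaging, not robustness to every bench artifact.

## Nanoindentation

The contact model is P = 4E√R·δ^{3/2}/(3(1 − ν²)), evaluated in kPa/μm/μN
units (the prefactor absorbs the 10⁻³ unit factor). R is treated as an
opaque configured length (default 500 μm, the flat tip's nominal dimension)
and the expression is evaluated literally; no reinterpretation as a sphere
radius is attempted, so moduli are comparable across records fitted with the
same R. ν defaults to 0.30.

Fitting is restricted to the loading segment — unloading-based
(Oliver–Pharr) analysis is out of scope and requesting it raises — and is a
through-origin linear least squares in the regressor δ^{3/2}, which is exact
and needs no iteration. Contact-point estimation, when requested, grid
searches δ₀ (81 coarse points over 75% of the travel, then a 41-point local
refinement) jointly with the closed-form E, minimizing RSS. Segment labeling
uses displacement-rate signs, splitting the negative-rate run into unloading
vs. retraction where the rate magnitude exceeds 1.5× the initial unloading
rate (the protocols of interest unload at 2 μm/s and retract at 5 μm/s).
Phase-boundary samples can land on either side of a label change; tests
treat ≥99.5% agreement with generator labels as exact.

The synthetic record follows the protocol: 40 μm loading at 2 μm/s, mirror
unloading, 5 s retraction at 5 μm/s with zero load (detached probe), optional
flat pre-contact approach, Gaussian load noise. Elastic (hysteresis-free)
unloading is generated; viscoelasticity and adhesion are not emulated, which
is consistent with fitting only the loading ramp.

## WSS, TAWSS, OSI, Q-criterion

TAWSS = (1/T)∫‖τ_w‖dt and OSI = ½(1 − ‖∫τ_w dt‖/(T·TAWSS)) with the
numerator read as the magnitude of the time-integrated WSS **vector** (the
standard He–Ku form). Time quadrature is trapezoidal with the last sample
identified with the first (fields must span exactly one period). OSI at
zero-TAWSS nodes is defined as 0 — no shear, no oscillatory character — and
is configurable only by masking beforehand. No clamping is applied: the
bound 0 ≤ OSI ≤ 0.5 follows from ‖∫τ‖ ≤ ∫‖τ‖ and holds numerically to
round-off (boundary cases can sit within ~10⁻¹⁷ of the limit).

Surface summaries use vertex-lumped area weights (one third of incident
triangle area), which is exact for piecewise-linear fields and invariant
under subdivision. Instantaneous WSS from a near-wall profile is a one-sided
first-order difference at the wall, μ·Δu/Δn, converted at 1 Pa = 10
dynes/cm². The Q-criterion uses central-difference gradients
(`numpy.gradient`) and Q = ½(‖Ω‖²_F − ‖S‖²_F); one-sided boundary stencils
make the outermost layer first-order, so tests evaluate interior cells.

The synthetic leaflet is a sunflower-packed, Delaunay-triangulated disk
(default 400 nodes, 12 mm radius) with the radial coordinate standing in for
belly → free-edge position and shear amplitude ramping linearly from
`belly_amplitude` to `edge_amplitude` — the qualitative low-belly /
high-edge pattern of real leaflets. The temporal basis is a ±1 square wave
with forward duty f, built from integer sample indices so the discrete
trapezoid reproduces the closed forms exactly when f·K is integral:
TAWSS = A(r) and OSI = ½(1 − |2f − 1|). The oscillatory-conditioning preset
uses duty 0.5 and amplitude 3.5 dynes/cm² (midpoint of the 3–4 dynes/cm²
operating band). Real FSI fields have direction changes that are not pure
reversals and spectra richer than a square wave; the generator's purpose is
exact ground truth for the estimators, not flow realism.

## Orifice planimetry

Pipeline: select the frame nearest the flow peak (ties to the earlier
frame); CLAHE (clip limit 0.01, 8×8 tiles) then Gaussian blur (σ 1.5);
threshold-seed the orifice inside the ROI (Otsu within the central 80% by
default), keep the largest connected component, fill holes; refine with an
edge-based morphological geodesic active contour (inverse-Gaussian-gradient
edge map, 30 iterations, smoothing 1, no balloon force); area is the mask
pixel count × (mm/px)²/100 — planimetry by counting, so the
area-from-mask identity is exact and rotation/translation invariant; the
contour is derived output. All processing parameters are keyword arguments
with these defaults, tuned once on the synthetic fixtures.

Calibration from the holder rim: Canny edges → Hough circles → take the
outermost circle with accumulator ≥ 0.35 (the orifice can be near-circular
but always lies inside the holder) → refine the radius to sub-pixel as the
brightness-weighted mean radius of the bright band (> 0.5 intensity) within
±6 px; mm/px = 26/diameter. On default synthetic frames this is accurate to
~0.3%. A rim occluded by tissue fails loudly. Known limitation: if the rim
is occluded *and* a circular bright region fills most of the frame,
detection may lock onto it; frames should include the holder.

The synthetic frame renders background 25, tissue 80, rim 230 and an orifice
at tissue + contrast·(255 − tissue) gray levels, blurred (σ 1.2) and
noised (σ 4). The orifice is r(θ) = r₀(1 + 0.18·cos(n_lobes·θ)) with r₀
solved from the target area (ε = 0 for a single lobe); the pre-blur raster
mask is the ground truth and matches the target within 2% for the sizes
used. Defaults target the published group areas (3.24/2.26/2.83 cm²). Not
emulated: specular reflections, leaflet texture, motion blur, uneven
illumination — the 5%-recovery tests certify the chain on clean geometry,
not on hostile video.

## Statistics

Normality screening is the D'Agostino–Pearson K² omnibus test (the standard
"skewness–kurtosis test"); below n = 8 the result is a warning with no
p-value rather than a meaningless statistic. Group comparisons are two-sided
unpaired Student's t-tests with pooled variance, Welch available by flag;
significance tiers at 0.05/0.01/0.001/0.0001. No multiple-testing correction
is applied by default, matching per-comparison reporting conventions.
Validation tables use %Δ = 100·|v₁ − v₂|/((v₁ + v₂)/2); the absolute value
and the ×100 are part of the definition here (the symmetric percent
difference is otherwise sign-ambiguous).

## Problem sizes and determinism

Default problem sizes — 1 kHz × 10 cycles waveforms, 50 Hz indentation
records (~2 250 samples), 400-node × 200-step surface fields, 192×192 frames
— were chosen as the smallest sizes at which the discretization errors are
at least an order of magnitude below every stated tolerance; the
property-style checks use 100-seed Monte Carlo for fits and segmentation,
1 000 random shear histories for the OSI bounds, and 10 000 null replicates
for t-test calibration. Every stochastic element takes an explicit seed
(`numpy.random.default_rng`); fixed seeds give bit-identical artifacts.

## Scope

The package post-processes fields and recordings; it does not solve flow or
structure. FSI-derived quantities (velocity fields, simulated WSS) are
inputs here, and published group-level simulation values are used only to
set realistic magnitudes for the synthetic presets. Likewise out of scope:
viscoelastic or substrate-corrected indentation models, video decoding, lens
distortion, ANOVA/mixed models and equivalence testing.
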