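# Methods

This note documents the models behind `mrgfus`, the parameters that matter,
what the synthetic-data generator does and does not emulate, and the design
choices made where the design was genuinely open.

## PRF-shift thermometry

Water's proton resonance frequency falls with temperature by
α ≈ −0.01 ppm/°C, so the phase a spoiled gradient echo accrues over its echo
time TE is temperature dependent. Referencing each frame to a pre-heating
baseline through the complex-conjugate product,

    Δφ(x) = angle( m_baseline*(x) · m_frame(x) )
    ΔT(x) = Δφ(x) / (2π · α · f₀ · TE)

with Δφ in radians, f₀ the Larmor frequency in Hz and TE in seconds.
Numerically we compute α·f₀ as (ppm/°C)·(MHz) = Hz/°C, which keeps all unit
conversions in one place. The 2π factor is required for radian consistency;
formulations that state ΔT = Δφ·α·f₀·TE without it (or that multiply where
they should divide) are dimensionally inconsistent and are not implemented.
Because α < 0, a phase *decrease* at the later frame maps to positive
heating; a `flip_sign` flag covers sequences with the reversed phase
convention.

Pipeline order: conjugate-product phase differences → per-voxel temporal
unwrapping (`np.unwrap` along time; valid while inter-frame steps stay below
π, which the 55 s gated acquisition cadence guarantees for physiological
heating rates; steps at π are flagged as unrecoverable) → scaling by the
equation above → per-frame drift correction (subtract the mean apparent ΔT
in a configured unheated ROI; scanner frequency drift is spatially global at
this scale). The baseline is a single pre-heating frame by default; a
multi-frame complex average is available. Zero-magnitude voxels carry NaN
(flagged, never propagated). Frames are treated as gated snapshots acquired
between sonications — imaging during sonication is too noisy to use.

Parameters: `alpha_ppm_per_C` (default −0.01; warning outside
[−0.012, −0.008], the accepted literature range around −0.0103), `TE_ms`,
`f0_MHz`, `baseline_index`, `drift_roi`, `T_ref_C` (reference absolute
temperature added to ΔT; default 37 °C, typically the first probe-log
sample).

## B0 field mapping

Two echoes at TE₁ < TE₂ give the off-resonance directly:
ω/2π [Hz] = angle(m₁*·m₂) / (2π·(TE₂−TE₁)). The conjugate product cancels
the unknown initial phase φ₀. We fix the sign convention so that a positive
off-resonance yields a positive map (dividing by TE₂−TE₁, the order in which
phase actually accrues). The unambiguous range is ±1/(2ΔTE) — ±50 Hz at the
10/20 ms echo pair — and larger offsets alias; an optional quality-guided
spatial unwrap (scikit-image) is available but off by default, since phantom
offsets are sub-wrap. Low-SNR regions outside the object can be cropped by a
magnitude threshold of k × the background Rayleigh mean (k = 5 default),
using a caller-supplied background ROI.

Field drift between hardware conditions is reported in every candidate
normalization at once — mean |ΔHz|, mean |Δppm|, percent of the Larmor
frequency, percent of the ±300 Hz display window — because a bare printed
"drift percentage" does not pin down its reference scale (a percent of f₀
would be physically implausible at 7 T).

## Image QC

Magnitude-image background noise is Rayleigh distributed with
SD = √(2−π/2)·σ ≈ 0.655σ for per-channel Gaussian SD σ, hence the corrected
SNR = 0.655·mean(signal ROI)/SD(background ROI). SDs use the n−1
denominator. Homogeneity is (1−(Smax−Smin)/(Smax+Smin))·100%, clipped to
[0, 100]. ROIs are config-specified rectangles in pixel coordinates for
reproducible placement; the background ROI must avoid the phase-encode
zipper column, which is checked when the column is known. Per-slice profiles
aggregate over repeated acquisitions; the repeat count is a parameter, never
hard-coded. Absolute SNR values are scanner- and coil-specific, so the
package's validation checks only the ordering of the four hardware
conditions (bare / transducer installed / electronics on / sonicating),
which the synthetic condition ladder realizes as increasing channel noise
plus artifact toggles.

## Synthetic data generator

The generator forward-models a complex FLASH series on a labeled phantom:

* magnitude per tissue label from the spoiled-GRE steady state
  PD·sinθ·(1−E₁)/(1−cosθ·E₁)·exp(−TE/T2\*), E₁ = exp(−TR/T1); the default
  agar phantom uses the measured relaxation times T1 = 283 ms, T2 = 75 ms,
  with T2\* = 60 ms set slightly below T2 for static dephasing;
* phase φ₀ + 2π·(B0_offset + drift + α·f₀·ΔT)·TE — temperature acts on phase
  only (the PRF mechanism); T1/T2\* temperature dependence is deliberately
  ignored, consistent with PRF-only thermometry;
* independent N(0, σ) noise added to the real and imaginary channels — never
  a Rician sampled directly — so phase noise stays physically coupled to
  magnitude;
* artifacts last: a zipper stripe (additive high intensity along the
  phase-encode direction through image center, default width 0.8 mm,
  modeling RF feed-through without its physics) and a transducer signal void
  (magnitude → 0 in a mask; the agar-pad remedy is represented by not
  applying the mask).

Focal heating truth couples the protocol simulator to the images: a
separable Gaussian kernel with unit peak at the focus voxel whose full
widths at half maximum equal the −6 dB focal beam widths (1.5 mm lateral,
7.3 mm axial by default), times the protocol temperature rise interpolated
at the frame times. The in-tissue temperature profile is not determined by
the beam metrics alone, so this kernel is a modeling stand-in, not a claim.

What passing tests on this generator do show: the reconstruction inverts the
forward model exactly at σ = 0, and its error stays below 1 °C at realistic
noise. What they do not show: robustness to motion/respiration, coil
sensitivity structure, k-space/EPI artifacts, or fat signal — none of which
the generator emulates.

## Acoustic field model

The 11×11 matrix array (pitch 909 µm, kerf 100 µm, aperture ≈ 10×10 mm²,
960 kHz, medium sound speed 1540 m/s) is modeled as uniform square pistons
tiled with point sub-sources at ≤ λ/4 spacing (3×3 per element at 960 kHz),
kerf non-radiating. Per-element geometric delays τₙ = (max d − dₙ)/c align
all arrivals at the focus; the complex pressure is the Rayleigh–Sommerfeld
sum p(r) = Σ exp(i(k·d + ωτ))/d. This is a continuous-wave single-frequency
model — the reported metrics (peak position, −6 dB widths, relative
intensity) are CW-type beam metrics — with a water-path (no attenuation)
assumption and uncalibrated absolute pressure.

Focal widths are measured at half amplitude (−6 dB pressure) with linear
interpolation between crossings, lateral through the on-axis pressure peak
and axial along the beam axis. For the (0,0,5) mm focus the model gives a
peak at z ≈ 4.4 mm (proximal focal shift from the 1/d weighting at this
Fresnel number), lateral width ≈ 1.3 mm — close to the device's 1.5 mm
figure — and axial width ≈ 5.2 mm, shorter than the device's printed
7.3 mm. A phase-only aperture model (no 1/d) would lengthen the axial lobe
to ≈ 6.6 mm, suggesting the printed figure reflects measurement or modeling
conventions beyond the free-field Rayleigh model; we keep the physically
correct sum and report the model's honest value. Grid convergence: the
lateral width changes < 0.1% when sub-source density doubles. The 2 MHz
figure that appears in some protocol descriptions conflicts with the 960 kHz
array specification; the module defaults to 960 kHz and exposes frequency as
a parameter.

Duty cycle is burst length × PRF (≤ 50 µs × 1 kHz = 5% at the hardware
maxima); time-averaged intensity is |p|²/(2ρc)·duty-cycle, relative unless a
source-pressure calibration is supplied.

## Hyperthermia protocol simulation

A lumped single-compartment surrogate replaces a full Pennes PDE because no
tissue thermal parameters are available for the target; the protocol logic
is the implementable content:

    dT/dt = a·P − (T − T_base)/τ_cool,   P ∈ [0, 1]

Calibration solves the linear-ODE closed form for the gain a given τ_cool so
that full power raises T from 37 to 45 °C in exactly 120 s:
a = 8/(τ·(1−e^(−120/τ))). The default τ_cool = 900 s is the one choice that
makes *both* protocol statements simultaneously consistent: the 2-minute
full-power ramp and a 45 °C hold with power between 10% and 15% of maximum
(the calibrated steady-state hold fraction is 8/(a·τ) = 1−e^(−120/τ), which
equals 0.125 at τ ≈ 900 s). Physically this is a slow-perfusion subcutaneous
tumor; tissues with τ ≲ 740 s cannot hold 45 °C inside that power band, and
the simulator diagnoses this explicitly rather than failing silently.

The ramp is open-loop at P = 1 (the protocol's "maximum power for the first
2 min"), terminating when the model temperature reaches the target — at
120 s by calibration. The hold uses a two-level hysteresis controller (P =
0.10 above target, 0.15 below) updated at the 55 s imaging cadence, matching
the sonicate-then-image loop; a proportional controller clipped to the band
is available. Feedback noise (0.2 °C SD, the probe accuracy) applies to the
measured temperature at hold decisions only; putting it on ramp termination
would jitter the crossing by seconds and contradict the fixed 2-minute ramp.
Integration is explicit Euler at dt = 1 s with a guard dt ≤ τ/10. Around the
hold target the per-decision temperature drift is ±0.1 °C, so the noiseless
hold stays within ±0.5 °C and the noisy hold within ±1 °C.

Both stated hold bands (10–15%, and 10% ± 3%) are accepted as presets via
the `power_band` argument.

## Tumor growth analysis

Volume from the two caliper diameters: V = π/6·a·b² with a the longest and b
the perpendicular diameter (auto-swap with a warning if reversed). Growth
curves are percent-of-baseline per animal, averaged within group (mean ±
SEM); the inhibition ratio between groups is the ratio of those percentages
and is deliberately day-agnostic. The humane-endpoint flag fires when any
diameter reaches 15 mm. Group statistics (one-way ANOVA, Tukey HSD) are
delegated to scipy and reported as-is — the package's own contribution is
the volume/growth arithmetic, not the inferential machinery.

## Problem sizes used in validation

The validation suite runs on deliberately small instances chosen to make
every check fast while keeping the statistics meaningful: 32×32 single-slice
phantoms with 35 frames at the 55 s cadence for thermometry (50 noise seeds
for the precision bound), 2×10⁵ samples for the Rician Monte Carlo, 20 seeds
for the noisy protocol hold, and 5–10 µm-step beam profiles over a 0.5–20 mm
axial span for the acoustic metrics. Matrix size does not enter the
per-voxel thermometry error, so the small in-plane matrix loses no
generality.

## Known limitations

* Image-space only: no k-space reconstruction, gridding, or EPI artifacts.
* No referenceless or fat-suppressed thermometry; no thermal dose (CEM43).
* Free-field linear acoustics: no attenuation, nonlinearity, or cavitation;
  absolute pressure/intensity uncalibrated.
* The lumped bioheat model has no spatial heat transport; the focal
  temperature profile in images is an imposed Gaussian, not a solved field.
* Growth analysis describes curves; survival modeling is out of scope.
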