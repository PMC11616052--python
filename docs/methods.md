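# Methods

## Model

The simulator propagates a magnetization 3-vector through piecewise-constant
RF segments in the water rotating frame. A segment is (amplitude a in Hz =
γB1/2π, transmit offset f_RF in Hz, phase Φ in degrees, duration τ in s).
In the frame rotating at the transmit offset the effective field is
constant, so the propagator is one exact rotation: about the axis
(a·cosΦ, a·sinΦ, Δf) with Δf = f_tissue − f_RF, by angle
2π·√(Δf² + a²)·τ, followed by the z-rotation 2π·f_RF·τ that returns the
result to the water frame. Positive frequency precesses counter-clockwise
about +z; fat sits at −440 Hz relative to water at 3T.

**Phase convention (carrier-referenced).** Subpulse phases are offsets
relative to the transmit carrier, which runs continuously for the whole
pulse — as on a scanner, where the synthesizer does not reset between
subpulses. Under this convention the LIBOR family facts reproduce with the
phases as published: the analytic fat-null condition for a two-subpulse
pulse is ΔΦ = 180° − 360·√((f_fat−f_RF)² + a²)·τ, which for 2×500 µs at
780 Hz gives −39.7°, matching the in-vivo optimum of 320° and placing the
−45° stopband on the fat resonance. The LIBRE offset is implemented as
ΔΦ = (−360·τ·f_RF) mod 360 — the phase that tracks the water magnetization
precessing at ≈ −f_RF relative to the carrier during the first subpulse.
Its magnitude equals the usual "2π·τ·f_RF" statement; the sign belongs to
the phase-sign convention (sources quoting a positive sign use the mirrored
convention, under which the same waveform is described). For the same
reason the on-resonant binomial comparator ("1-90°-1") takes a +90°
increment here to put its null on the negative-frequency (fat) side; −90°
mirrors it to +500 Hz.

**Relaxation.** Neglected during RF (segments ≤ 1.1 ms ≪ T2) and applied
only across TR in the spoiled-GRE loop: excite → record |M_xy| → null the
transverse components (perfect spoiling) → Mz ← M0 + (Mz − M0)·exp(−TR/T1).
The recorded signal is |M_xy| immediately after excitation; no TE/T2*
decay is applied (TE only enters timing arithmetic). T1 recovery uses the
full TR (the ≤1.1 ms pulse is not subtracted; the difference is <0.1 % at
TR 5 ms / T1 2 s).

**Steady-state convergence.** With perfect spoiling the longitudinal
recurrence contracts by E1·cos(α_eff) per excitation. At TR 5 ms / T1 2 s
the standard 500 excitations converge to machine precision for α ≳ 20° but
leave ~1e−5 residual at small angles; tests that compare against the
closed-form spoiled-GRE signal sinα·(1−E1)/(1−E1·cosα) therefore run 6000
excitations. Default sweep sizes follow the published grids: off-resonance
−800…800 Hz step 5 (321 points), phase 0–360° step 5° (73), set angle
2–30° step 2° (15), 500 excitations — small enough that every simulation
here runs in well under a minute on one CPU.

## Suppression band and optimum selection

The stopband is the maximal contiguous run of grid points with
|M_xy| ≤ threshold that contains the anchor (−440 Hz); its width is the
frequency span of the run. The threshold is 10 % of a reference maximum:
by default the profile's own maximum, or — for a profile that is one row of
a sweep — the maximum observed anywhere in that sweep (pass `reference=`).
The second reading is the published criterion ("maximum observed
transverse magnetization") and is what makes the LIBOR −45° band exactly
300 Hz; the own-maximum reading gives 290 Hz.

A band whose run reaches the edge of the simulated grid is flagged
*truncated*: its true width is unknown (the measured span is a lower
bound). `optimal_phase` maximizes the anchored band width and by default
does not let truncated bands win (`exclude_truncated=True`), because
comparing an unknowable width against interior bands biases the argmax
toward the grid edge. Ties break toward the band center nearest the
anchor, then the smaller phase.

**Known sensitivity.** On the published sweep the widest untruncated band
is at 305° (360 Hz; the 370 Hz band at 300° is cut by the −800 Hz edge),
the band at 315° is exactly 300 Hz, and the deepest −440 Hz null — the
quantity the in-vivo calibration actually optimizes — is at 320°, in
agreement with the analytic null condition. The "about 315°" figure
annotation in the source study is therefore reproduced to within two 5°
grid steps but not exactly by the width-argmax rule; no defensible variant
of the width measure we examined (own- vs sweep-maximum threshold,
amplitude convention, edge handling, steady-state weighting, fat-centered
symmetric width) moves the argmax to 315° while keeping the 300 Hz band
fact intact.

## Calibration, efficiency and energy

`required_set_angle` bisects the set angle (amplitude scales linearly with
it) until the water rotation arccos(Mz) after one excitation equals the
nominal target, asserting monotonicity along the walked bracket, then
rounds to 1° (half-way ties toward the smaller angle). Water-excitation
efficiency is nominal/set; relative RF energy is ∑a²τ (proportional to the
SAR-relevant ∫B1²dt — no hardware calibration to W/kg is attempted). At a
6° nominal angle this yields set angles 12° (LIBOR), 27° (LIBRE 1 ms), 34°
(BORR), 11° (LIBRE 2.2 ms): the LIBOR values and the orderings
(efficiency LIBOR>LIBRE>BORR at 1 ms, energy BORR>LIBRE>LIBOR) match the
published comparison, while the LIBRE/BORR set angles differ from the
published console values by a few degrees — console amplitude calibration
details are not derivable from first principles.

## Trajectory

`phyllotaxis(n_segments, lines_per_segment)` generates unit spoke
directions: within a segment, line k points at polar angle
(π/2)·√(k/k_max) — sunflower-seed spacing from pole to equator — with
azimuth advancing by the golden angle (137.51°) per line; segment m is
rotated azimuthally by m·137.51°. With `si_leading` (default) line 0 of
every segment repeats the +z (superior-inferior) spoke used for
respiratory self-navigation. The construction follows the public
description of the spiral phyllotaxis pattern (counts plus golden-angle
segment rotation); the within-segment ordering is chosen for smooth
interleaves and is stated here rather than taken from any reference
implementation. `lines_per_window(window, tr) = floor(window/tr)`
reproduces the cardiac segmentations (100 ms window: TR 4.30 ms → 23
lines, TR 5.53 ms → 18).

## Phantom

The synthetic scene is deliberately minimal: a 128×128 image with a water
disc (radius 32 px; T1 2 s, T2 50 ms, 0 Hz — the simulation-study tissue),
a subcutaneous-fat ring (width 10 px; T1 350 ms, T2 80 ms, −440 Hz —
literature-typical 3T values, a package default rather than a source
value), and empty background. Per-pixel signal is the steady-state |M_xy|
of the pixel's compartment; independent zero-mean Gaussian noise (default
SD 0.001·M0 per channel, chosen to put water SNR near 40, the regime of
the in-vivo ROI analysis) is added on two quadrature channels before the
magnitude, giving Rician statistics with a pure-noise background. SNR is
ROI mean over background SD (population SD, divisor N) and CNR the
difference of two SNRs. Note the background SD of a magnitude image
underestimates the per-channel σ by the Rayleigh factor √((4−π)/2)≈0.655;
the Monte-Carlo consistency test accounts for this.

What the phantom does *not* emulate: anatomy, coil sensitivities, B0/B1
inhomogeneity, radial undersampling/streaking, motion, partial volume.
Passing phantom tests therefore demonstrate the pulse-dependent signal
model and the SNR/CNR pipeline, not in-vivo image quality; in-vivo SNR,
vessel detection and sharpness are out of scope.

## Degenerate inputs and numerical choices

Zero-amplitude segments propagate as free precession at the tissue
frequency. Zero-amplitude pulses return all-zero profiles; arccos-based
angles are clipped to [−1, 1] and are accurate only to ~1e−5 degrees near
zero rotation. Band search on an all-suppressed profile returns the full
grid (flagged truncated at both edges). A zero background SD (noise-free
phantom) surfaces as a flagged report entry rather than an exception.
Bisection uses 100 iterations on a bracket found by a 5° upward walk and
raises if the nominal rotation is unreachable below 360°.
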