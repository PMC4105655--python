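# Methods

This note records the models implemented in `sweeptract`, their
assumptions, the numerical choices made where the design was open, and
what the synthetic test conditions do and do not establish.

## Exponential sine sweep and inverse filter

The sweep is `x(t) = A sin(2π f1 L_p (e^{t/L_p} − 1))` with
`L_p = T / ln(f2/f1)`; its instantaneous frequency is
`f(t) = f1 (f2/f1)^{t/T}` and its power spectral density falls at
−3 dB/octave because the sweep dwells a time `∝ 1/f` near each frequency.
The inverse filter is the time-reversed sweep multiplied by the
exponentially decaying post-modulation `m(τ) = e^{−τ ln(f2/f1)/T}`,
normalised to unity at the sample where the reversed sweep passes `f2`.
Post-modulation (modulating the inverse filter) is used rather than
pre-modulating the excitation: the excitation keeps its −3 dB/octave
slope, which concentrates energy at low frequencies where drivers are
weakest, and the product sweep∗inverse is flat in band.

Defaults: `f1 = 20 Hz`, `f2 = 20 kHz`, `T = 10 s`, `fs = 192 kHz`,
fade anchors 50 Hz and 18 kHz, peak amplitude 1.0.  The band and duration
are implementation choices: wide enough to cover the vocal-tract range
with margin for the fades, long enough that harmonic-order responses
separate by ~1 s.

**Fades.**  Abrupt sweep edges create broadband bursts ("pre-" and
"post-ringing") in the deconvolved timeline.  The fade-in multiplies the
start by `sin²(at + b)` rising from exactly 0 at `t = 0` to 1 at the last
sample time not later than the moment the sweep crosses the fade-in
frequency (crossover times are snapped to sample boundaries); the
fade-out mirrors this, reaching exactly 0 at the final sample.  The
envelope parameters are solved in closed form from the two boundary
conditions (a quarter period of the underlying sine spans the support).

## Deconvolution and harmonic separation

The timeline is the full linear convolution of the recording with the
inverse filter (frequency-domain convolution; verified equivalent to
direct convolution to 1e-9 relative on short inputs).  The linear
response sits at lag `T`; the k-th harmonic-distortion response is
advanced by `T ln k / ln(f2/f1)`.  `t_linear` is set to the nominal lag
`(len(inverse) − 1)/fs`, with the global maximum of a 0.5 ms short-time
energy envelope as a cross-check (a warning is raised beyond 10 ms
disagreement — system group delay legitimately shifts the peak by a few
milliseconds).

**Windowing.**  Each response is isolated automatically: from the local
peak, walk upstream until a 0.5 ms moving-maximum log envelope has fallen
`threshold_db` below the peak; end the window symmetrically, or 1 ms
before the next (later) response if that comes sooner, with a warning.
The single-response default threshold is 60 dB.  The full
measure-and-subtract pipeline (`rig.measure_tract`) uses 80 dB instead:
the dB subtraction needs the slow low-frequency tails of the band-limited
impulse on both the system and the driver measurement, and at 60 dB the
lowest in-band bins of the recovered spectrum err by about 1 dB while at
80 dB they stay below 0.2 dB.  Manual window bounds can override the
policy.

**Spectra.**  The transform follows four steps in order: next power of
two at or above the window length, unit-peak amplitude normalisation,
zero-padding, FFT (real-input transform on the grid `fs·j/N`).  Repeats
are complex-averaged — phase alignment is guaranteed by freezing the
first repeat's window for the later repeats — which reduces independent
additive noise by ~1/√n.  The driver-alone spectrum is subtracted in dB
magnitude (not complex division), with near-zero bins floored at 1e-12;
phase is not propagated past this point.  `measure_tract` undoes the
unit-peak normalisation before averaging so the subtraction also cancels
the absolute driver gain and the recovered level is physical.

## Analytic tube acoustics

Speed of sound: `c = 331.3·√(1 + T/273)` m/s — at the 5 °C measurement
temperature this gives 334.32 m/s, the value that back-solves exactly
from every reference sinus-length/antiresonance pair.  Air density is
computed from the ideal-gas law at ambient pressure.

The closed-open tube resonance condition is `cot(kL) = k·δ(k)` with the
frequency-dependent end correction
`δ(k) = OECC · 0.8216 a / (1 + (0.77ka)² / (1 + 0.77ka))` (fit valid for
`ka < 1.5`; low-frequency limit `0.8216 a` for an infinite flange).  The
finite-flange scaling is the empirical
`OECC = (0.821 − 0.13(0.42 + w/a)^{−0.54}) / 0.821`, which tends to 1 for
a wide flange and reproduces the unflanged constant `0.6133 a` at
`w = 0` — an internal consistency check of the two fits.  Roots are
bracketed by a sign-change scan at step `c/40L` (twenty points per mode
interval) and polished by bisection to 0.01 Hz; simple roots interlace
the bare-length quarter-wave predictions, so the scan cannot skip one.
A warning is issued when the requested band exceeds the plane-wave limit
(bore diameter = half wavelength).

The piriform antiresonance is the quarter-wave formula
`F_n = (2n−1) c / 4L_sinus` on the sinus length alone; no end correction
is applied (the fossae terminate inside the tract), which is why the
predictor is reported to the nearest Hz but carries a few-percent model
uncertainty relative to a full 3-D computation.

## 1-D waveguide simulator

The tract is a chain of short cylindrical transmission-line elements
(exact lossy two-ports), with at least 20 elements per shortest
wavelength (halving the element size moves peaks by < 0.2 %; an
explicitly under-resolved element count is refused).  Wall absorption is
a frequency-independent factor `α` converted to a real normal impedance
through `α = 1 − |(Z_n − ρc)/(Z_n + ρc)|²` and entering the shunt
admittance per length as `P/Z_n` (P the perimeter).  The default
`α = 0.02` is a configuration choice, logged with each run, giving
formant bandwidths of a plausible magnitude; `α = 0` is the lossless
reference.  A closed side branch enters as the parallel admittance
`tanh(Γ_b L_b)/Z_{c,b}` at its attachment — pressure continuity and flow
sum — which short-circuits the line at the branch's quarter-wave
frequency.  The lip end carries a flanged-piston radiation load: exact
piston resistance `1 − J1(2ka)/ka` (the low-frequency `(ka)²/2` form
overestimates damping above `ka ≈ 1` and detunes the upper modes) plus
the OECC-scaled length correction as reactance.  The source is a unit
volume velocity at the glottis; the observable is the free-field pressure
3 cm beyond the lips.

The lossless uniform-cylinder simulation agrees with the transcendental
roots within 1 % over the plane-wave band of the benchmark cylinder
(below 5 kHz for the 30 mm bore); above that band the model's radiation
damping moves peaks by more than the 1-D approximation is good for
anyway.

**Formants, troughs, repulsion.**  Formants are magnitude peaks above a
dB prominence (default 6 dB; peaks closer than three grid steps are
merged with a warning).  Troughs are peaks of the inverted magnitude; a
branch antiresonance is far more prominent (≳ 20 dB) than inter-formant
valleys (≲ 12 dB), so a 15 dB prominence isolates it.  Repulsion analysis
pairs formants by order (nearest-frequency alignment, flagged, when the
counts differ) and reports `f_with − f_without` against the side of the
antiresonance; peak positions are quantised to the frequency grid, so
shifts are meaningful only beyond one grid step.

**Fossae-removal filter.**  The dB difference (branch-free minus
with-branch) is realised as a linear-phase FIR (`firwin2`, default 8193
taps — enough that filter-then-inverse round trips below −60 dB error)
applied with group-delay compensation, i.e. zero phase overall.

## Virtual rig and what the tests show

The rig chain is: short driver FIR → memoryless polynomial nonlinearity
(orders 2–4, the simplest model producing the temporally separated
harmonic responses the method exploits) → known tract FIR → additive
Gaussian noise at a set SNR, all driven by one seeded generator so every
fixture is bit-reproducible.  Test and acceptance runs use a 2 s sweep at
48 kHz (full 20 Hz–20 kHz band, desk-scale problem size); voices are
impulse trains at a fixed fundamental through the tract FIR.

Passing the suite shows that the *method* is internally correct:
truth-in/truth-out recovery within ±1 dB under three distinct rigs
including −20 dB second/third-order distortion, two-driver agreement
within ±1 dB, harmonic lags at their closed-form positions, ≥ 40 dB edge
suppression from the fades.  It does not certify real-hardware behaviour:
the rig has no room reflections, no transducer memory (its nonlinearity
is instantaneous), no microphone directivity, and its noise is white and
stationary.  Likewise the 1-D simulator omits transverse modes,
viscothermal boundary-layer losses and 3-D junction effects, so its
absolute formant positions for real tract geometries carry the usual
few-percent plane-wave error.

## Known limitations

* Subtraction is magnitude-only; the recovered tract spectrum has no
  usable phase.
* The piriform predictor ignores the fossae's end correction; predicted
  antiresonances are a few percent high relative to full 3-D models.
* The plane-wave simulator is trustworthy only to roughly 5 kHz for
  vocal-tract bores; results above ~10 kHz are refused territory.
* The mean antiresonance across singers depends on which tracts are
  pooled; only per-geometry frequencies and the per-singer vowel mean are
  treated as reproducible quantities.
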