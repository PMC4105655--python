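"""Seeded virtual measurement rig: driver -> nonlinearity -> tract -> mic.

Emulates the physical measurement chain (a loudspeaker driver exciting a
resonator observed by a probe microphone) so the whole sweep-measurement
pipeline can be exercised without hardware.  The driver is a short linear FIR
followed by a memoryless polynomial nonlinearity (the harmonic distortion
every real transducer exhibits); the resonator is a known FIR filter; the
microphone adds seeded Gaussian noise at a chosen SNR.  Because the tract
filter and all random draws are known, the rig provides ground truth for the
headline property of the method: the recovered, driver-subtracted tract
spectrum must match the known filter regardless of the driver used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import fftconvolve, firwin2

from .deconvolve import (TransferFunction, WindowPolicy, complex_average,
                         deconvolve_timeline, extract_ir, ir_to_spectrum,
                         subtract_reference)
from .errors import ParameterError
from .sweep import SampledSignal, SweepSpec, build_inverse_filter

__all__ = ["RigSpec", "simulate_measurement", "make_voice_fixture",
           "measure_tract", "tract_fir_from_tf"]


@dataclass(frozen=True)
class RigSpec:
    """A virtual driver/tract/microphone chain.

    ``distortion_coeffs[k]`` multiplies the k-th power of the driver output
    (index 0 is a DC offset, index 1 the linear term, which must be nonzero).
    """

    driver_ir: np.ndarray
    distortion_coeffs: np.ndarray
    tract_fir: np.ndarray
    noise_snr_db: float = 300.0
    seed: int = 0
    fs: float = 48_000.0

    def __post_init__(self) -> None:
        for name in ("driver_ir", "distortion_coeffs", "tract_fir"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if self.distortion_coeffs.size < 2 or self.distortion_coeffs[1] == 0:
            raise ParameterError("the linear distortion term must be nonzero")
        if not np.isfinite(self.noise_snr_db):
            raise ParameterError("noise SNR must be finite")


def tract_fir_from_tf(tf: TransferFunction, fs: float,
                      numtaps: int = 2049,
                      scale: float | None = None) -> np.ndarray:
    """Design a linear-phase FIR approximating a simulated tract spectrum.

    ``scale`` divides the magnitude before the design (default: its own
    maximum); pass a common value when building matched filter pairs whose
    relative level must be preserved.
    """
    nyq = fs / 2.0
    sel = (tf.freqs > 0) & (tf.freqs < nyq)
    mag = np.abs(tf.values)[sel] if not tf.is_db \
        else 10.0 ** (tf.values[sel] / 20.0)
    mag = mag / (scale if scale is not None else mag.max())
    grid = np.concatenate(([0.0], tf.freqs[sel], [nyq]))
    gains = np.concatenate(([mag[0]], mag, [0.0]))
    if numtaps % 2 == 0:
        numtaps += 1
    return firwin2(numtaps, grid / nyq, gains)


def simulate_measurement(ess: SampledSignal, rig: RigSpec,
                         include_tract: bool = True,
                         seed: int | None = None) -> SampledSignal:
    """Record the rig's response to the sweep.

    ``output = noise + tract(nonlinearity(driver * sweep))``; the tract stage
    is skipped when ``include_tract`` is false (the driver-alone reference
    measurement).  Deterministic for a given seed (default ``rig.seed``).
    Outputs that would clip beyond +-1 are rescaled with a warning.
    """
    if ess.fs != rig.fs:
        raise ParameterError(f"sweep fs={ess.fs} differs from rig fs={rig.fs}")
    x = fftconvolve(ess.samples, rig.driver_ir, mode="full")
    y = np.polynomial.polynomial.polyval(x, rig.distortion_coeffs)
    if include_tract:
        y = fftconvolve(y, rig.tract_fir, mode="full")
    rng = np.random.default_rng(rig.seed if seed is None else seed)
    rms = np.sqrt(np.mean(y ** 2))
    noise = rng.standard_normal(y.size) * rms * 10.0 ** (-rig.noise_snr_db / 20.0)
    y = y + noise
    peak = np.max(np.abs(y))
    if peak > 1.0:
        warnings.warn(f"rig output peak {peak:.2f} clipped; rescaled to +-1",
                      stacklevel=2)
        y = y / peak
    return SampledSignal(y, rig.fs)


def make_voice_fixture(f0: float, tract_fir: np.ndarray, rig: RigSpec,
                       duration: float) -> SampledSignal:
    """A synthetic sung vowel: pulse train at ``f0`` through the tract filter.

    A glottal-like impulse train (period ``round(fs / f0)`` samples, so the
    spectrum carries harmonics of ``f0``) is filtered by the tract FIR and a
    seeded noise floor is added.
    """
    if f0 <= 0:
        raise ParameterError(f"fundamental must be positive, got {f0}")
    if duration <= 0:
        raise ParameterError("duration must be positive")
    n = round(duration * rig.fs)
    if n == 0:
        raise ParameterError("duration too short for one sample")
    src = np.zeros(n)
    period = max(1, round(rig.fs / f0))
    src[::period] = 1.0
    voice = fftconvolve(src, np.asarray(tract_fir, dtype=np.float64),
                        mode="full")[:n]
    rng = np.random.default_rng(rig.seed)
    rms = np.sqrt(np.mean(voice ** 2))
    voice = voice + rng.standard_normal(n) * rms * 10.0 ** (-rig.noise_snr_db / 20.0)
    return SampledSignal(voice, rig.fs)


def measure_tract(ess: SampledSignal, spec: SweepSpec, rig: RigSpec,
                  repeats: int = 3,
                  window_policy: WindowPolicy | None = None) -> TransferFunction:
    """Run the full measurement pipeline on the virtual rig.

    Records ``repeats`` sweeps through the rig with and without the tract,
    deconvolves each with the inverse filter, windows out the linear impulse
    response, transforms it, complex-averages the repeats, and subtracts the
    driver-alone spectrum.  Returns the recovered tract transfer function in
    dB magnitude.

    The default window threshold here is -80 dB, deeper than the -60 dB
    single-response default, because the dB subtraction needs the slow
    low-frequency tails of the band-limited impulse on both measurements.
    """
    inverse = build_inverse_filter(ess, spec)

    base = window_policy or WindowPolicy(threshold_db=80.0)

    def _irs(include_tract: bool) -> list:
        out = []
        frozen = None
        for i in range(repeats):
            rec = simulate_measurement(
                ess, rig, include_tract,
                seed=rig.seed + 1000 * i + (0 if include_tract else 500))
            tl = deconvolve_timeline(rec, inverse)
            ir = extract_ir(tl, order=1, spec=spec, window=frozen or base)
            if frozen is None:
                # freeze the first repeat's window so later repeats are
                # windowed identically and stay phase-aligned for averaging
                frozen = WindowPolicy(
                    start_s=ir.start_s,
                    end_s=ir.start_s + ir.samples.size / ir.fs)
            out.append(ir)
        return out

    irs_sys = _irs(True)
    irs_drv = _irs(False)
    # pad every window to one power-of-two length so all spectra share a grid
    n_fft = 1 << (max(ir.samples.size for ir in irs_sys + irs_drv) - 1).bit_length()

    def _average(irs) -> TransferFunction:
        spectra = []
        for ir in irs:
            # undo the unit-peak normalisation so levels stay physical and
            # the driver gain cancels exactly in the subtraction
            peak = np.max(np.abs(ir.samples))
            tf = ir_to_spectrum(replace(
                ir, samples=np.pad(ir.samples, (0, n_fft - ir.samples.size))))
            spectra.append(replace(tf, values=tf.values * peak))
        return spectra[0] if len(spectra) == 1 else complex_average(spectra)

    return subtract_reference(_average(irs_sys), _average(irs_drv))
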