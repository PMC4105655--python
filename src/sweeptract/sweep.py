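"""Exponential sine sweep design: sweep, fade envelopes, inverse filter.

An exponential sine sweep (ESS) is a sinusoid whose instantaneous frequency
grows exponentially from ``f1`` to ``f2`` over a duration ``T``::

    x(t) = A sin( (2*pi*f1*T / ln r) * (r**(t/T) - 1) ),   r = f2/f1

Its instantaneous frequency is ``f(t) = f1 * r**(t/T)`` and its power spectral
density falls at -3 dB/octave, because the sweep dwells a time proportional to
``1/f`` around each frequency ``f``.  Deconvolving a recording of a system
driven by the sweep with the *inverse filter* -- the time-reversed sweep with
an exponentially decaying amplitude modulation that turns the -3 dB/octave
slope into +3 dB/octave -- yields the system's impulse-response timeline, in
which harmonic-distortion responses precede the linear response.

Abrupt sweep onset/offset injects broadband bursts ("pre-/post-ringing") into
the deconvolved timeline; sine-squared quarter-period fade envelopes anchored
at user-chosen frequencies suppress them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError

__all__ = [
    "SweepSpec", "SampledSignal", "EnvelopeParams", "generate_ess",
    "apply_fade_in", "apply_fade_out", "build_inverse_filter",
]


@dataclass(frozen=True)
class SweepSpec:
    """Parameters of an exponential sine sweep and its fade envelopes.

    Parameters
    ----------
    f1, f2 : float
        Start and end frequency of the sweep in Hz.
    T : float
        Sweep duration in seconds.
    fs : float
        Sampling rate in Hz.
    f_env_lo : float
        Frequency (Hz) at which the fade-in envelope reaches unity.
    f_env_hi : float
        Frequency (Hz) at which the fade-out envelope starts to fall.
    amplitude : float
        Peak linear amplitude of the generated sweep.
    """

    f1: float = 20.0
    f2: float = 20_000.0
    T: float = 10.0
    fs: float = 192_000.0
    f_env_lo: float = 50.0
    f_env_hi: float = 18_000.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ParameterError(f"sweep duration T must be > 0, got {self.T}")
        if not self.fs > 0:
            raise ParameterError(f"sampling rate fs must be > 0, got {self.fs}")
        if not (0 < self.f1 < self.f_env_lo < self.f_env_hi < self.f2):
            raise ParameterError(
                "require 0 < f1 < f_env_lo < f_env_hi < f2, got "
                f"f1={self.f1}, f_env_lo={self.f_env_lo}, "
                f"f_env_hi={self.f_env_hi}, f2={self.f2}"
            )
        if not self.f2 <= self.fs / 2:
            raise ParameterError(
                f"f2={self.f2} exceeds the Nyquist frequency {self.fs / 2}"
            )
        if not self.amplitude > 0:
            raise ParameterError("amplitude must be > 0")

    # -- sweep kinematics -------------------------------------------------

    @property
    def rate_ratio(self) -> float:
        """Frequency ratio ``r = f2 / f1`` swept over the duration."""
        return self.f2 / self.f1

    @property
    def log_rate(self) -> float:
        """``ln(f2/f1)``, the exponential growth constant times T."""
        return math.log(self.rate_ratio)

    @property
    def n_samples(self) -> int:
        return round(self.T * self.fs)

    def instantaneous_frequency(self, t):
        """Instantaneous frequency (Hz) at time ``t`` seconds."""
        return self.f1 * np.exp(np.asarray(t) * (self.log_rate / self.T))

    def time_of_frequency(self, f: float) -> float:
        """Time (s) at which the instantaneous frequency equals ``f``."""
        if not self.f1 <= f <= self.f2:
            raise ParameterError(
                f"frequency {f} Hz outside the sweep band "
                f"[{self.f1}, {self.f2}] Hz"
            )
        return self.T * math.log(f / self.f1) / self.log_rate

    def phase(self, t):
        """Sweep phase (rad) at time ``t`` seconds."""
        lp = self.T / self.log_rate  # time constant of the exponential
        return 2.0 * math.pi * self.f1 * lp * np.expm1(np.asarray(t) / lp)


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled real-valued waveform."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if not self.fs > 0:
            raise ParameterError(f"fs must be > 0, got {self.fs}")
        if samples.ndim != 1:
            raise ParameterError("samples must be one-dimensional")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ParameterError("samples contain non-finite values")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class EnvelopeParams:
    """Closed-form parameters of a sine-squared fade, ``env(t) = sin^2(a t + b)``.

    The envelope is applied on the support ``[t_start, t_end]`` and traverses a
    quarter period of the underlying sine, so it goes monotonically from 0 to 1
    (fade-in) or from 1 to 0 (fade-out) across the support.
    """

    a: float
    b: float
    t_start: float
    t_end: float

    def __call__(self, t):
        return np.sin(self.a * np.asarray(t) + self.b) ** 2


def generate_ess(spec: SweepSpec) -> SampledSignal:
    """Generate the exponential sine sweep defined by ``spec``.

    The returned signal has ``round(T * fs)`` samples; its instantaneous
    frequency rises exponentially from ``f1`` at t=0 towards ``f2`` at t=T and
    its averaged spectrum has a -3 dB/octave slope.
    """
    t = np.arange(spec.n_samples) / spec.fs
    x = spec.amplitude * np.sin(spec.phase(t))
    return SampledSignal(x, spec.fs)


def _fade_in_envelope(spec: SweepSpec) -> EnvelopeParams:
    t_cross = spec.time_of_frequency(spec.f_env_lo)
    # snap to the maximum sampled time <= the exact crossover time
    t1 = math.floor(t_cross * spec.fs) / spec.fs
    if t1 <= 0:
        raise ParameterError(
            f"f_env_lo={spec.f_env_lo} Hz is reached before the first sample; "
            "choose a higher fade-in frequency"
        )
    return EnvelopeParams(a=math.pi / (2.0 * t1), b=0.0, t_start=0.0, t_end=t1)


def _fade_out_envelope(spec: SweepSpec, n_samples: int) -> EnvelopeParams:
    t_cross = spec.time_of_frequency(spec.f_env_hi)
    # snap to the minimum sampled time >= the exact crossover time
    t2 = math.ceil(t_cross * spec.fs) / spec.fs
    t_end = (n_samples - 1) / spec.fs
    if t2 >= t_end:
        raise ParameterError(
            f"f_env_hi={spec.f_env_hi} Hz is reached at or after the last "
            "sample; choose a lower fade-out frequency"
        )
    a = math.pi / (2.0 * (t_end - t2))
    b = math.pi / 2.0 - a * t2
    return EnvelopeParams(a=a, b=b, t_start=t2, t_end=t_end)


def apply_fade_in(sig: SampledSignal, spec: SweepSpec) -> SampledSignal:
    """Multiply the sweep start by a sine-squared ramp ending at ``f_env_lo``.

    The ramp is 0 at t=0 and reaches 1 at the last sample time not later than
    the moment the instantaneous frequency crosses ``f_env_lo``; all later
    samples are untouched.
    """
    env = _fade_in_envelope(spec)
    i1 = round(env.t_end * spec.fs)
    out = sig.samples.copy()
    t = np.arange(i1 + 1) / spec.fs
    ramp = env(t)
    ramp[0] = 0.0  # exact zero at the sweep origin
    ramp[-1] = 1.0
    out[: i1 + 1] *= ramp
    return replace(sig, samples=out)


def apply_fade_out(sig: SampledSignal, spec: SweepSpec) -> SampledSignal:
    """Multiply the sweep end by a sine-squared fall starting at ``f_env_hi``.

    Mirror of :func:`apply_fade_in`: the envelope is 1 at the first sample time
    not earlier than the ``f_env_hi`` crossing and falls to exactly 0 at the
    last sample.
    """
    env = _fade_out_envelope(spec, len(sig))
    i2 = round(env.t_start * spec.fs)
    out = sig.samples.copy()
    t = np.arange(i2, len(sig)) / spec.fs
    fall = env(t)
    fall[0] = 1.0
    fall[-1] = 0.0  # exact zero at the sweep end
    out[i2:] *= fall
    return replace(sig, samples=out)


def build_inverse_filter(ess: SampledSignal, spec: SweepSpec) -> SampledSignal:
    """Construct the amplitude-modulated, time-reversed inverse filter.

    The time-reversed sweep retains the -3 dB/octave slope, so it is multiplied
    by the exponentially decaying post-modulation envelope
    ``m(tau) = exp(-tau * ln(f2/f1) / T)``, which equals 1 at the sample where
    the (reversed) instantaneous frequency is ``f2`` and equals ``f1/f2`` at
    the far end.  This gives the inverse filter a +3 dB/octave slope so that
    sweep * inverse approximates a band-limited impulse at lag T.
    """
    if len(ess) != spec.n_samples:
        raise ParameterError(
            f"sweep length {len(ess)} does not match spec "
            f"round(T*fs)={spec.n_samples}"
        )
    tau = np.arange(len(ess)) / spec.fs
    modulation = np.exp(-tau * (spec.log_rate / spec.T))
    inv = ess.samples[::-1] * modulation
    return replace(ess, samples=inv)


def inverse_modulation(spec: SweepSpec, tau) -> np.ndarray:
    """Post-modulation envelope of the inverse filter at reversed time ``tau``.

    ``tau = 0`` corresponds to the end of the original sweep (instantaneous
    frequency ``f2``), where the modulation is fixed to unity.
    """
    return np.exp(-np.asarray(tau) * (spec.log_rate / spec.T))
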