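"""Deconvolution of sweep recordings into impulse responses and spectra.

Convolving a recording of the swept system with the inverse filter produces an
impulse-response *timeline*: the linear impulse response (LIR) appears at the
lag equal to the sweep duration T, and the impulse response of each k-th order
harmonic distortion appears *earlier*, advanced by ``T ln k / ln(f2/f1)``.
Each response can therefore be windowed out individually; an FFT of the LIR
gives the linear transfer function free of distortion products.  Measuring the
full chain once with the resonator attached and once with the bare driver, and
subtracting the two dB-magnitude spectra, yields the transfer function of the
resonator alone, independent of the driver's own frequency response.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .errors import ParameterError
from .sweep import SampledSignal, SweepSpec

__all__ = [
    "IrTimeline", "ImpulseResponse", "TransferFunction", "WindowPolicy",
    "deconvolve_timeline", "locate_harmonics", "extract_ir", "ir_to_spectrum",
    "complex_average", "subtract_reference",
]

#: linear floor applied before taking log magnitudes
EPS_FLOOR = 1e-12


@dataclass(frozen=True)
class IrTimeline:
    """Full deconvolved timeline with harmonic responses before the LIR."""

    samples: np.ndarray
    fs: float
    t_linear: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=np.float64))
        if not 0 <= self.t_linear <= self.samples.size / self.fs:
            raise ParameterError(
                f"t_linear={self.t_linear} s outside the timeline duration"
            )


@dataclass(frozen=True)
class ImpulseResponse:
    """A single windowed impulse response; ``order`` 1 is the linear one.

    ``start_s`` records where the window begins on the source timeline, so
    that repeats can be re-windowed identically (phase-aligned) before
    complex averaging.
    """

    samples: np.ndarray
    fs: float
    order: int = 1
    start_s: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=np.float64))
        if self.order < 1:
            raise ParameterError(f"harmonic order must be >= 1, got {self.order}")
        if self.samples.size == 0:
            raise ParameterError("impulse response must be nonempty")


@dataclass(frozen=True)
class TransferFunction:
    """A sampled transfer function on a strictly increasing frequency grid.

    ``values`` is complex for spectra obtained from an FFT; after dB-magnitude
    subtraction it holds real dB values and ``is_db`` is set.
    """

    freqs: np.ndarray
    values: np.ndarray
    meta: str = ""
    is_db: bool = False

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=np.float64)
        values = np.asarray(self.values)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "values", values)
        if freqs.size != values.size:
            raise ParameterError("freqs and values must have equal length")
        if freqs.size > 1 and not np.all(np.diff(freqs) > 0):
            raise ParameterError("frequency grid must be strictly increasing")

    @property
    def magnitude_db(self) -> np.ndarray:
        if self.is_db:
            return np.asarray(self.values, dtype=np.float64)
        mag = np.abs(self.values)
        return 20.0 * np.log10(np.maximum(mag, EPS_FLOOR))

    def band(self, f_lo: float, f_hi: float) -> np.ndarray:
        """Boolean mask selecting ``f_lo <= f <= f_hi``."""
        return (self.freqs >= f_lo) & (self.freqs <= f_hi)


@dataclass(frozen=True)
class WindowPolicy:
    """How to isolate one impulse response from the timeline.

    The automatic policy walks upstream from the response peak until the
    smoothed log-magnitude envelope has fallen ``threshold_db`` below the
    peak; the window ends symmetrically about the peak, or at the start of the
    next (later) response if that comes sooner.  ``start_s``/``end_s``
    override the automatic bounds (absolute timeline times in seconds).
    """

    threshold_db: float = 60.0
    search_halfwidth_s: float = 0.010
    envelope_width_s: float = 0.0005
    start_s: float | None = None
    end_s: float | None = None


def deconvolve_timeline(recorded: SampledSignal,
                        inverse: SampledSignal) -> IrTimeline:
    """Convolve a recording with the inverse filter.

    Returns the full linear convolution as a timeline whose ``t_linear`` is
    the lag of the sweep duration, i.e. ``(len(inverse) - 1) / fs``; the
    global maximum of a short-time energy envelope is used as a cross-check
    and a warning is emitted if it falls far from that lag (e.g. because the
    recording is dominated by something other than the sweep response).
    """
    if recorded.fs != inverse.fs:
        raise ParameterError(
            f"sampling-rate mismatch: recorded fs={recorded.fs}, "
            f"inverse fs={inverse.fs}"
        )
    y = fftconvolve(recorded.samples, inverse.samples, mode="full")
    fs = recorded.fs
    t_linear = (len(inverse) - 1) / fs
    # cross-check: short-time energy must peak near the nominal linear lag
    width = max(1, round(0.0005 * fs))
    energy = np.convolve(y ** 2, np.ones(width), mode="same")
    t_peak = np.argmax(energy) / fs
    if abs(t_peak - t_linear) > 0.010:
        warnings.warn(
            f"timeline energy peaks at {t_peak:.4f} s, "
            f"{abs(t_peak - t_linear) * 1e3:.1f} ms away from the nominal "
            f"linear lag {t_linear:.4f} s", stacklevel=2)
    return IrTimeline(samples=y, fs=fs, t_linear=t_linear)


def locate_harmonics(tl: IrTimeline, spec: SweepSpec,
                     k_max: int) -> list[tuple[int, float]]:
    """Predicted lag of each harmonic-order response on the timeline.

    Order ``k`` appears advanced by ``T ln k / ln(f2/f1)`` relative to the
    linear response, i.e. ``lag(k) = t_linear - T ln k / ln(f2/f1)``.
    """
    if k_max < 1:
        raise ParameterError(f"k_max must be >= 1, got {k_max}")
    return [
        (k, tl.t_linear - spec.T * math.log(k) / spec.log_rate)
        for k in range(1, k_max + 1)
    ]


def _log_envelope(x: np.ndarray, fs: float, width_s: float) -> np.ndarray:
    """Moving-maximum magnitude envelope in dB (relative scale arbitrary)."""
    from scipy.ndimage import maximum_filter1d

    width = max(1, round(width_s * fs))
    env = maximum_filter1d(np.abs(x), size=width)
    return 20.0 * np.log10(np.maximum(env, EPS_FLOOR))


def extract_ir(tl: IrTimeline, order: int = 1,
               spec: SweepSpec | None = None,
               window: WindowPolicy | None = None) -> ImpulseResponse:
    """Isolate one impulse response from the timeline.

    For ``order > 1`` a :class:`~sweeptract.sweep.SweepSpec` is required to
    locate the harmonic lag.  The window is chosen by ``window`` (see
    :class:`WindowPolicy`); if it would collide with the adjacent response it
    is truncated with a warning.
    """
    window = window or WindowPolicy()
    fs = tl.fs
    if order == 1:
        lag = tl.t_linear
        next_lag = None
    else:
        if spec is None:
            raise ParameterError("spec is required to locate harmonic orders > 1")
        lags = dict(locate_harmonics(tl, spec, order))
        lag = lags[order]
        if lag < 0:
            raise ParameterError(
                f"order {order} lag {lag:.3f} s lies before the timeline start")
        # the next response downstream is order-1, at a later lag
        next_lag = tl.t_linear - spec.T * math.log(order - 1) / spec.log_rate \
            if order > 1 else None

    x = tl.samples
    centre = round(lag * fs)
    half = round(window.search_halfwidth_s * fs)
    lo = max(0, centre - half)
    hi = min(x.size, centre + half + 1)
    peak_idx = lo + int(np.argmax(np.abs(x[lo:hi])))

    if window.start_s is not None and window.end_s is not None:
        start = max(0, round(window.start_s * fs))
        end = min(x.size, round(window.end_s * fs))
        return ImpulseResponse(x[start:end], fs, order, start / fs)

    env = _log_envelope(x, fs, window.envelope_width_s)
    thresh = env[peak_idx] - window.threshold_db
    below = np.nonzero(env[:peak_idx] <= thresh)[0]
    start = int(below[-1]) if below.size else 0
    end = peak_idx + (peak_idx - start)  # symmetric about the peak
    if next_lag is not None:
        guard = round((next_lag - 0.001) * fs)  # 1 ms before the next response
        if guard < end:
            warnings.warn(
                f"window for order {order} truncated at the start of the "
                f"order-{order - 1} response", stacklevel=2)
            end = guard
    end = min(end, x.size)
    if end <= start:
        raise ParameterError(
            f"empty extraction window for order {order} at lag {lag:.4f} s")
    return ImpulseResponse(x[start:end], fs, order, start / fs)


def ir_to_spectrum(ir: ImpulseResponse) -> TransferFunction:
    """Transform an impulse response to its spectrum.

    Steps, in order: find the next power of two >= the length, normalise the
    amplitude to unit peak, zero-pad to that length, take the discrete Fourier
    transform.  The frequency grid is ``fs * j / N`` for the nonnegative
    frequencies of the real-input transform.
    """
    x = ir.samples
    peak = np.max(np.abs(x))
    if peak == 0:
        raise ParameterError("cannot transform an all-zero impulse response")
    n = 1 << (ir.samples.size - 1).bit_length()
    spectrum = np.fft.rfft(x / peak, n)
    freqs = ir.fs * np.arange(spectrum.size) / n
    return TransferFunction(freqs, spectrum, meta=f"order={ir.order}")


def _check_grids(tfs) -> np.ndarray:
    ref = tfs[0].freqs
    for tf in tfs[1:]:
        if tf.freqs.size != ref.size or not np.allclose(tf.freqs, ref):
            raise ParameterError("transfer functions are on different grids")
    return ref


def complex_average(spectra) -> TransferFunction:
    """Element-wise complex mean of spectra on identical grids.

    With independent additive noise across repeats, the deviation of the
    averaged spectrum from the noiseless one shrinks roughly as 1/sqrt(n).
    """
    spectra = list(spectra)
    if len(spectra) < 2:
        raise ParameterError("complex averaging needs at least two spectra")
    if any(tf.is_db for tf in spectra):
        raise ParameterError("complex averaging requires complex spectra, not dB")
    freqs = _check_grids(spectra)
    values = np.mean([tf.values for tf in spectra], axis=0)
    return TransferFunction(freqs, values, meta=f"avg_of_{len(spectra)}")


def subtract_reference(tf_system: TransferFunction,
                       tf_driver: TransferFunction,
                       floor: float = EPS_FLOOR) -> TransferFunction:
    """dB-magnitude difference: system spectrum minus driver-alone spectrum.

    Returns ``20 log10|H_sys| - 20 log10|H_drv|``, the transfer function of
    the standalone resonator; the driver's gain and linear response cancel.
    Phase is not propagated.  Near-zero driver bins are floored at ``floor``
    (linear) with a warning.
    """
    _check_grids([tf_system, tf_driver])
    if tf_system.is_db or tf_driver.is_db:
        sys_db = tf_system.magnitude_db
        drv_db = tf_driver.magnitude_db
    else:
        sys_mag = np.abs(tf_system.values)
        drv_mag = np.abs(tf_driver.values)
        n_floored = int(np.count_nonzero(drv_mag < floor))
        if n_floored:
            warnings.warn(
                f"{n_floored} driver bins below the {floor:g} floor; "
                "subtraction unreliable there", stacklevel=2)
        sys_db = 20.0 * np.log10(np.maximum(sys_mag, floor))
        drv_db = 20.0 * np.log10(np.maximum(drv_mag, floor))
    return TransferFunction(tf_system.freqs, sys_db - drv_db,
                            meta="subtracted", is_db=True)
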