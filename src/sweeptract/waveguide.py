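"""1-D plane-wave simulation of a vocal tract with piriform side branches.

The tract is described by an area function (cross-section versus distance from
the glottis) and simulated as a chain of short cylindrical transmission-line
elements.  Each element carries the exact lossy-line two-port::

    [p_in ]   [ cosh(G l)      Zc sinh(G l) ] [p_out]
    [U_in ] = [ sinh(G l)/Zc   cosh(G l)    ] [U_out]

with series impedance per length ``Z' = j w rho / S`` and shunt admittance per
length ``Y' = j w S / (rho c^2) + P / Z_n``, where ``P`` is the perimeter and
``Z_n`` the normal wall impedance.  ``Z_n`` follows from a frequency-
independent wall absorption factor ``alpha`` through the plane-wave relation
``alpha = 1 - |(Z_n - rho c) / (Z_n + rho c)|^2``.  A closed side branch (a
piriform fossa) enters as a parallel admittance ``1/Z_b`` at its attachment
point, ``Z_b = Zc_b coth(G_b L_b)``; it short-circuits the main line near its
own quarter-wave frequency, carving an antiresonance (trough) into the output
spectrum and repelling the formants away from it.  The lip end is loaded with
a flanged-piston radiation impedance and the pressure is observed by a probe
3 cm from the lips in free field; the source is a unit volume velocity at the
glottis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, find_peaks, firwin2
from scipy.special import j1

from .deconvolve import TransferFunction
from .errors import ParameterError
from .sweep import SampledSignal
from .tubes import AirModel, FLANGED_CORRECTION, oecc

__all__ = [
    "AreaFunction", "SideBranch", "WallModel", "FormantSet", "FilterSpec",
    "simulate_tf", "find_formants", "find_troughs", "repulsion_analysis",
    "fossae_removal_filter", "apply_filter",
]


@dataclass(frozen=True)
class AreaFunction:
    """Cross-sectional area (mm^2) versus distance from the glottis (mm)."""

    x: np.ndarray
    area: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=np.float64)
        area = np.asarray(self.area, dtype=np.float64)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "area", area)
        if x.size < 2 or x.size != area.size:
            raise ParameterError("area function needs >= 2 (x, area) points")
        if not np.all(np.diff(x) > 0):
            raise ParameterError("positions must be strictly increasing")
        if not np.all(area > 0):
            raise ParameterError("areas must be positive")

    @classmethod
    def uniform(cls, length_mm: float, radius_mm: float) -> "AreaFunction":
        """A uniform cylinder of the given length and radius."""
        area = math.pi * radius_mm ** 2
        return cls(np.array([0.0, length_mm]), np.array([area, area]))

    @property
    def length_mm(self) -> float:
        return float(self.x[-1] - self.x[0])


@dataclass(frozen=True)
class SideBranch:
    """A side branch attached to the main tract; closed ends model fossae."""

    attach_x: float
    length: float
    area: float
    closed_end: bool = True

    def __post_init__(self) -> None:
        if self.length <= 0 or self.area <= 0:
            raise ParameterError("branch length and area must be positive")


@dataclass(frozen=True)
class WallModel:
    """Wall absorption; ``alpha`` = 0 is a rigid (lossless) wall."""

    alpha: float = 0.02
    air: AirModel = AirModel()

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ParameterError(f"alpha must be in [0, 1], got {self.alpha}")

    @property
    def z_normal(self) -> float:
        """Normal wall impedance (Pa s/m); inf for a rigid wall."""
        if self.alpha == 0.0:
            return math.inf
        r = math.sqrt(1.0 - self.alpha)
        return self.air.rho * self.air.c * (1.0 + r) / (1.0 - r)


def _element_params(omega: np.ndarray, area_m2: float, wall: WallModel):
    """Propagation constant and characteristic impedance of one element."""
    rho, c = wall.air.rho, wall.air.c
    perimeter = 2.0 * math.sqrt(math.pi * area_m2)
    z_series = 1j * omega * rho / area_m2
    y_shunt = 1j * omega * area_m2 / (rho * c ** 2)
    if np.isfinite(wall.z_normal):
        y_shunt = y_shunt + perimeter / wall.z_normal
    gamma = np.sqrt(z_series * y_shunt)
    z_char = np.sqrt(z_series / y_shunt)
    return gamma, z_char


def _branch_admittance(omega: np.ndarray, branch: SideBranch,
                       wall: WallModel) -> np.ndarray:
    gamma, z_char = _element_params(omega, branch.area * 1e-6, wall)
    gl = gamma * branch.length * 1e-3
    if branch.closed_end:
        # Z = Zc coth(G L): zero impedance (full short) at the quarter wave
        return np.tanh(gl) / z_char
    return 1.0 / (z_char * np.tanh(gl))


def _mat_mul(m, other):
    """Multiply two (2, 2, nf) chain-matrix stacks."""
    a = m[0, 0] * other[0, 0] + m[0, 1] * other[1, 0]
    b = m[0, 0] * other[0, 1] + m[0, 1] * other[1, 1]
    c = m[1, 0] * other[0, 0] + m[1, 1] * other[1, 0]
    d = m[1, 0] * other[0, 1] + m[1, 1] * other[1, 1]
    return np.array([[a, b], [c, d]])


def simulate_tf(tract: AreaFunction, branches=(), wall: WallModel | None = None,
                f_grid: np.ndarray | None = None, *,
                flange_width_mm: float | None = None,
                probe_distance_m: float = 0.03,
                elements_per_wavelength: int = 20,
                n_elements: int | None = None) -> TransferFunction:
    """Pressure transfer function at a probe 3 cm beyond the lips.

    Propagates a unit volume-velocity glottal source through the discretised
    tract (at least ``elements_per_wavelength`` elements per shortest
    wavelength), with each side branch as a parallel admittance at its
    attachment, a flanged-piston radiation load at the lips and free-field
    spreading to the probe.  ``flange_width_mm`` scales the radiation length
    correction by the OECC; ``None`` means an infinite flange.

    If ``n_elements`` is given but smaller than the resolution rule demands,
    the call is refused and the required element count reported.
    """
    wall = wall or WallModel()
    if f_grid is None:
        f_grid = np.arange(50.0, 10_000.0, 2.0)
    f_grid = np.asarray(f_grid, dtype=np.float64)
    if f_grid.max() > 10_000.0:
        warnings.warn("plane-wave model doubtful above ~10 kHz", stacklevel=2)
    air = wall.air
    length_m = tract.length_mm * 1e-3
    lam_min = air.c / f_grid.max()
    n_required = max(math.ceil(length_m / (lam_min / elements_per_wavelength)),
                     tract.x.size - 1)
    if n_elements is None:
        n_elements = n_required
    elif n_elements < n_required:
        raise ParameterError(
            f"{n_elements} elements under-resolve the grid: need at least "
            f"{n_required} ({elements_per_wavelength} per shortest wavelength)")

    for br in branches:
        if not tract.x[0] <= br.attach_x <= tract.x[-1]:
            raise ParameterError(
                f"branch attachment {br.attach_x} mm outside the tract")

    omega = 2.0 * math.pi * f_grid
    k = omega / air.c
    edges = np.linspace(tract.x[0], tract.x[-1], n_elements + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    areas_m2 = np.interp(mids, tract.x, tract.area) * 1e-6
    elem_len_m = (edges[1] - edges[0]) * 1e-3

    # branch shunt admittance assigned to the nearest element boundary
    shunts = {}
    for br in branches:
        idx = int(np.argmin(np.abs(edges - br.attach_x)))
        y = _branch_admittance(omega, br, wall)
        shunts[idx] = shunts.get(idx, 0.0) + y

    eye = np.zeros((2, 2, f_grid.size), dtype=complex)
    eye[0, 0] = eye[1, 1] = 1.0
    m = eye
    for i in range(n_elements):
        if i in shunts:
            shunt = np.array([[np.ones_like(omega, dtype=complex),
                               np.zeros_like(omega, dtype=complex)],
                              [shunts[i],
                               np.ones_like(omega, dtype=complex)]])
            m = _mat_mul(m, shunt)
        gamma, z_char = _element_params(omega, areas_m2[i], wall)
        gl = gamma * elem_len_m
        ch, sh = np.cosh(gl), np.sinh(gl)
        elem = np.array([[ch, z_char * sh], [sh / z_char, ch]])
        m = _mat_mul(m, elem)
    if n_elements in shunts:
        shunt = np.array([[np.ones_like(omega, dtype=complex),
                           np.zeros_like(omega, dtype=complex)],
                          [shunts[n_elements],
                           np.ones_like(omega, dtype=complex)]])
        m = _mat_mul(m, shunt)

    # radiation load: flanged-piston resistance 1 - J1(2ka)/ka (which tends
    # to (ka)^2/2 at low ka and saturates at 1) plus the length correction as
    # reactance, scaled by the OECC for a finite flange
    s_lip = areas_m2[-1]
    a_lip_m = math.sqrt(s_lip / math.pi)
    ka = k * a_lip_m
    resistance = 1.0 - j1(2.0 * ka) / ka
    delta_m = FLANGED_CORRECTION * a_lip_m / (
        1.0 + (0.77 * ka) ** 2 / (1.0 + 0.77 * ka))
    if flange_width_mm is not None:
        delta_m = delta_m * oecc(a_lip_m * 1e3, flange_width_mm)
    z_rad = (air.rho * air.c / s_lip) * (resistance + 1j * k * delta_m)

    # unit glottal volume velocity: U_g = M21 p_lip + M22 U_lip, p = Zrad U
    u_lip = 1.0 / (m[1, 0] * z_rad + m[1, 1])
    r = probe_distance_m
    p_probe = 1j * omega * air.rho * u_lip * np.exp(-1j * k * r) / (2.0 * math.pi * r)
    label = "+".join(f"branch@{b.attach_x:g}mm" for b in branches) or "no-branch"
    return TransferFunction(f_grid, p_probe, meta=f"waveguide:{label}")


@dataclass(frozen=True)
class FormantSet:
    """Detected spectral peaks, in ascending frequency, labelled F1..Fn."""

    freqs_hz: np.ndarray
    magnitudes_db: np.ndarray
    labels: tuple[str, ...]

    def __len__(self) -> int:
        return self.freqs_hz.size


def find_formants(tf: TransferFunction, prominence_db: float = 6.0) -> FormantSet:
    """Local maxima of the magnitude spectrum with the given dB prominence.

    Peaks closer than three grid steps are merged (keeping the taller one)
    with a warning, since such pairs are not resolved by the grid.
    """
    mag = tf.magnitude_db
    peaks, props = find_peaks(mag, prominence=prominence_db)
    if peaks.size > 1:
        keep = []
        for p in peaks:
            if keep and p - keep[-1] < 3:
                warnings.warn(
                    "two peaks closer than the grid resolution; merged",
                    stacklevel=2)
                if mag[p] > mag[keep[-1]]:
                    keep[-1] = p
            else:
                keep.append(p)
        peaks = np.asarray(keep)
    freqs = tf.freqs[peaks]
    return FormantSet(
        freqs_hz=freqs,
        magnitudes_db=mag[peaks],
        labels=tuple(f"F{i + 1}" for i in range(freqs.size)),
    )


def find_troughs(tf: TransferFunction, prominence_db: float = 6.0) -> np.ndarray:
    """Frequencies (Hz) of magnitude minima with the given dB prominence."""
    mag = tf.magnitude_db
    dips, _ = find_peaks(-mag, prominence=prominence_db)
    return tf.freqs[dips]


def repulsion_analysis(tf_with: TransferFunction, tf_without: TransferFunction,
                       f_antires: float,
                       prominence_db: float = 6.0) -> pd.DataFrame:
    """Per-formant frequency shifts caused by adding the side branches.

    Formants of the branch-free and with-branch spectra are paired by order
    (or by nearest frequency if the counts differ, flagged in the ``aligned``
    column).  ``shift_hz = f_with - f_without``; the ``side`` column records
    whether the branch-free formant lies below or above the antiresonance.
    The side branches act as formant repellents: shifts are expected <= 0
    below ``f_antires`` and >= 0 above it.
    """
    if tf_with.freqs.size != tf_without.freqs.size or \
            not np.allclose(tf_with.freqs, tf_without.freqs):
        raise ParameterError("spectra must share one frequency grid")
    fw = find_formants(tf_with, prominence_db)
    fo = find_formants(tf_without, prominence_db)
    aligned = len(fw) == len(fo)
    if aligned:
        pairs = list(zip(fo.freqs_hz, fw.freqs_hz))
    else:
        warnings.warn(
            f"formant count mismatch ({len(fw)} with vs {len(fo)} without); "
            "aligning by nearest frequency", stacklevel=2)
        pairs = [
            (f0, fw.freqs_hz[np.argmin(np.abs(fw.freqs_hz - f0))])
            for f0 in fo.freqs_hz
        ]
    rows = []
    for i, (f0, f1) in enumerate(pairs):
        rows.append({
            "formant": f"F{i + 1}",
            "f_without_hz": f0,
            "f_with_hz": f1,
            "shift_hz": f1 - f0,
            "side": "below" if f0 < f_antires else "above",
            "aligned": aligned,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FilterSpec:
    """A zero-phase FIR realising a dB gain curve on a frequency grid."""

    taps: np.ndarray
    fs: float
    freqs: np.ndarray
    gain_db: np.ndarray

    @property
    def delay_samples(self) -> int:
        return (self.taps.size - 1) // 2

    def inverse(self, numtaps: int | None = None) -> "FilterSpec":
        """The filter with the negated gain curve."""
        return _design(self.freqs, -self.gain_db, self.fs,
                       numtaps or self.taps.size)


def _design(freqs: np.ndarray, gain_db: np.ndarray, fs: float,
            numtaps: int) -> FilterSpec:
    nyq = fs / 2.0
    if numtaps % 2 == 0:
        numtaps += 1
    grid = np.concatenate(([0.0], freqs[(freqs > 0) & (freqs < nyq)], [nyq]))
    gains = np.interp(grid, freqs, gain_db)
    taps = firwin2(numtaps, grid / nyq, 10.0 ** (gains / 20.0))
    return FilterSpec(taps=taps, fs=fs, freqs=freqs, gain_db=gain_db)


def fossae_removal_filter(tf_with: TransferFunction,
                          tf_without: TransferFunction,
                          fs: float, numtaps: int = 8193) -> FilterSpec:
    """Filter that maps a voice produced *with* fossae to one *without*.

    Its gain is the dB difference between the branch-free and the with-branch
    spectra, so applying it to audio recorded with the fossae lifts the fossa
    trough and undoes the formant shifts, mimicking the fossa-less tract.
    Requires ``fs >= 2 * max(grid)`` so the whole curve is below Nyquist.
    """
    if tf_with.freqs.size != tf_without.freqs.size or \
            not np.allclose(tf_with.freqs, tf_without.freqs):
        raise ParameterError("spectra must share one frequency grid")
    if fs < 2.0 * tf_with.freqs.max():
        raise ParameterError(
            f"audio fs={fs} Hz cannot represent the grid up to "
            f"{tf_with.freqs.max():.0f} Hz")
    gain_db = tf_without.magnitude_db - tf_with.magnitude_db
    return _design(tf_with.freqs, gain_db, fs, numtaps)


def apply_filter(audio: SampledSignal, filt: FilterSpec) -> SampledSignal:
    """Apply the zero-phase FIR to audio (group delay compensated)."""
    if audio.fs != filt.fs:
        raise ParameterError(
            f"audio fs={audio.fs} differs from filter fs={filt.fs}")
    y = fftconvolve(audio.samples, filt.taps, mode="full")
    d = filt.delay_samples
    return replace(audio, samples=y[d:d + len(audio)])
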