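"""Analytic resonance predictors for tubes and piriform-fossa side branches.

A hard-walled tube closed at one end and open at the other is a quarter-wave
resonator: its modes sit at odd multiples of ``c / (4 L')``, where ``L'`` is
the *acoustical* length — the physical length plus an end correction that
accounts for the plug of air oscillating just outside the open end.  The end
correction is known in closed form only for the two extreme flange cases
(infinite baffle: ``0.8216 a``; no flange: ``0.6133 a``); a finite flange is
handled by scaling the infinite-flange value with an empirical open-end
correction coefficient (OECC).  The exact 1-D resonance condition, with a
frequency-dependent end correction ``delta(k)``, is the transcendental
equation ``cot(k L) = k delta(k)``.

The piriform fossae — the paired cavities lateral to the laryngeal vestibule —
act as closed side branches of the vocal tract, producing an antiresonance
near their own quarter-wave frequency ``c / (4 L_sinus)``, typically in the
4–5 kHz region for adult singers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import ParameterError

__all__ = [
    "AirModel", "TubeSpec", "PiriformGeometry", "AntiresonanceSummary",
    "speed_of_sound", "quarter_wave_modes", "transcendental_modes",
    "end_correction", "oecc", "piriform_antiresonance",
    "antiresonance_summary",
    "FLANGED_CORRECTION", "UNFLANGED_CORRECTION",
]

#: low-frequency end correction / radius, infinite circular flange
FLANGED_CORRECTION = 0.8216
#: low-frequency end correction / radius, unflanged (thin-walled) pipe
UNFLANGED_CORRECTION = 0.6133


def speed_of_sound(temperature_c: float) -> float:
    """Speed of sound in air (m/s) at a temperature in Celsius.

    Uses ``c = 331.3 * sqrt(1 + T/273)``; at the 5 °C measurement condition
    this gives 334.32 m/s.
    """
    if not -50.0 < temperature_c < 100.0:
        raise ParameterError(
            f"temperature {temperature_c} °C outside the supported "
            "range (-50, 100)")
    return 331.3 * math.sqrt(1.0 + temperature_c / 273.0)


@dataclass(frozen=True)
class AirModel:
    """Air properties; ``c`` is recomputed from temperature unless overridden."""

    temperature_c: float = 5.0
    c: float | None = None
    rho: float | None = None

    def __post_init__(self) -> None:
        if self.c is None:
            object.__setattr__(self, "c", speed_of_sound(self.temperature_c))
        if not self.c > 0:
            raise ParameterError("speed of sound must be positive")
        if self.rho is None:
            # dry air at ambient pressure
            rho = 101_325.0 / (287.05 * (self.temperature_c + 273.15))
            object.__setattr__(self, "rho", rho)


@dataclass(frozen=True)
class TubeSpec:
    """Geometry of a cylindrical tube (lengths in mm, area in mm^2)."""

    L: float
    a: float
    w: float
    S: float | None = None

    def __post_init__(self) -> None:
        if min(self.L, self.a, self.w) <= 0:
            raise ParameterError("tube dimensions must all be positive")
        area = math.pi * self.a ** 2
        if self.S is None:
            object.__setattr__(self, "S", area)
        elif abs(self.S - area) > 1e-3 * area:
            raise ParameterError(
                f"cross-section S={self.S} mm^2 inconsistent with radius "
                f"a={self.a} mm (pi a^2 = {area:.3f} mm^2)")


@dataclass(frozen=True)
class PiriformGeometry:
    """Piriform-sinus dimensions: length in mm, volumes in cm^3."""

    L_sinus: float
    PV: float
    VTV: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.L_sinus <= 0:
            raise ParameterError("sinus length must be positive")
        if not 0 < self.PV < self.VTV:
            raise ParameterError(
                f"require 0 < PV < VTV, got PV={self.PV}, VTV={self.VTV}")

    @property
    def volume_ratio_pct(self) -> float:
        """Piriform volume as a percentage of the vocal-tract volume."""
        return 100.0 * self.PV / self.VTV


def quarter_wave_modes(L_eff_mm: float, air: AirModel,
                       n_modes: int = 5) -> np.ndarray:
    """Quarter-wave resonances ``f_n = (2n - 1) c / (4 L_eff)`` in Hz."""
    if L_eff_mm <= 0:
        raise ParameterError("effective length must be positive")
    n = np.arange(1, n_modes + 1)
    return (2 * n - 1) * air.c / (4.0 * L_eff_mm * 1e-3)


def end_correction(tube: TubeSpec, k: float) -> float:
    """Open-end length correction (mm) for an infinitely flanged tube.

    Fit valid for ``k a < 1.5`` (``k`` in rad/m): the correction starts at
    ``0.8216 a`` at low frequency and decreases with ``k a``.  Scale by
    :func:`oecc` to account for a finite flange.
    """
    a_m = tube.a * 1e-3
    ka = k * a_m
    if ka >= 1.5:
        warnings.warn(
            f"k a = {ka:.2f} outside the fit validity (k a < 1.5)",
            stacklevel=2)
    return FLANGED_CORRECTION * tube.a / (1.0 + (0.77 * ka) ** 2 / (1.0 + 0.77 * ka))


def oecc(radius_mm: float, flange_width_mm: float) -> float:
    """Open End Correction Coefficient for a finite flange.

    Empirical low-frequency scaling of the infinite-flange end correction:
    ``(0.821 - 0.13 (0.42 + w/a)^-0.54) / 0.821``.  It tends to 1 as the
    flange widens and recovers the unflanged value (0.6133 a) at ``w = 0``.
    """
    if radius_mm <= 0 or flange_width_mm < 0:
        raise ParameterError("radius must be > 0 and flange width >= 0")
    w_over_a = flange_width_mm / radius_mm
    return (0.821 - 0.13 * (0.42 + w_over_a) ** -0.54) / 0.821


def _resonance_condition(f: float, tube: TubeSpec, air: AirModel) -> float:
    """cos(kL) - k delta(k) sin(kL); zero at the closed-open tube resonances."""
    k = 2.0 * math.pi * f / air.c
    L_m = tube.L * 1e-3
    delta_m = oecc(tube.a, tube.w) * end_correction(tube, k) * 1e-3
    return math.cos(k * L_m) - k * delta_m * math.sin(k * L_m)


def transcendental_modes(tube: TubeSpec, air: AirModel,
                         f_max: float) -> np.ndarray:
    """All resonances below ``f_max`` of the 1-D transcendental condition.

    Solves ``cot(k L) = k delta(k)`` with the frequency-dependent flanged end
    correction scaled by the OECC, by a sign-change scan (step ``c / 40 L``)
    followed by bisection to 0.01 Hz.  The plane-wave assumption degrades when
    the tube diameter approaches half a wavelength; a warning is emitted when
    ``f_max`` exceeds that limit.
    """
    L_m = tube.L * 1e-3
    a_m = tube.a * 1e-3
    f_plane = air.c / (4.0 * a_m)  # diameter = half wavelength
    if f_max > f_plane:
        warnings.warn(
            f"plane-wave model doubtful above {f_plane:.0f} Hz for radius "
            f"{tube.a} mm", stacklevel=2)
    step = air.c / (40.0 * L_m)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # the ka-validity warning, per bracket
        grid = np.arange(step * 1e-3, f_max + step, step)
        vals = np.array([_resonance_condition(f, tube, air) for f in grid])
        roots = []
        for i in np.nonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))[0]:
            root = brentq(_resonance_condition, grid[i], grid[i + 1],
                          args=(tube, air), xtol=0.01)
            if root <= f_max:
                roots.append(root)
    return np.asarray(roots)


def piriform_antiresonance(geom: PiriformGeometry, air: AirModel,
                           n: int = 1) -> float:
    """n-th antiresonance of a piriform sinus: ``(2n - 1) c / (4 L_sinus)`` Hz."""
    if n < 1:
        raise ParameterError("mode index n must be >= 1")
    return (2 * n - 1) * air.c / (4.0 * geom.L_sinus * 1e-3)


@dataclass(frozen=True)
class AntiresonanceSummary:
    """First-antiresonance statistics over a set of piriform geometries."""

    frequencies_hz: np.ndarray
    mean_hz: float
    std_hz: float
    ratios_pct: np.ndarray
    labels: tuple[str, ...] = ()


def antiresonance_summary(geoms, air: AirModel) -> AntiresonanceSummary:
    """Mean and sample (n-1) std of first antiresonances, plus volume ratios."""
    geoms = list(geoms)
    if len(geoms) < 2:
        raise ParameterError("summary needs at least two geometries")
    freqs = np.array([piriform_antiresonance(g, air) for g in geoms])
    ratios = np.array([g.volume_ratio_pct for g in geoms])
    return AntiresonanceSummary(
        frequencies_hz=freqs,
        mean_hz=float(np.mean(freqs)),
        std_hz=float(np.std(freqs, ddof=1)),
        ratios_pct=ratios,
        labels=tuple(g.label for g in geoms),
    )
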