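"""Band-shape parameters and the frequency -> O...O distance transform.

The OD stretching frequency of an HDO molecule reports on the length of the
hydrogen bond its deuteron donates: shorter O...O distances pull the band
red.  Given a monotone empirical correlation nu(R), a band eps(nu) maps to
an oxygen-oxygen distance distribution by a change of variables,

    P(R) = eps(nu(R)) * |d nu / d R| / Z,

normalised to unit area.  Because the Jacobian is non-uniform, the mode of
P(R) is *not* in general the image of the band maximum, and the ordering of
modes between two solutes can invert relative to the ordering of their band
maxima.

The package ships a default calibration table assembled from literature
ice/clathrate-hydrate correlation points; it is an approximate, synthetic
stand-in for a laboratory calibration and should be replaced (CSV with
columns ``R_angstrom,nu_cm-1``) for quantitative work.  Every distance
distribution records which calibration produced it.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, PchipInterpolator

from .errors import DomainError, RangeError, ValidationError
from .spectra import Spectrum

__all__ = [
    "BandParameters",
    "FrequencyDistanceMap",
    "DistanceDistribution",
    "DeltaDistribution",
    "band_parameters",
    "to_distance_distribution",
    "delta_P",
    "load_frequency_distance_map",
    "default_frequency_distance_map",
]


@dataclass(frozen=True)
class BandParameters:
    """Position, gravity center, width and integrated intensity of a band."""

    nu_max: float  # cm^-1, parabolically refined argmax
    nu_grav: float  # cm^-1, intensity-weighted mean (mean H-bond energy proxy)
    fwhh: float  # cm^-1
    intensity: float  # integrated intensity

    def __post_init__(self):
        if self.fwhh <= 0:
            raise ValidationError("fwhh must be positive")

    def as_dict(self) -> dict:
        return {
            "nu_max": self.nu_max,
            "nu_grav": self.nu_grav,
            "fwhh": self.fwhh,
            "intensity": self.intensity,
        }


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through points i-1, i, i+1 (falls back to the node)."""
    if i == 0 or i == len(x) - 1:
        return float(x[i]), float(y[i])
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:  # not locally concave; keep the grid point
        return float(x1), float(y1)
    xv = -b / (2 * a)
    c = y1 - a * x1**2 - b * x1
    return float(xv), float(a * xv**2 + b * xv + c)


def band_parameters(s: Spectrum) -> BandParameters:
    """Band maximum, gravity center, fwhh and integrated intensity.

    The maximum is refined with a local parabola; the fwhh comes from linear
    interpolation of the half-height crossings.  If the band crosses the
    half-height more than twice the outermost crossings are used and a
    warning is emitted.
    """
    v = s.values
    if np.max(v) <= 0:
        raise DomainError("band_parameters requires a positive peak")
    i = int(np.argmax(v))
    nu_max, peak = _parabolic_refine(s.grid, v, i)
    area = float(np.trapezoid(v, s.grid))
    nu_grav = float(np.trapezoid(s.grid * v, s.grid)) / area
    half = peak / 2.0
    above = v >= half
    crossings = []
    for j in range(len(v) - 1):
        if above[j] != above[j + 1]:
            x0, x1 = s.grid[j], s.grid[j + 1]
            y0, y1 = v[j], v[j + 1]
            crossings.append(float(x0 + (half - y0) * (x1 - x0) / (y1 - y0)))
    if len(crossings) < 2:
        raise DomainError("band does not fall below half height on both sides of the window")
    if len(crossings) > 2:
        warnings.warn(
            f"{len(crossings)} half-height crossings found; using the outermost pair",
            stacklevel=2,
        )
    fwhh = max(crossings) - min(crossings)
    return BandParameters(nu_max=nu_max, nu_grav=nu_grav, fwhh=float(fwhh), intensity=area)


class FrequencyDistanceMap:
    """Monotone map between OD stretching frequency and O...O distance.

    Built from ``(R angstrom, nu cm^-1)`` knots with nu strictly increasing
    in R; interpolated with a monotone (PCHIP) cubic so the inverse exists
    everywhere on the knot range.
    """

    def __init__(self, knots_r: np.ndarray, knots_nu: np.ndarray, name: str = "custom"):
        r = np.asarray(knots_r, dtype=float)
        nu = np.asarray(knots_nu, dtype=float)
        if r.size != nu.size or r.size < 3:
            raise ValidationError("need >= 3 (R, nu) knots")
        order = np.argsort(r)
        r, nu = r[order], nu[order]
        if np.any(np.diff(r) <= 0) or np.any(np.diff(nu) <= 0):
            raise ValidationError("knots must be strictly monotone: nu increasing with R")
        self.knots_r = r
        self.knots_nu = nu
        self.name = name
        self._nu_of_r = PchipInterpolator(r, nu)
        self._dnu_dr = self._nu_of_r.derivative()

    @property
    def r_range(self) -> tuple[float, float]:
        return float(self.knots_r[0]), float(self.knots_r[-1])

    @property
    def nu_range(self) -> tuple[float, float]:
        return float(self.knots_nu[0]), float(self.knots_nu[-1])

    def nu(self, r: np.ndarray) -> np.ndarray:
        return self._nu_of_r(r)

    def r(self, nu: np.ndarray) -> np.ndarray:
        """Exact inverse of :meth:`nu` (monotone root-finding per query)."""
        from scipy.optimize import brentq

        nu_arr = np.atleast_1d(np.asarray(nu, dtype=float))
        lo, hi = self.nu_range
        if np.any(nu_arr < lo - 1e-9) or np.any(nu_arr > hi + 1e-9):
            raise RangeError(f"frequency outside the calibrated range [{lo}, {hi}]")
        out = np.empty_like(nu_arr)
        for i, v in enumerate(np.clip(nu_arr, lo, hi)):
            k = int(np.searchsorted(self.knots_nu, v).clip(1, self.knots_nu.size - 1))
            a, b = self.knots_r[k - 1], self.knots_r[k]
            out[i] = brentq(lambda rr: float(self._nu_of_r(rr)) - v, a, b, xtol=1e-12)
        return out if np.ndim(nu) else float(out[0])

    def jacobian(self, r: np.ndarray) -> np.ndarray:
        """d nu / d R along the curve (cm^-1 per angstrom)."""
        return self._dnu_dr(r)


def load_frequency_distance_map(path, name: str | None = None) -> FrequencyDistanceMap:
    """Load a calibration CSV with columns ``R_angstrom,nu_cm-1``."""
    df = pd.read_csv(path, comment="#")
    cols = {c.strip(): c for c in df.columns}
    try:
        r = df[cols["R_angstrom"]].to_numpy()
        nu = df[cols["nu_cm-1"]].to_numpy()
    except KeyError as exc:
        raise ValidationError(f"calibration file must have columns R_angstrom,nu_cm-1: {exc}")
    return FrequencyDistanceMap(r, nu, name=name or str(path))


def default_frequency_distance_map() -> FrequencyDistanceMap:
    """The packaged approximate nu(OD) <-> R(O...O) correlation.

    Synthetic stand-in assembled from published ice/clathrate correlation
    trends (steep near 2.55 angstrom, saturating toward the free-OD limit);
    replace with a laboratory calibration for quantitative distances.
    """
    ref = importlib.resources.files("hydr").joinpath("data/nu_roo_calibration.csv")
    with importlib.resources.as_file(ref) as path:
        return load_frequency_distance_map(path, name="hydr-default-ice-hydrate")


@dataclass(frozen=True)
class DistanceDistribution:
    """Unit-area probability density of O...O distances."""

    r_grid: np.ndarray  # angstrom, ascending
    density: np.ndarray  # 1/angstrom
    r_mode: float  # most likely O...O distance
    r_mean: float  # mean O...O distance
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.density < -1e-12):
            raise ValidationError("density must be non-negative")
        area = float(np.trapezoid(self.density, self.r_grid))
        if abs(area - 1.0) > 1e-6:
            raise ValidationError(f"density must integrate to 1, got {area}")
        lo, hi = self.r_grid[0], self.r_grid[-1]
        if not (lo <= self.r_mode <= hi and lo <= self.r_mean <= hi):
            raise ValidationError("r_mode and r_mean must lie inside the grid span")


@dataclass(frozen=True)
class DeltaDistribution:
    """Difference of two unit-area distance distributions (integrates to 0)."""

    r_grid: np.ndarray
    values: np.ndarray


def to_distance_distribution(
    s: Spectrum,
    fmap: FrequencyDistanceMap,
    delta: float = 0.0,
    r_step: float = 0.001,
) -> DistanceDistribution:
    """Transform a band into P(R) through the calibration map.

    Small negative intensities (within ``delta``) are clipped to zero before
    normalisation; the clipped intensity fraction is recorded in ``meta``.
    Wavenumbers outside the spectrum's support contribute zero density and
    set the ``clamped`` flag.
    """
    if np.min(s.values) < -delta - 1e-12:
        raise DomainError(
            f"spectrum dips to {np.min(s.values):.4g}, below the tolerance -{delta:.4g}"
        )
    r_lo, r_hi = fmap.r_range
    r_grid = np.arange(r_lo, r_hi + r_step / 2, r_step)
    nu = fmap.nu(r_grid)
    lo, hi = s.span
    inside = (nu >= lo) & (nu <= hi)
    if not np.any(inside):
        raise DomainError("band and calibration map do not overlap")
    spline = CubicSpline(s.grid, np.clip(s.values, 0.0, None))
    eps = np.zeros_like(r_grid)
    eps[inside] = np.clip(spline(nu[inside]), 0.0, None)
    raw = eps * np.abs(fmap.jacobian(r_grid))
    Z = float(np.trapezoid(raw, r_grid))
    if Z <= 0:
        raise DomainError("zero total intensity after clipping; cannot normalise")
    density = raw / Z
    i = int(np.argmax(density))
    r_mode, _ = _parabolic_refine(r_grid, density, i)
    r_mean = float(np.trapezoid(r_grid * density, r_grid))
    clipped = float(np.trapezoid(np.clip(-np.interp(nu, s.grid, s.values), 0, None) * inside, r_grid))
    return DistanceDistribution(
        r_grid=r_grid,
        density=density,
        r_mode=float(np.clip(r_mode, r_grid[0], r_grid[-1])),
        r_mean=r_mean,
        meta={
            "calibration": fmap.name,
            "clamped": bool(np.any(~inside)),
            "clipped_fraction": clipped / Z if Z > 0 else 0.0,
            "role": s.role,
        },
    )


def delta_P(p1: DistanceDistribution, p2: DistanceDistribution) -> DeltaDistribution:
    """Difference P1 - P2 on the overlap grid; integrates to 0 within 1e-6.

    Both densities are re-interpolated onto the common overlap grid and
    renormalised there before subtraction, so the zero-integral contract
    holds even when the native grids differ.
    """
    lo = max(p1.r_grid[0], p2.r_grid[0])
    hi = min(p1.r_grid[-1], p2.r_grid[-1])
    if hi <= lo:
        raise RangeError("distance grids do not overlap")
    step = min(np.min(np.diff(p1.r_grid)), np.min(np.diff(p2.r_grid)))
    grid = np.arange(lo, hi + step / 2, step)

    def _on(p):
        d = np.interp(grid, p.r_grid, p.density)
        area = np.trapezoid(d, grid)
        if area <= 0:
            raise DomainError("distribution has zero mass on the overlap")
        return d / area

    return DeltaDistribution(r_grid=grid, values=_on(p1) - _on(p2))
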