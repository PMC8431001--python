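"""Spectrum containers, file I/O, unit conversion and resampling.

Spectra are stored on a strictly ascending wavenumber grid (cm^-1).
Intensity is either absorbance (dimensionless) or molar absorptivity
(dm^3 mol^-1 cm^-1); derived spectra carry dedicated roles so downstream
stages can assert what they are handed.  All pointwise arithmetic across
spectra happens on a common analysis grid, by default 1 cm^-1 spacing
over the OD-stretch window 2200-2800 cm^-1.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.interpolate import CubicSpline

from .errors import DomainError, ParseError, RangeError, ValidationError

__all__ = [
    "Spectrum",
    "SeriesEntry",
    "SeriesManifest",
    "ROLES",
    "DEFAULT_WINDOW",
    "analysis_grid",
    "read_spectrum",
    "write_spectrum",
    "to_molar_absorptivity",
    "resample",
    "scale_to_max",
    "load_manifest",
    "write_manifest",
    "molality_from_counts",
    "WATER_MOLAR_MASS",
]

#: Mean molar mass of water in kg/mol (isotope correction ignored).
WATER_MOLAR_MASS = 0.018015

ROLES = ("absorbance", "molar_absorptivity", "affected", "theoretical", "shared_excess")

#: Default analysis window (cm^-1) covering the OD stretching band of HDO.
DEFAULT_WINDOW = (2200.0, 2800.0)


def analysis_grid(window: tuple[float, float] = DEFAULT_WINDOW, spacing: float = 1.0) -> np.ndarray:
    """Uniform wavenumber grid over *window* with the given spacing (cm^-1)."""
    lo, hi = window
    if not hi > lo:
        raise DomainError(f"empty analysis window {window}")
    n = int(round((hi - lo) / spacing)) + 1
    return lo + spacing * np.arange(n)


@dataclass(frozen=True)
class Spectrum:
    """A single spectrum on an ascending wavenumber grid.

    Parameters
    ----------
    grid
        Wavenumbers in cm^-1, strictly increasing.
    values
        Intensities; unit depends on ``role``.
    role
        One of :data:`ROLES`.
    meta
        Free-form provenance (temperature in deg C, path length in um, ...).
    """

    grid: np.ndarray
    values: np.ndarray
    role: str = "absorbance"
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)
        if grid.ndim != 1 or values.ndim != 1 or grid.size != values.size:
            raise ValidationError("grid and values must be 1-D arrays of equal length")
        if grid.size < 2:
            raise ValidationError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(grid)) or not np.all(np.isfinite(values)):
            raise ValidationError("grid and values must be finite")
        d = np.diff(grid)
        if np.any(d <= 0):
            bad = grid[1:][d <= 0][0]
            raise ValidationError(f"grid must be strictly increasing (violation near {bad} cm-1)")
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}; expected one of {ROLES}")

    def __len__(self) -> int:
        return self.grid.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.grid[0]), float(self.grid[-1])

    def with_values(self, values: np.ndarray, role: str | None = None) -> "Spectrum":
        return replace(self, values=np.asarray(values, dtype=float), role=role or self.role)

    def integral(self) -> float:
        """Trapezoid integral of the values over the grid."""
        return float(np.trapezoid(self.values, self.grid))


# ---------------------------------------------------------------------------
# File I/O

_CSV_HEADER = "wavenumber_cm-1,value"


def _read_csv(text: str, source_name: str) -> tuple[np.ndarray, np.ndarray, str]:
    xs, ys = [], []
    role = "absorbance"
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            if line.lower().lstrip("# ").startswith("role:"):
                role = line.split(":", 1)[1].strip()
            continue
        if lineno == 1 and line.replace(" ", "").lower().startswith("wavenumber"):
            # header may declare the intensity role: `wavenumber_cm-1,<role>`
            declared = line.split(",", 1)[-1].strip()
            if declared in ROLES:
                role = declared
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ParseError(f"{source_name}: line {lineno}: expected two comma-separated columns, got {raw!r}")
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as exc:
            raise ParseError(f"{source_name}: line {lineno}: {exc}") from None
    return np.array(xs), np.array(ys), role


def _read_jcamp(text: str, source_name: str) -> tuple[np.ndarray, np.ndarray, str]:
    """Minimal JCAMP-DX reader for XYDATA=(X++(Y..Y)) blocks in AFFN form."""
    ldrs: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper()
            val = val.strip()
            if key == "XYDATA":
                if "X++(Y..Y)" not in val:
                    raise ParseError(f"{source_name}: line {lineno}: only XYDATA=(X++(Y..Y)) is supported")
                in_data = True
            elif key == "END":
                in_data = False
            else:
                ldrs[key] = val
        elif in_data:
            data_lines.append((lineno, line))
    for required in ("FIRSTX", "LASTX", "NPOINTS"):
        if required not in ldrs:
            raise ParseError(f"{source_name}: missing ##{required}= record")
    try:
        firstx = float(ldrs["FIRSTX"])
        lastx = float(ldrs["LASTX"])
        npoints = int(ldrs["NPOINTS"])
        xfactor = float(ldrs.get("XFACTOR", "1"))
        yfactor = float(ldrs.get("YFACTOR", "1"))
    except ValueError as exc:
        raise ParseError(f"{source_name}: bad numeric LDR: {exc}") from None
    ys: list[float] = []
    for lineno, line in data_lines:
        fields = line.split()
        if len(fields) < 2:
            raise ParseError(f"{source_name}: line {lineno}: data line needs an X value and at least one Y")
        try:
            ys.extend(float(f) for f in fields[1:])
        except ValueError as exc:
            raise ParseError(f"{source_name}: line {lineno}: {exc}") from None
    if len(ys) != npoints:
        raise ParseError(f"{source_name}: NPOINTS={npoints} but {len(ys)} Y values found")
    if npoints < 2:
        raise ParseError(f"{source_name}: need at least 2 points")
    dx = (lastx - firstx) / (npoints - 1)
    grid = (firstx + dx * np.arange(npoints)) * xfactor
    values = np.array(ys) * yfactor
    role = ldrs.get("$ROLE", "absorbance").lower()
    if role not in ROLES:
        role = "absorbance"
    return grid, values, role


def read_spectrum(source, format: str = "csv") -> Spectrum:
    """Read a spectrum from a CSV or JCAMP-DX text resource.

    ``source`` may be a path or an open text stream.  Descending grids are
    reversed; duplicated wavenumbers raise a validation error.
    """
    if hasattr(source, "read"):
        text, name = source.read(), getattr(source, "name", "<stream>")
    else:
        name = os.fspath(source)
        with open(name, "r") as fh:
            text = fh.read()
    if format == "csv":
        grid, values, role = _read_csv(text, name)
    elif format == "jcamp":
        grid, values, role = _read_jcamp(text, name)
    else:
        raise DomainError(f"unknown format {format!r}; expected 'csv' or 'jcamp'")
    if grid.size >= 2 and grid[0] > grid[-1]:
        grid, values = grid[::-1].copy(), values[::-1].copy()
    if np.any(np.diff(grid) == 0):
        dup = grid[1:][np.diff(grid) == 0][0]
        raise ValidationError(f"{name}: duplicated wavenumber {dup}")
    return Spectrum(grid, values, role=role, meta={"source": name})


def write_spectrum(s: Spectrum, target, format: str = "csv") -> None:
    """Write a spectrum as CSV (default) or restricted JCAMP-DX."""
    own = not hasattr(target, "write")
    fh = open(target, "w") if own else target
    try:
        if format == "csv":
            fh.write(f"wavenumber_cm-1,{s.role}\n")
            for x, y in zip(s.grid, s.values):
                fh.write(f"{x:.6f},{y:.12g}\n")
        elif format == "jcamp":
            d = np.diff(s.grid)
            if not np.allclose(d, d[0], rtol=0, atol=1e-9):
                raise DomainError("JCAMP X++(Y..Y) writing requires a uniform grid")
            fh.write("##TITLE=hydr spectrum\n##JCAMP-DX=4.24\n##DATA TYPE=INFRARED SPECTRUM\n")
            fh.write("##XUNITS=1/CM\n##YUNITS=ARBITRARY UNITS\n")
            fh.write(f"##$ROLE={s.role}\n")
            fh.write(f"##FIRSTX={s.grid[0]:.9f}\n##LASTX={s.grid[-1]:.9f}\n")
            fh.write("##XFACTOR=1\n##YFACTOR=1\n")
            fh.write(f"##NPOINTS={len(s)}\n")
            fh.write("##XYDATA=(X++(Y..Y))\n")
            per_line = 5
            for i in range(0, len(s), per_line):
                ys = " ".join(f"{y:.12g}" for y in s.values[i : i + per_line])
                fh.write(f"{s.grid[i]:.9f} {ys}\n")
            fh.write("##END=\n")
        else:
            raise DomainError(f"unknown format {format!r}")
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# Conversions

def to_molar_absorptivity(s: Spectrum, path_length_um: float, c_hdo: float) -> Spectrum:
    """Beer-Lambert conversion of absorbance to molar absorptivity.

    eps = A / (c * d) with the path length converted from um to cm; the
    result is in dm^3 mol^-1 cm^-1 for ``c_hdo`` in mol dm^-3.
    """
    if s.role != "absorbance":
        raise DomainError(f"expected an absorbance spectrum, got role {s.role!r}")
    if path_length_um <= 0:
        raise DomainError(f"path length must be positive, got {path_length_um}")
    if c_hdo <= 0:
        raise DomainError(f"HDO molarity must be positive, got {c_hdo}")
    d_cm = path_length_um * 1e-4
    meta = dict(s.meta)
    meta.update(path_length_um=path_length_um, hdo_molarity=c_hdo)
    return Spectrum(s.grid, s.values / (c_hdo * d_cm), role="molar_absorptivity", meta=meta)


def resample(s: Spectrum, grid: Sequence[float]) -> Spectrum:
    """Cubic interpolation of a spectrum onto *grid* (no extrapolation)."""
    grid = np.asarray(grid, dtype=float)
    lo, hi = s.span
    if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
        raise RangeError(
            f"target grid [{grid.min()}, {grid.max()}] extends beyond source span [{lo}, {hi}]"
        )
    spline = CubicSpline(s.grid, s.values)
    return Spectrum(grid, spline(np.clip(grid, lo, hi)), role=s.role, meta=dict(s.meta))


def scale_to_max(s: Spectrum) -> Spectrum:
    """Scale values so the maximum equals 1 (for visual band-shape comparison)."""
    peak = float(np.max(s.values))
    if peak <= 0:
        raise DomainError("cannot scale a spectrum with non-positive maximum")
    return s.with_values(s.values / peak)


def denoise(s: Spectrum, width: float = 25.0, order: int = 2) -> Spectrum:
    """Savitzky-Golay smoothing over ~width cm^-1 (quadratic-preserving).

    Bands in the OD-stretch region are >= 100 cm^-1 wide, so a 25 cm^-1
    quadratic filter suppresses white noise by ~3.5x with negligible shape
    distortion.  Smoothing is linear: applying the same filter to every
    spectrum entering a linear decomposition leaves the mixture weights
    unchanged.
    """
    from scipy.signal import savgol_filter

    spacing = float(np.median(np.diff(s.grid)))
    win = max(int(round(width / spacing)) | 1, order + 2)
    if win >= len(s):
        win = (len(s) - 1) | 1
    return s.with_values(savgol_filter(s.values, win, order))


def savgol_noise_gain(width: float = 25.0, spacing: float = 1.0, order: int = 2) -> float:
    """White-noise standard-deviation gain of :func:`denoise` (l2 norm of coefficients)."""
    from scipy.signal import savgol_coeffs

    win = max(int(round(width / spacing)) | 1, order + 2)
    return float(np.sqrt(np.sum(savgol_coeffs(win, order) ** 2)))


def molality_from_counts(n_solute: float, n_water: float, M: float = WATER_MOLAR_MASS) -> float:
    """Molality (mol solute per kg water) implied by molecule counts.

    Useful to translate simulation-box compositions (e.g. a few osmolyte
    molecules among a few thousand waters) into the concentration scale of
    the spectroscopic series.
    """
    if n_solute < 0 or n_water <= 0:
        raise DomainError("counts must be positive")
    return n_solute / (n_water * M)


# ---------------------------------------------------------------------------
# Series manifests

@dataclass(frozen=True)
class SeriesEntry:
    """One solution in a concentration series."""

    source: str
    molality: float  # mol solute per kg water
    composition: Mapping[str, float]  # mole fractions among solutes only
    hdo_molarity: float  # mol dm^-3
    spectrum: Spectrum | None = None


@dataclass(frozen=True)
class SeriesManifest:
    """A concentration series: bulk reference plus >= 3 nonzero molalities.

    Mole fractions in each entry's composition refer to the solutes only;
    the molar contribution of water is ignored.
    """

    entries: tuple[SeriesEntry, ...]
    bulk_source: str
    bulk_hdo_molarity: float
    path_length_um: float
    temperature_C: float
    bulk_spectrum: Spectrum | None = None

    def __post_init__(self):
        object.__setattr__(self, "entries", tuple(self.entries))
        if self.path_length_um <= 0:
            raise ValidationError("path length must be positive")
        molalities = [e.molality for e in self.entries]
        if any(m < 0 for m in molalities):
            raise ValidationError("molalities must be >= 0")
        nonzero = {round(m, 12) for m in molalities if m > 0}
        if len(nonzero) < 3:
            raise ValidationError("need at least 3 distinct nonzero molalities plus a bulk entry")
        for e in self.entries:
            total = sum(e.composition.values())
            if abs(total - 1.0) > 1e-6:
                raise ValidationError(
                    f"solute mole fractions must sum to 1, got {total} for {e.source}"
                )

    @property
    def molalities(self) -> np.ndarray:
        return np.array([e.molality for e in self.entries])


def load_manifest(path, load_spectra: bool = True) -> SeriesManifest:
    """Load a YAML series manifest; spectrum paths resolve relative to it.

    Expected keys: ``bulk``, ``entries`` (each with ``file``,
    ``molality_mol_per_kg``, ``composition``), ``path_length_um``,
    ``temperature_C``, ``hdo_molarity`` (list parallel to entries),
    optional ``bulk_hdo_molarity``.
    """
    path = os.fspath(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    base = os.path.dirname(os.path.abspath(path))

    def _resolve(p):
        return p if os.path.isabs(p) else os.path.join(base, p)

    raw_entries = doc["entries"]
    hdo = doc["hdo_molarity"]
    if len(hdo) != len(raw_entries):
        raise ValidationError("hdo_molarity must have one value per entry")
    entries = []
    for rec, c in zip(raw_entries, hdo):
        spec = read_spectrum(_resolve(rec["file"])) if load_spectra else None
        entries.append(
            SeriesEntry(
                source=rec["file"],
                molality=float(rec["molality_mol_per_kg"]),
                composition=dict(rec["composition"]),
                hdo_molarity=float(c),
                spectrum=spec,
            )
        )
    bulk = read_spectrum(_resolve(doc["bulk"])) if load_spectra else None
    return SeriesManifest(
        entries=tuple(entries),
        bulk_source=doc["bulk"],
        bulk_hdo_molarity=float(doc.get("bulk_hdo_molarity", hdo[0])),
        path_length_um=float(doc["path_length_um"]),
        temperature_C=float(doc.get("temperature_C", 25.0)),
        bulk_spectrum=bulk,
    )


def write_manifest(manifest: SeriesManifest, path) -> None:
    doc = {
        "bulk": manifest.bulk_source,
        "bulk_hdo_molarity": manifest.bulk_hdo_molarity,
        "path_length_um": manifest.path_length_um,
        "temperature_C": manifest.temperature_C,
        "hdo_molarity": [e.hdo_molarity for e in manifest.entries],
        "entries": [
            {
                "file": e.source,
                "molality_mol_per_kg": e.molality,
                "composition": dict(e.composition),
            }
            for e in manifest.entries
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def series_molar_absorptivity(
    manifest: SeriesManifest, grid: np.ndarray | None = None
) -> tuple[Spectrum, list[tuple[float, Spectrum]]]:
    """Convert a loaded series to molar absorptivity on a common grid.

    Returns the bulk spectrum and ``(molality, spectrum)`` pairs, all
    resampled to *grid* (default: the package analysis grid clipped to the
    data span).
    """
    if manifest.bulk_spectrum is None:
        raise ValidationError("manifest was loaded without spectra")
    if grid is None:
        grid = analysis_grid()
        lo = max(grid[0], manifest.bulk_spectrum.span[0])
        hi = min(grid[-1], manifest.bulk_spectrum.span[1])
        grid = grid[(grid >= lo) & (grid <= hi)]
    bulk = to_molar_absorptivity(
        manifest.bulk_spectrum, manifest.path_length_um, manifest.bulk_hdo_molarity
    )
    bulk = resample(bulk, grid)
    series = []
    for e in manifest.entries:
        eps = to_molar_absorptivity(e.spectrum, manifest.path_length_um, e.hdo_molarity)
        series.append((e.molality, resample(eps, grid)))
    return bulk, series
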