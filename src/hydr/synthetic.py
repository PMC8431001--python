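"""Ground-truthed synthetic inputs for every pipeline stage.

Spectra series are built directly from the two-state mixture model, so the
extraction stage can be checked against exact generator truth; ternary
series additionally embed shared/excess water components with known
weights.  Toy trajectories realise known radial, orientational and
hydrogen-bond structure (uniform gas, fixed-radius shells, water lattices
with an exact bond count, oriented rigid probes).

Band shapes are pseudo-Voigt sums.  The default Gaussian fraction is 1:
identification of the affected-water number by the non-negativity criterion
requires the affected band to decay at least as fast as the bulk band in
the far wings, which Lorentzian tails violate.  Mimic asymmetry with
multi-component sums rather than Lorentzian character when the extraction
stage is the consumer.

Every generator is driven by a single explicit seed and records it in the
truth object; rerunning with the same seed reproduces the output exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DomainError, GenerationError
from .spectra import (
    Spectrum,
    SeriesEntry,
    SeriesManifest,
    WATER_MOLAR_MASS,
    analysis_grid,
    write_manifest,
    write_spectrum,
)
from .trajectory import Trajectory

__all__ = [
    "PseudoVoigtBand",
    "SpectralTruth",
    "TrajectoryTruth",
    "BinarySeries",
    "TernarySeries",
    "make_binary_series",
    "make_ternary_series",
    "n_sh_for_share",
    "make_trajectory",
    "write_series",
    "DEFAULT_MOLALITIES",
    "default_bulk_truth",
    "default_peptide_truth",
    "default_osmolyte_truth",
]

#: Default concentration ladder (mol solute per kg water).
DEFAULT_MOLALITIES = (0.2, 0.4, 0.6, 0.8, 1.0)

#: Default measurement geometry: CaF2 cell path length (um) and HDO molarity.
DEFAULT_PATH_LENGTH_UM = 28.4
DEFAULT_HDO_MOLARITY = 4.25


@dataclass(frozen=True)
class PseudoVoigtBand:
    """Pseudo-Voigt profile: eta * Gaussian + (1 - eta) * Lorentzian.

    Both components share the center, amplitude and full width at half
    height; ``eta`` is the Gaussian fraction.
    """

    center: float  # cm^-1
    fwhh: float  # cm^-1
    amplitude: float
    eta: float = 1.0

    def __post_init__(self):
        if self.fwhh <= 0 or self.amplitude <= 0:
            raise DomainError("band fwhh and amplitude must be positive")
        if not (0.0 <= self.eta <= 1.0):
            raise DomainError("Gaussian fraction eta must be in [0, 1]")

    def __call__(self, nu: np.ndarray) -> np.ndarray:
        u = (np.asarray(nu, dtype=float) - self.center) / self.fwhh
        gauss = np.exp(-4.0 * np.log(2.0) * u**2)
        lorentz = 1.0 / (1.0 + 4.0 * u**2)
        return self.amplitude * (self.eta * gauss + (1.0 - self.eta) * lorentz)


def _band_sum(bands: Sequence[PseudoVoigtBand], nu: np.ndarray) -> np.ndarray:
    out = np.zeros_like(np.asarray(nu, dtype=float))
    for b in bands:
        out = out + b(nu)
    return out


@dataclass(frozen=True)
class SpectralTruth:
    """Generator truth for one solute's concentration series.

    The bulk band emulates the HDO OD-stretch of pure water (peak molar
    absorptivity ~58 at 2509 cm^-1, fwhh 162 cm^-1); the affected band is a
    red-shifted two-component profile typical of a structure-enhancing
    solute.  ``noise_sigma`` is the relative (multiplicative) noise level.
    """

    bulk_bands: tuple[PseudoVoigtBand, ...]
    affected_bands: tuple[PseudoVoigtBand, ...]
    N_true: float = 6.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.N_true <= 0:
            raise DomainError("N_true must be positive")
        if self.noise_sigma < 0:
            raise DomainError("noise_sigma must be >= 0")

    def eps_b(self, grid: np.ndarray) -> Spectrum:
        return Spectrum(grid, _band_sum(self.bulk_bands, grid), role="molar_absorptivity")

    def eps_a(self, grid: np.ndarray) -> Spectrum:
        return Spectrum(grid, _band_sum(self.affected_bands, grid), role="affected")


def default_bulk_truth() -> tuple[PseudoVoigtBand, ...]:
    """Bulk HDO OD band: single Gaussian, integrated intensity ~10000."""
    return (PseudoVoigtBand(center=2509.0, fwhh=162.0, amplitude=58.3, eta=1.0),)


def default_peptide_truth(N_true: float = 6.0, noise_sigma: float = 0.0, seed: int = 0) -> SpectralTruth:
    """Peptide-like truth: red-shifted asymmetric affected band, N ~ 6."""
    return SpectralTruth(
        bulk_bands=default_bulk_truth(),
        affected_bands=(
            PseudoVoigtBand(center=2430.0, fwhh=150.0, amplitude=40.0, eta=1.0),
            PseudoVoigtBand(center=2520.0, fwhh=120.0, amplitude=22.0, eta=1.0),
        ),
        N_true=N_true,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def default_osmolyte_truth(N_true: float = 4.0, noise_sigma: float = 0.0, seed: int = 1) -> SpectralTruth:
    """Osmolyte-like truth: band closer to bulk, smaller hydration number."""
    return SpectralTruth(
        bulk_bands=default_bulk_truth(),
        affected_bands=(
            PseudoVoigtBand(center=2480.0, fwhh=140.0, amplitude=35.0, eta=1.0),
            PseudoVoigtBand(center=2555.0, fwhh=100.0, amplitude=14.0, eta=1.0),
        ),
        N_true=N_true,
        noise_sigma=noise_sigma,
        seed=seed,
    )


@dataclass(frozen=True)
class BinarySeries:
    """A synthetic binary concentration series plus its generator truth."""

    bulk: Spectrum
    series: tuple[tuple[float, Spectrum], ...]
    truth: dict


@dataclass(frozen=True)
class TernarySeries:
    bulk: Spectrum
    series: tuple[tuple[float, Spectrum], ...]
    truth: dict


def _apply_noise(values: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return values
    return values * (1.0 + sigma * rng.standard_normal(values.shape))


def make_binary_series(
    truth: SpectralTruth,
    molalities: Sequence[float] = DEFAULT_MOLALITIES,
    grid: np.ndarray | None = None,
    M: float = WATER_MOLAR_MASS,
) -> BinarySeries:
    """Series obeying eps(nu; m) = (1 - N M m) eps_b + N M m eps_a, plus noise."""
    if grid is None:
        grid = analysis_grid()
    mmax = max(molalities)
    if truth.N_true * M * mmax >= 1:
        raise DomainError(
            f"affected fraction N*M*m = {truth.N_true * M * mmax:.3f} >= 1 at m={mmax}"
        )
    rng = np.random.default_rng(truth.seed)
    eps_b = truth.eps_b(grid)
    eps_a = truth.eps_a(grid)
    bulk = eps_b.with_values(_apply_noise(eps_b.values, truth.noise_sigma, rng))
    series = []
    for m in molalities:
        frac = truth.N_true * M * m
        clean = (1 - frac) * eps_b.values + frac * eps_a.values
        noisy = _apply_noise(clean, truth.noise_sigma, rng)
        series.append((float(m), Spectrum(grid, noisy, role="molar_absorptivity")))
    record = {
        "kind": "binary",
        "N_true": truth.N_true,
        "M": M,
        "noise_sigma": truth.noise_sigma,
        "seed": truth.seed,
        "eps_a": eps_a,
        "eps_b": eps_b,
        "molalities": list(map(float, molalities)),
    }
    return BinarySeries(bulk=bulk, series=tuple(series), truth=record)


def n_sh_for_share(
    truth_p: SpectralTruth,
    truth_o: SpectralTruth,
    x: float,
    shared_bands: Sequence[PseudoVoigtBand],
    share_pct: float,
    w_p: float = 1.0,
    w_o: float = 1.0,
    grid: np.ndarray | None = None,
) -> float:
    """Shared-water count giving a target integrated-intensity share (%)."""
    if not (0 < share_pct < 100):
        raise DomainError("share_pct must be in (0, 100)")
    if grid is None:
        grid = analysis_grid()
    i_p = float(np.trapezoid(truth_p.eps_a(grid).values, grid))
    i_o = float(np.trapezoid(truth_o.eps_a(grid).values, grid))
    i_sh = float(np.trapezoid(_band_sum(shared_bands, grid), grid))
    retained = w_p * (1 - x) * truth_p.N_true * i_p + w_o * x * truth_o.N_true * i_o
    return share_pct / (100.0 - share_pct) * retained / i_sh


def make_ternary_series(
    truth_p: SpectralTruth,
    truth_o: SpectralTruth,
    x: float,
    shared_bands: Sequence[PseudoVoigtBand] = (),
    N_sh: float = 0.0,
    w_p: float = 1.0,
    w_o: float = 1.0,
    molalities: Sequence[float] = DEFAULT_MOLALITIES,
    grid: np.ndarray | None = None,
    noise_sigma: float | None = None,
    seed: int | None = None,
    M: float = WATER_MOLAR_MASS,
) -> TernarySeries:
    """Mixture series with implied affected spectrum built from known parts.

    The implied experimental affected spectrum is

        eps_exp = [w_p (1-x) N_p eps_p + w_o x N_o eps_o + N_sh eps_sh] / N_exp

    with N_exp = w_p (1-x) N_p + w_o x N_o + N_sh, and the series follows the
    two-state mixture model at each total solute-pair molality.  Bulk bands
    of the two component truths must agree.
    """
    if not (0.0 <= x <= 1.0):
        raise DomainError("x must be in [0, 1]")
    for w, name in ((w_p, "w_p"), (w_o, "w_o")):
        if not (0.0 <= w <= 1.0):
            raise DomainError(f"{name} must be in [0, 1]")
    if N_sh < 0:
        raise DomainError("N_sh must be >= 0")
    if N_sh > 0 and not shared_bands:
        raise DomainError("N_sh > 0 requires shared_bands")
    if truth_p.bulk_bands != truth_o.bulk_bands:
        raise DomainError("component truths must share the same bulk band")
    if grid is None:
        grid = analysis_grid()
    if noise_sigma is None:
        noise_sigma = max(truth_p.noise_sigma, truth_o.noise_sigma)
    if seed is None:
        seed = truth_p.seed
    eps_p = truth_p.eps_a(grid).values
    eps_o = truth_o.eps_a(grid).values
    eps_sh = _band_sum(shared_bands, grid) if shared_bands else np.zeros_like(grid)
    a = w_p * (1 - x) * truth_p.N_true
    b = w_o * x * truth_o.N_true
    n_exp = a + b + N_sh
    if n_exp <= 0:
        raise DomainError("the implied affected number is not positive")
    exp_values = (a * eps_p + b * eps_o + N_sh * eps_sh) / n_exp
    eps_exp = Spectrum(grid, exp_values, role="affected")
    mmax = max(molalities)
    if n_exp * M * mmax >= 1:
        raise DomainError(f"affected fraction {n_exp * M * mmax:.3f} >= 1 at m={mmax}")
    rng = np.random.default_rng(seed)
    eps_b = truth_p.eps_b(grid)
    bulk = eps_b.with_values(_apply_noise(eps_b.values, noise_sigma, rng))
    series = []
    for m in molalities:
        frac = n_exp * M * m
        clean = (1 - frac) * eps_b.values + frac * exp_values
        series.append((float(m), Spectrum(grid, _apply_noise(clean, noise_sigma, rng), role="molar_absorptivity")))
    total = float(np.trapezoid(n_exp * exp_values, grid))
    share_true = 100.0 * float(np.trapezoid(N_sh * eps_sh, grid)) / total if total > 0 else 0.0
    record = {
        "kind": "ternary",
        "x": x,
        "w_p": w_p,
        "w_o": w_o,
        "N_p": truth_p.N_true,
        "N_o": truth_o.N_true,
        "N_sh": N_sh,
        "N_exp": float(n_exp),
        "share_pct_true": share_true,
        "noise_sigma": noise_sigma,
        "seed": seed,
        "M": M,
        "eps_exp": eps_exp,
        "eps_p": truth_p.eps_a(grid),
        "eps_o": truth_o.eps_a(grid),
        "eps_sh": Spectrum(grid, eps_sh, role="shared_excess") if shared_bands else None,
        "eps_b": eps_b,
        "molalities": list(map(float, molalities)),
    }
    return TernarySeries(bulk=bulk, series=tuple(series), truth=record)


def write_series(
    series: BinarySeries | TernarySeries,
    outdir,
    solute_name: str = "solute",
    composition: dict | None = None,
    path_length_um: float = DEFAULT_PATH_LENGTH_UM,
    hdo_molarity: float = DEFAULT_HDO_MOLARITY,
) -> str:
    """Write a synthetic series as absorbance CSVs + YAML manifest + truth JSON.

    Molar absorptivity is converted back to absorbance with the declared
    path length and HDO molarity so the files look like instrument output.
    Returns the manifest path.
    """
    os.makedirs(outdir, exist_ok=True)
    d_cm = path_length_um * 1e-4
    comp = composition or {solute_name: 1.0}

    def _absorbance(s: Spectrum) -> Spectrum:
        return Spectrum(s.grid, s.values * hdo_molarity * d_cm, role="absorbance")

    bulk_file = "bulk.csv"
    write_spectrum(_absorbance(series.bulk), os.path.join(outdir, bulk_file))
    entries = []
    for i, (m, s) in enumerate(series.series):
        fname = f"{solute_name}_{i:02d}.csv"
        write_spectrum(_absorbance(s), os.path.join(outdir, fname))
        entries.append(
            SeriesEntry(source=fname, molality=m, composition=comp, hdo_molarity=hdo_molarity)
        )
    manifest = SeriesManifest(
        entries=tuple(entries),
        bulk_source=bulk_file,
        bulk_hdo_molarity=hdo_molarity,
        path_length_um=path_length_um,
        temperature_C=25.0,
    )
    manifest_path = os.path.join(outdir, "manifest.yaml")
    write_manifest(manifest, manifest_path)
    truth_out = {
        k: v for k, v in series.truth.items() if not isinstance(v, Spectrum) and v is not None
    }
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth_out, fh, indent=2, sort_keys=True)
    return manifest_path


# ---------------------------------------------------------------------------
# Toy trajectories

@dataclass(frozen=True)
class TrajectoryTruth:
    """Specification of a toy trajectory with known structure.

    ``rule`` is one of ``ideal_gas``, ``fixed_radius_shell``, ``lattice``,
    ``oriented_osmolytes``; rule-specific parameters go into ``params``.
    """

    box: tuple[float, float, float] = (20.0, 20.0, 20.0)
    n_frames: int = 10
    rule: str = "ideal_gas"
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if any(l <= 0 for l in self.box):
            raise DomainError("box lengths must be positive")
        if self.n_frames <= 0:
            raise DomainError("need at least one frame")


def make_trajectory(truth: TrajectoryTruth) -> tuple[Trajectory, dict]:
    """Generate a toy trajectory and its machine-readable truth record."""
    rng = np.random.default_rng(truth.seed)
    box = np.array(truth.box, dtype=float)
    p = dict(truth.params)
    rule = truth.rule
    record: dict = {"rule": rule, "box": list(map(float, box)), "seed": truth.seed, "n_frames": truth.n_frames}

    if rule == "ideal_gas":
        n = int(p.get("n_atoms", 1000))
        min_sep = float(p.get("min_separation", 0.0))
        if min_sep > 0 and n * (4 / 3) * np.pi * (min_sep / 2) ** 3 > 0.5 * np.prod(box):
            raise GenerationError("requested minimum separation overfills the box")
        coords = rng.uniform(0, 1, size=(truth.n_frames, n, 3)) * box
        elements = ("Ar",) * n
        record.update(n_atoms=n)

    elif rule == "fixed_radius_shell":
        k = int(p.get("k", 12))
        d = float(p.get("d", 3.0))
        if d >= np.min(box) / 2:
            raise GenerationError("shell radius must fit inside half the box")
        center = box / 2
        frames = []
        for _ in range(truth.n_frames):
            u = rng.standard_normal((k, 3))
            u /= np.linalg.norm(u, axis=1)[:, None]
            frames.append(np.vstack([center, center + d * u]))
        coords = np.array(frames)
        elements = ("C",) + ("O",) * k
        record.update(k=k, d=d, center_index=0)

    elif rule == "lattice":
        n_side = int(p.get("n_side", 4))
        spacing = float(p.get("spacing", 3.1))
        r_oh = float(p.get("r_oh", 0.96))
        if spacing > 3.5:
            raise GenerationError("lattice spacing beyond the H-bond cutoff has no known count")
        box = np.array([n_side * spacing] * 3)
        ii, jj, kk = np.meshgrid(*([np.arange(n_side)] * 3), indexing="ij")
        o_pos = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]) * spacing + spacing / 2
        n_w = o_pos.shape[0]
        coords_1, elements_l, waters = [], [], []
        for w in range(n_w):
            o = o_pos[w]
            i0 = len(elements_l)
            coords_1 += [o, o + [r_oh, 0, 0], o + [0, r_oh, 0]]
            elements_l += ["O", "H", "H"]
            waters.append((i0, (i0 + 1, i0 + 2)))
        coords = np.tile(np.array(coords_1), (truth.n_frames, 1, 1))
        elements = tuple(elements_l)
        record["box"] = list(map(float, box))
        # each water donates exactly two bonds (to its +x and +y neighbours)
        record.update(
            n_waters=n_w,
            spacing=spacing,
            waters=[[o, list(h)] for o, h in waters],
            expected_pairs=2 * n_w,
            expected_bonds_per_water=4.0,
        )

    elif rule == "oriented_osmolytes":
        n_probes = int(p.get("n_probes", 200))
        law = p.get("law", "isotropic")
        theta0 = float(p.get("theta0", 0.0))
        bond = float(p.get("bond_length", 1.2))
        d_min = float(p.get("d_min", 3.0))
        d_max = float(p.get("d_max", min(box) / 2 - bond - 0.5))
        if d_max <= d_min:
            raise GenerationError("d_max must exceed d_min")
        center = box / 2
        frames = []
        for _ in range(truth.n_frames):
            pts = [center]
            dirs = rng.standard_normal((n_probes, 3))
            dirs /= np.linalg.norm(dirs, axis=1)[:, None]
            radii = rng.uniform(d_min, d_max, size=n_probes)
            c_pos = center + radii[:, None] * dirs
            for i in range(n_probes):
                to_gc = (center - c_pos[i]) / np.linalg.norm(center - c_pos[i])
                if law == "isotropic":
                    u = rng.standard_normal(3)
                    u /= np.linalg.norm(u)
                elif law == "delta":
                    u = _rotate_away(to_gc, np.radians(theta0), rng)
                else:
                    raise GenerationError(f"unknown orientation law {law!r}")
                pts += [c_pos[i], c_pos[i] + bond * u, c_pos[i] - bond * u]
            frames.append(np.array(pts))
        coords = np.array(frames)
        elements = ("X",) + ("C", "O", "H") * n_probes
        record.update(
            n_probes=n_probes,
            law=law,
            theta0=theta0,
            center_index=0,
            bond_vectors=[[1 + 3 * i, 2 + 3 * i] for i in range(n_probes)],
        )

    else:
        raise GenerationError(f"unknown placement rule {rule!r}")

    traj = Trajectory(coords=np.mod(coords, box), box=box, elements=elements)
    return traj, record


def _rotate_away(axis: np.ndarray, theta: float, rng: np.random.Generator) -> np.ndarray:
    """Unit vector at polar angle theta from *axis*, uniform in azimuth."""
    # orthonormal frame around the axis
    a = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    phi = rng.uniform(0, 2 * np.pi)
    return np.cos(theta) * a + np.sin(theta) * (np.cos(phi) * e1 + np.sin(phi) * e2)
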