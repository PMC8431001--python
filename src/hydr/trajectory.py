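"""Solvation-shell statistics from molecular trajectories.

Analyses operate on orthorhombic boxes with the minimum-image convention:
fragment-geometric-center radial distribution functions
g(r) = (V/N) dN/dV, distance-binned orientation-angle histograms for
osmolyte bond vectors (e.g. urea C=O or TMAO N-O against the vector to a
fragment geometric center), and geometric hydrogen-bond counting with a
donor-acceptor distance and donor-angle criterion.

Atom indices are 0-based throughout the Python API; configuration files use
1-based indices (converted on load), matching common topology conventions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DomainError, ParseError, RangeError, ValidationError

__all__ = [
    "Trajectory",
    "FragmentSpec",
    "RDFResult",
    "AngleHistogram",
    "HBondCriteria",
    "ShellStats",
    "read_xyz",
    "write_xyz",
    "read_gro",
    "minimum_image",
    "geometric_center",
    "rdf_around_center",
    "angle_distribution",
    "count_hbonds",
    "shell_hbond_stats",
    "load_fragment_config",
]


@dataclass(frozen=True)
class Trajectory:
    """Frames of coordinates (angstrom) in orthorhombic boxes."""

    coords: np.ndarray  # (n_frames, n_atoms, 3)
    box: np.ndarray  # (n_frames, 3) box edge lengths
    elements: tuple[str, ...]

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        box = np.asarray(self.box, dtype=float)
        if box.ndim == 1:
            box = np.tile(box, (coords.shape[0], 1))
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "box", box)
        object.__setattr__(self, "elements", tuple(self.elements))
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValidationError("coords must have shape (n_frames, n_atoms, 3)")
        if box.shape != (coords.shape[0], 3):
            raise ValidationError("box must have shape (n_frames, 3)")
        if np.any(box <= 0):
            raise ValidationError("box lengths must be positive")
        if len(self.elements) != coords.shape[1]:
            raise ValidationError("one element label per atom is required")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class FragmentSpec:
    """Named atom groups, bond vectors and the analysed selection (0-based)."""

    fragments: Mapping[str, tuple[int, ...]]
    bond_vectors: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    selection: tuple[int, ...] = ()

    def validate(self, n_atoms: int) -> None:
        for name, idx in self.fragments.items():
            if len(idx) == 0:
                raise ValidationError(f"fragment {name!r} is empty")
            if any(i < 0 or i >= n_atoms for i in idx):
                raise ValidationError(f"fragment {name!r} has out-of-range indices")
        for name, (i, j) in self.bond_vectors.items():
            if i == j:
                raise ValidationError(f"bond vector {name!r} uses the same atom twice")
            if any(k < 0 or k >= n_atoms for k in (i, j)):
                raise ValidationError(f"bond vector {name!r} has out-of-range indices")
        if any(i < 0 or i >= n_atoms for i in self.selection):
            raise ValidationError("selection has out-of-range indices")


def load_fragment_config(path) -> FragmentSpec:
    """Load fragments/bond_vectors/selection from YAML (1-based indices)."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    fragments = {k: tuple(i - 1 for i in v) for k, v in (doc.get("fragments") or {}).items()}
    bonds = {k: (v[0] - 1, v[1] - 1) for k, v in (doc.get("bond_vectors") or {}).items()}
    selection = tuple(i - 1 for i in doc.get("selection", []))
    return FragmentSpec(fragments=fragments, bond_vectors=bonds, selection=selection)


# ---------------------------------------------------------------------------
# Trajectory file formats

_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_BOX_RE = re.compile(r"box=(\S+)\s+(\S+)\s+(\S+)")


def write_xyz(traj: Trajectory, path) -> None:
    """Write extended XYZ with the box on the comment line (Lattice= style)."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            lx, ly, lz = traj.box[f]
            fh.write(f"{traj.n_atoms}\n")
            fh.write(
                f'Lattice="{lx:.9f} 0 0 0 {ly:.9f} 0 0 0 {lz:.9f}" '
                "Properties=species:S:1:pos:R:3\n"
            )
            for el, (x, y, z) in zip(traj.elements, traj.coords[f]):
                fh.write(f"{el} {x:.9f} {y:.9f} {z:.9f}\n")


def read_xyz(path) -> Trajectory:
    """Read extended XYZ; box from Lattice="..." or box=Lx Ly Lz comments."""
    frames, boxes = [], []
    elements: list[str] | None = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"{path}: line {i + 1}: expected atom count, got {lines[i]!r}")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        m = _LATTICE_RE.search(comment)
        if m:
            vals = [float(v) for v in m.group(1).split()]
            if len(vals) != 9 or any(abs(v) > 1e-9 for v in (vals[1], vals[2], vals[3], vals[5], vals[6], vals[7])):
                raise ParseError(f"{path}: line {i + 2}: only orthorhombic lattices are supported")
            box = [vals[0], vals[4], vals[8]]
        else:
            m = _BOX_RE.search(comment)
            if not m:
                raise ParseError(f"{path}: line {i + 2}: comment lacks Lattice= or box= record")
            box = [float(m.group(k)) for k in (1, 2, 3)]
        els, xyz = [], []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise ParseError(f"{path}: line {i + 3 + j}: expected 'El x y z'")
            els.append(parts[0])
            xyz.append([float(p) for p in parts[1:4]])
        if elements is None:
            elements = els
        elif els != list(elements):
            raise ValidationError(f"{path}: atom labels change between frames")
        frames.append(xyz)
        boxes.append(box)
        i += 2 + n
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return Trajectory(np.array(frames), np.array(boxes), tuple(elements))


def read_gro(path) -> Trajectory:
    """Read a GROMACS .gro file (possibly multi-frame) via MDAnalysis.

    Coordinates are converted from nm to angstrom by MDAnalysis itself.
    """
    import MDAnalysis as mda

    u = mda.Universe(path)
    frames, boxes = [], []
    for ts in u.trajectory:
        if abs(ts.dimensions[3] - 90) > 1e-6 or abs(ts.dimensions[4] - 90) > 1e-6 or abs(ts.dimensions[5] - 90) > 1e-6:
            raise ValidationError("only orthorhombic boxes are supported")
        frames.append(ts.positions.copy())
        boxes.append(ts.dimensions[:3].copy())
    elements = tuple(str(n) for n in u.atoms.names)
    return Trajectory(np.array(frames), np.array(boxes), elements)


# ---------------------------------------------------------------------------
# Geometry

def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Map displacement vectors into the central image of an orthorhombic box."""
    return d - box * np.round(d / box)


def geometric_center(coords: np.ndarray, box: np.ndarray, indices: Sequence[int]) -> np.ndarray:
    """Unweighted centroid of a fragment, unwrapped by minimum image.

    Member atoms are unwrapped relative to the first atom of the fragment;
    a fragment spanning more than half the box in any direction after
    unwrapping is ambiguous under periodicity and raises an error.  The
    center is wrapped back into [0, L).
    """
    idx = np.asarray(indices, dtype=int)
    if idx.size == 0:
        raise DomainError("fragment must contain at least one atom")
    ref = coords[idx[0]]
    disp = minimum_image(coords[idx] - ref, box)
    span = disp.max(axis=0) - disp.min(axis=0)
    if np.any(span > box / 2):
        raise DomainError("fragment spans more than half the box; geometric center is ambiguous")
    center = ref + disp.mean(axis=0)
    return np.mod(center, box)


@dataclass(frozen=True)
class RDFResult:
    """Radial distribution of selected atoms around a fragment center."""

    r: np.ndarray  # bin centers, angstrom
    g: np.ndarray
    counts: np.ndarray  # raw pair counts per bin, summed over frames
    bin_width: float
    normalization: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.g < 0):
            raise ValidationError("g(r) must be non-negative")


def rdf_around_center(
    traj: Trajectory,
    fragment: Sequence[int],
    selection: Sequence[int],
    r_max: float,
    bin_width: float = 0.1,
) -> RDFResult:
    """g(r) = (V/N) * count / (frames * V_shell) around the fragment centroid."""
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise DomainError("selection must not be empty")
    l_min = float(np.min(traj.box))
    if r_max > l_min / 2 + 1e-9:
        raise RangeError(f"r_max={r_max} exceeds half the smallest box length ({l_min / 2})")
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    counts = np.zeros(len(edges) - 1)
    volumes = []
    for f in range(traj.n_frames):
        box = traj.box[f]
        gc = geometric_center(traj.coords[f], box, fragment)
        d = minimum_image(traj.coords[f][selection] - gc, box)
        r = np.linalg.norm(d, axis=1)
        h, _ = np.histogram(r, bins=edges)
        counts += h
        volumes.append(float(np.prod(box)))
    v_mean = float(np.mean(volumes))
    n_sel = selection.size
    shells = (4.0 * np.pi / 3.0) * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = (v_mean / n_sel) * counts / (traj.n_frames * shells)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFResult(
        r=centers,
        g=g,
        counts=counts,
        bin_width=bin_width,
        normalization={"V": v_mean, "N": int(n_sel), "frames": traj.n_frames},
    )


@dataclass(frozen=True)
class AngleHistogram:
    """Per-distance-bin angle densities, each normalised to unit area in degrees."""

    distance_edges: np.ndarray  # angstrom
    angle_edges: np.ndarray  # degrees, spanning [0, 180]
    densities: tuple  # one array (or None for an empty bin) per distance bin
    counts: np.ndarray  # observations per distance bin


def angle_distribution(
    traj: Trajectory,
    fragment: Sequence[int],
    bond_vectors: Sequence[tuple[int, int]],
    distance_bins: Sequence[float],
    angle_bin_width: float = 5.0,
) -> AngleHistogram:
    """Orientation of probe bond vectors relative to a fragment's center.

    For each probe and frame the angle between the bond vector (reference
    atom -> partner atom) and the vector from the reference atom to the
    fragment geometric center is accumulated into the probe's distance bin
    (distance of the reference atom to the center).  Each distance bin's
    histogram is normalised to unit area over degrees; empty bins are
    flagged with ``None`` rather than NaN-filled.
    """
    d_edges = np.asarray(distance_bins, dtype=float)
    if d_edges.size < 2 or np.any(np.diff(d_edges) <= 0):
        raise ValidationError("distance_bins must be ascending edges with >= 2 values")
    a_edges = np.arange(0.0, 180.0 + angle_bin_width / 2, angle_bin_width)
    hists = np.zeros((d_edges.size - 1, a_edges.size - 1))
    nobs = np.zeros(d_edges.size - 1, dtype=int)
    import warnings as _warnings

    for f in range(traj.n_frames):
        box = traj.box[f]
        gc = geometric_center(traj.coords[f], box, fragment)
        for i_ref, j in bond_vectors:
            v_bond = minimum_image(traj.coords[f][j] - traj.coords[f][i_ref], box)
            v_gc = minimum_image(gc - traj.coords[f][i_ref], box)
            nb, ng = np.linalg.norm(v_bond), np.linalg.norm(v_gc)
            if nb < 1e-12 or ng < 1e-12:
                _warnings.warn("zero-length vector encountered; probe skipped", stacklevel=2)
                continue
            k = np.searchsorted(d_edges, ng, side="right") - 1
            if k < 0 or k >= d_edges.size - 1:
                continue
            cosang = np.clip(np.dot(v_bond, v_gc) / (nb * ng), -1.0, 1.0)
            theta = np.degrees(np.arccos(cosang))
            a = min(int(theta // angle_bin_width), a_edges.size - 2)
            hists[k, a] += 1
            nobs[k] += 1
    densities = []
    for k in range(d_edges.size - 1):
        if nobs[k] == 0:
            densities.append(None)
        else:
            densities.append(hists[k] / (nobs[k] * angle_bin_width))
    return AngleHistogram(
        distance_edges=d_edges, angle_edges=a_edges, densities=tuple(densities), counts=nobs
    )


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition (donor-centred angle criterion)."""

    r_max: float = 3.5  # donor O ... acceptor O maximum distance, angstrom
    angle_max: float = 30.0  # H-O(donor)...O(acceptor) maximum angle, degrees

    def __post_init__(self):
        if self.r_max <= 0 or self.angle_max <= 0:
            raise ValidationError("H-bond cutoffs must be positive")


def count_hbonds(
    coords: np.ndarray,
    box: np.ndarray,
    donors: Sequence[tuple[int, Sequence[int]]],
    acceptors: Sequence[int],
    criteria: HBondCriteria = HBondCriteria(),
) -> tuple[int, list[tuple[int, int]]]:
    """Count hydrogen-bonded O-O pairs in one frame.

    ``donors`` are ``(oxygen index, [attached H indices])`` records;
    ``acceptors`` are oxygen indices.  A pair is bonded when the O...O
    distance is within ``r_max`` and the angle between O_d->H and O_d->O_a
    is within ``angle_max`` for some attached H.  Each unordered pair counts
    once even if both members donate to each other.
    """
    pairs: set[tuple[int, int]] = set()
    acceptors = np.asarray(acceptors, dtype=int)
    for o_d, hs in donors:
        if len(hs) == 0:
            raise ValidationError(f"donor oxygen {o_d} has no attached hydrogens")
        d_oa = minimum_image(coords[acceptors] - coords[o_d], box)
        dist = np.linalg.norm(d_oa, axis=1)
        cand = np.nonzero((dist <= criteria.r_max) & (acceptors != o_d) & (dist > 1e-9))[0]
        if cand.size == 0:
            continue
        for h in hs:
            v_oh = minimum_image(coords[h] - coords[o_d], box)
            n_oh = np.linalg.norm(v_oh)
            if n_oh < 1e-12:
                raise ValidationError(f"hydrogen {h} coincides with its donor oxygen {o_d}")
            cosang = (d_oa[cand] @ v_oh) / (dist[cand] * n_oh)
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            for k in cand[ang <= criteria.angle_max]:
                a = int(acceptors[k])
                pairs.add((min(o_d, a), max(o_d, a)))
    return len(pairs), sorted(pairs)


@dataclass(frozen=True)
class ShellStats:
    """Mean water-water hydrogen bonds per shell water and per bulk water."""

    mean_shell: float
    mean_bulk: float
    var_shell: float  # variance of the per-frame shell means
    var_bulk: float
    n_shell: float  # mean shell population per frame
    n_bulk: float
    criteria: HBondCriteria = HBondCriteria()
    shell_cutoff: float = 4.0


def shell_hbond_stats(
    traj: Trajectory,
    solute: Sequence[int],
    waters: Sequence[tuple[int, Sequence[int]]],
    shell_cutoff: float = 4.0,
    criteria: HBondCriteria = HBondCriteria(),
) -> ShellStats:
    """Water-water H-bond counts split by solvation-shell membership.

    A water belongs to the shell when its oxygen lies within ``shell_cutoff``
    (closed interval: a distance exactly equal to the cutoff is included) of
    any solute heavy atom.  Waters double as donors and acceptors; the
    per-water bond count attributes each bonded pair to both members.
    """
    solute = np.asarray(solute, dtype=int)
    if solute.size == 0:
        raise DomainError("solute selection must not be empty")
    w_ox = np.array([o for o, _ in waters], dtype=int)
    if np.intersect1d(solute, w_ox).size:
        raise ValidationError("solute and water selections must be disjoint")
    shell_means, bulk_means, shell_ns, bulk_ns = [], [], [], []
    any_shell = False
    for f in range(traj.n_frames):
        coords, box = traj.coords[f], traj.box[f]
        d = minimum_image(coords[w_ox][:, None, :] - coords[solute][None, :, :], box)
        dmin = np.linalg.norm(d, axis=2).min(axis=1)
        in_shell = dmin <= shell_cutoff
        _, pairs = count_hbonds(coords, box, waters, w_ox, criteria)
        per_water = {int(o): 0 for o in w_ox}
        for i, j in pairs:
            per_water[i] += 1
            per_water[j] += 1
        counts = np.array([per_water[int(o)] for o in w_ox], dtype=float)
        if in_shell.any():
            any_shell = True
            shell_means.append(float(counts[in_shell].mean()))
        shell_ns.append(int(in_shell.sum()))
        if (~in_shell).any():
            bulk_means.append(float(counts[~in_shell].mean()))
        bulk_ns.append(int((~in_shell).sum()))
    if not any_shell:
        raise DomainError("no water entered the solvation shell in any frame")
    return ShellStats(
        mean_shell=float(np.mean(shell_means)),
        mean_bulk=float(np.mean(bulk_means)) if bulk_means else float("nan"),
        var_shell=float(np.var(shell_means)),
        var_bulk=float(np.var(bulk_means)) if bulk_means else float("nan"),
        n_shell=float(np.mean(shell_ns)),
        n_bulk=float(np.mean(bulk_ns)),
        criteria=criteria,
        shell_cutoff=shell_cutoff,
    )
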