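import itertools

import numpy as np
import pytest

from hydr.errors import DomainError, RangeError, ValidationError
from hydr.synthetic import TrajectoryTruth, make_trajectory
from hydr.trajectory import (
    HBondCriteria,
    Trajectory,
    angle_distribution,
    count_hbonds,
    geometric_center,
    rdf_around_center,
    shell_hbond_stats,
)

BOX = np.array([10.0, 10.0, 10.0])


class TestGeometricCenter:
    def test_single_atom_is_itself(self):
        coords = np.array([[1.0, 2.0, 3.0]])
        assert np.allclose(geometric_center(coords, BOX, [0]), [1, 2, 3])

    def test_midpoint_of_pair(self):
        coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        assert np.allclose(geometric_center(coords, BOX, [0, 1]), [1, 0, 0])

    def test_pair_straddling_periodic_boundary(self):
        coords = np.array([[9.5, 5.0, 5.0], [0.5, 5.0, 5.0]])
        gc = geometric_center(coords, BOX, [0, 1])
        assert gc[0] == pytest.approx(0.0, abs=1e-12) or gc[0] == pytest.approx(10.0, abs=1e-12)

    def test_matches_brute_force_image_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            base = rng.uniform(0, 10, 3)
            offsets = rng.uniform(-2, 2, (4, 3))
            coords = np.mod(base + offsets, BOX)
            gc = geometric_center(coords, BOX, [0, 1, 2, 3])
            # oracle: enumerate periodic images of each atom around atom 0
            ref = coords[0]
            best = []
            for i in range(4):
                candidates = [
                    coords[i] + BOX * np.array(shift)
                    for shift in itertools.product((-1, 0, 1), repeat=3)
                ]
                best.append(min(candidates, key=lambda c: np.linalg.norm(c - ref)))
            expected = np.mod(np.mean(best, axis=0), BOX)
            assert np.allclose(gc, expected, atol=1e-9)

    def test_fragment_wider_than_half_box_rejected(self):
        coords = np.array([[0.0, 5, 5], [3.0, 5, 5], [6.5, 5, 5]])
        with pytest.raises(DomainError):
            geometric_center(coords, BOX, [0, 1, 2])


def _single_frame_traj(coords, box=BOX, elements=None):
    coords = np.asarray(coords, dtype=float)
    elements = elements or tuple("X" * len(coords))
    return Trajectory(coords[None, :, :], np.asarray(box, dtype=float), tuple(elements))


class TestRDF:
    def test_single_atom_closed_form_bin(self):
        # one selection atom at 3.05 angstrom from the center atom
        box = np.array([20.0, 20.0, 20.0])
        coords = [[10.0, 10, 10], [13.05, 10, 10]]
        traj = _single_frame_traj(coords, box)
        res = rdf_around_center(traj, [0], [1], r_max=5.0, bin_width=0.1)
        k = 30  # bin [3.0, 3.1)
        v_shell = (4 * np.pi / 3) * (3.1**3 - 3.0**3)
        assert res.g[k] == pytest.approx(20.0**3 / v_shell, rel=1e-9)
        others = np.delete(res.g, k)
        assert np.all(others == 0)

    def test_pair_count_conservation(self):
        traj, _ = make_trajectory(
            TrajectoryTruth(box=(20, 20, 20), n_frames=10, rule="ideal_gas", params={"n_atoms": 200}, seed=6)
        )
        sel = list(range(1, 200))
        res = rdf_around_center(traj, [0], sel, r_max=9.9, bin_width=0.1)
        # every selection atom within r_max lands in exactly one bin
        per_frame = res.counts.sum() / traj.n_frames
        assert per_frame <= len(sel)
        assert per_frame > 0.5 * len(sel)  # most of the box is inside r_max

    def test_empty_selection_rejected(self):
        traj = _single_frame_traj([[1.0, 1, 1], [2.0, 2, 2]])
        with pytest.raises(DomainError):
            rdf_around_center(traj, [0], [], r_max=4.0)

    def test_r_max_beyond_half_box_rejected(self):
        traj = _single_frame_traj([[1.0, 1, 1], [2.0, 2, 2]])
        with pytest.raises(RangeError):
            rdf_around_center(traj, [0], [1], r_max=6.0)

    def test_translation_and_rewrap_invariance(self):
        traj, _ = make_trajectory(
            TrajectoryTruth(box=(20, 20, 20), n_frames=5, rule="ideal_gas", params={"n_atoms": 100}, seed=7)
        )
        res1 = rdf_around_center(traj, [0], list(range(1, 100)), r_max=8.0)
        shifted = Trajectory(
            np.mod(traj.coords + np.array([7.3, -4.1, 11.9]), 20.0), traj.box, traj.elements
        )
        res2 = rdf_around_center(shifted, [0], list(range(1, 100)), r_max=8.0)
        assert np.allclose(res1.counts, res2.counts)


class TestAngles:
    def test_aligned_probes_fill_first_bin(self):
        # bond vectors pointing exactly at the center
        box = np.array([30.0, 30.0, 30.0])
        center = np.array([15.0, 15, 15])
        coords = [center]
        bonds = []
        rng = np.random.default_rng(8)
        for k in range(10):
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            c = center + 6.0 * u
            o = c - 1.2 * u  # points toward the center
            idx = len(coords)
            coords += [c, o]
            bonds.append((idx, idx + 1))
        traj = _single_frame_traj(coords, box)
        hist = angle_distribution(traj, [0], bonds, distance_bins=[0.0, 10.0], angle_bin_width=5.0)
        assert hist.densities[0][0] * 5.0 == pytest.approx(1.0)

    def test_each_distance_bin_has_unit_area(self):
        traj, rec = make_trajectory(
            TrajectoryTruth(
                box=(30, 30, 30),
                n_frames=10,
                rule="oriented_osmolytes",
                params={"n_probes": 100, "law": "isotropic", "d_min": 3.0, "d_max": 12.0},
                seed=9,
            )
        )
        hist = angle_distribution(
            traj, [rec["center_index"]], rec["bond_vectors"], distance_bins=[3.0, 6.0, 9.0, 12.0]
        )
        for dens, n in zip(hist.densities, hist.counts):
            if n:
                assert np.sum(dens) * 5.0 == pytest.approx(1.0, abs=1e-9)

    def test_empty_distance_bin_flagged_not_nan(self):
        traj, rec = make_trajectory(
            TrajectoryTruth(
                box=(30, 30, 30),
                n_frames=2,
                rule="oriented_osmolytes",
                params={"n_probes": 20, "law": "isotropic", "d_min": 5.0, "d_max": 8.0},
                seed=10,
            )
        )
        hist = angle_distribution(
            traj, [rec["center_index"]], rec["bond_vectors"], distance_bins=[0.0, 2.0, 10.0]
        )
        assert hist.densities[0] is None
        assert hist.counts[0] == 0

    def test_isotropic_probes_follow_sine_law(self):
        traj, rec = make_trajectory(
            TrajectoryTruth(
                box=(30, 30, 30),
                n_frames=20,
                rule="oriented_osmolytes",
                params={"n_probes": 500, "law": "isotropic"},
                seed=11,
            )
        )
        hist = angle_distribution(
            traj, [rec["center_index"]], rec["bond_vectors"], distance_bins=[0.0, 15.0], angle_bin_width=5.0
        )
        centers = np.radians(0.5 * (hist.angle_edges[1:] + hist.angle_edges[:-1]))
        expected = np.sin(centers) / 2.0 * (np.pi / 180.0)  # per degree
        observed = hist.densities[0]
        n = hist.counts[0]
        se = np.sqrt(np.maximum(expected, 1e-12) / (n * 5.0 * (np.pi / 180.0)) * (np.pi / 180.0))
        assert np.all(np.abs(observed - expected) < 4 * se + 1e-4)


class TestHBonds:
    def _water(self, o, h1, h2):
        return np.array(o, float), [np.array(h1, float), np.array(h2, float)]

    def test_pair_beyond_cutoff_not_bonded(self):
        coords = np.array([[0.0, 0, 0], [0.96, 0, 0], [0, 0.96, 0], [5.0, 0, 0], [5.96, 0, 0], [5, 0.96, 0]])
        n, pairs = count_hbonds(coords, np.array([20.0, 20, 20]), [(0, [1, 2]), (3, [4, 5])], [0, 3])
        assert n == 0

    def test_linear_dimer_counts_one_bond(self):
        coords = np.array([[0.0, 0, 0], [0.96, 0, 0], [0, 0.96, 0], [2.8, 0, 0], [3.76, 0, 0], [2.8, 0.96, 0]])
        n, pairs = count_hbonds(coords, np.array([20.0, 20, 20]), [(0, [1, 2]), (3, [4, 5])], [0, 3])
        assert n == 1
        assert pairs == [(0, 3)]

    def test_cluster_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        box = np.array([15.0, 15.0, 15.0])
        waters = []
        coords = []
        for w in range(5):
            o = rng.uniform(4, 11, 3)
            h1 = o + 0.96 * _unit(rng)
            h2 = o + 0.96 * _unit(rng)
            i = len(coords)
            coords += [o, h1, h2]
            waters.append((i, [i + 1, i + 2]))
        coords = np.array(coords)
        crit = HBondCriteria()
        n, pairs = count_hbonds(coords, box, waters, [o for o, _ in waters], crit)
        assert set(pairs) == _brute_force_pairs(coords, box, waters, crit)
        assert n == len(pairs)

    def test_missing_hydrogen_rejected(self):
        coords = np.array([[0.0, 0, 0], [2.8, 0, 0]])
        with pytest.raises(ValidationError):
            count_hbonds(coords, np.array([10.0, 10, 10]), [(0, [])], [1])


def _unit(rng):
    u = rng.standard_normal(3)
    return u / np.linalg.norm(u)


def _brute_force_pairs(coords, box, waters, crit):
    """Independent all-pairs H-bond enumeration (pure python loops)."""
    found = set()
    for oi, his in waters:
        for oj, _ in waters:
            if oi == oj:
                continue
            d = coords[oj] - coords[oi]
            d = d - box * np.round(d / box)
            if np.linalg.norm(d) > crit.r_max:
                continue
            for h in his:
                v = coords[h] - coords[oi]
                v = v - box * np.round(v / box)
                cosang = (d @ v) / (np.linalg.norm(d) * np.linalg.norm(v))
                ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if ang <= crit.angle_max:
                    found.add((min(oi, oj), max(oi, oj)))
    return found


class TestShellStats:
    @staticmethod
    def _construct():
        """4 shell waters with 2 bonds each, 4 bulk waters with 3 each.

        Shell: square ring (each water donates to its clockwise neighbour).
        Bulk: regular tetrahedron with 6 edges covered by directed donations.
        """
        box = np.array([40.0, 40.0, 40.0])
        a = 2.8
        coords = [np.array([10.0, 10.0, 10.0])]  # solute heavy atom
        waters = []
        ring = [
            np.array([10.0 + a / 2, 10.0 + a / 2, 10.0]),
            np.array([10.0 - a / 2, 10.0 + a / 2, 10.0]),
            np.array([10.0 - a / 2, 10.0 - a / 2, 10.0]),
            np.array([10.0 + a / 2, 10.0 - a / 2, 10.0]),
        ]
        for k, o in enumerate(ring):
            nxt = ring[(k + 1) % 4]
            u = (nxt - o) / np.linalg.norm(nxt - o)
            i = len(coords)
            coords += [o, o + 0.96 * u, o + 0.96 * np.array([0, 0, 1.0])]
            waters.append((i, [i + 1, i + 2]))
        # tetrahedron 20 angstrom away
        base = np.array([30.0, 30.0, 30.0])
        verts = [
            base,
            base + [a, 0, 0],
            base + [a / 2, a * np.sqrt(3) / 2, 0],
            base + [a / 2, a * np.sqrt(3) / 6, a * np.sqrt(2.0 / 3.0)],
        ]
        donations = {0: (1, 2), 1: (2, 3), 2: (3,), 3: (0,)}
        for k, o in enumerate(verts):
            hs = []
            for tgt in donations[k]:
                u = (verts[tgt] - o) / np.linalg.norm(verts[tgt] - o)
                hs.append(o + 0.96 * u)
            while len(hs) < 2:
                hs.append(o + 0.96 * np.array([0, 0, -1.0]))
            i = len(coords)
            coords += [o] + hs
            waters.append((i, [i + 1, i + 2]))
        traj = Trajectory(np.array(coords)[None, :, :], box, tuple("X" * len(coords)))
        return traj, waters

    def test_constructed_shell_and_bulk_means(self):
        traj, waters = self._construct()
        stats = shell_hbond_stats(traj, [0], waters, shell_cutoff=4.0)
        assert stats.n_shell == 4
        assert stats.n_bulk == 4
        assert stats.mean_shell == pytest.approx(2.0)
        assert stats.mean_bulk == pytest.approx(3.0)

    def test_boundary_distance_included_in_shell(self):
        box = np.array([30.0, 30.0, 30.0])
        coords = np.array(
            [[5.0, 5, 5], [9.0, 5, 5], [9.96, 5, 5], [9.0, 5.96, 5]]
        )
        traj = Trajectory(coords[None], box, ("S", "O", "H", "H"))
        stats = shell_hbond_stats(traj, [0], [(1, [2, 3])], shell_cutoff=4.0)
        assert stats.n_shell == 1  # distance exactly 4.0: closed interval

    def test_empty_solute_rejected(self):
        traj, waters = self._construct()
        with pytest.raises(DomainError):
            shell_hbond_stats(traj, [], waters)

    def test_overlapping_solute_and_water_rejected(self):
        traj, waters = self._construct()
        with pytest.raises(ValidationError):
            shell_hbond_stats(traj, [waters[0][0]], waters)
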