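import filecmp
import os

import numpy as np
import pytest
from scipy.stats import kstest

from hydr.errors import DomainError, GenerationError
from hydr.spectra import load_manifest, series_molar_absorptivity
from hydr.synthetic import (
    PseudoVoigtBand,
    SpectralTruth,
    TrajectoryTruth,
    default_osmolyte_truth,
    default_peptide_truth,
    make_binary_series,
    make_ternary_series,
    make_trajectory,
    n_sh_for_share,
    write_series,
)
from hydr.ternary import theoretical_affected


class TestPseudoVoigt:
    def test_gaussian_limit_has_correct_fwhh(self):
        band = PseudoVoigtBand(2500.0, 150.0, 2.0, eta=1.0)
        assert band(np.array([2500.0]))[0] == pytest.approx(2.0)
        assert band(np.array([2575.0]))[0] == pytest.approx(1.0)  # half height at fwhh/2

    def test_lorentzian_limit_has_correct_fwhh(self):
        band = PseudoVoigtBand(2500.0, 150.0, 2.0, eta=0.0)
        assert band(np.array([2575.0]))[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("kwargs", [dict(fwhh=-1.0), dict(amplitude=0.0), dict(eta=1.5)])
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(center=2500.0, fwhh=150.0, amplitude=1.0)
        base.update(kwargs)
        with pytest.raises(DomainError):
            PseudoVoigtBand(**base)


class TestBinarySeries:
    def test_noiseless_mixture_identity(self, peptide_series):
        truth = peptide_series.truth
        for m, spec in peptide_series.series:
            frac = truth["N_true"] * truth["M"] * m
            expected = (1 - frac) * truth["eps_b"].values + frac * truth["eps_a"].values
            assert np.max(np.abs(spec.values - expected)) < 1e-12

    def test_same_seed_is_byte_identical(self, tmp_path, peptide_truth):
        t = default_peptide_truth(noise_sigma=0.01, seed=42)
        for d in ("a", "b"):
            write_series(make_binary_series(t), tmp_path / d, solute_name="pep")
        for name in os.listdir(tmp_path / "a"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False), name

    def test_affected_fraction_must_stay_below_one(self, peptide_truth):
        with pytest.raises(DomainError):
            make_binary_series(peptide_truth, molalities=(1.0, 5.0, 12.0))

    def test_written_series_round_trips_through_manifest(self, tmp_path, peptide_series):
        path = write_series(peptide_series, tmp_path / "s", solute_name="pep")
        mf = load_manifest(path)
        bulk, series = series_molar_absorptivity(mf, grid=peptide_series.bulk.grid)
        assert np.max(np.abs(bulk.values - peptide_series.bulk.values)) < 1e-6
        for (m0, s0), (m1, s1) in zip(peptide_series.series, series):
            assert m0 == m1
            assert np.max(np.abs(s0.values - s1.values)) < 1e-6


class TestTernarySeries:
    def test_non_interacting_limit_equals_theoretical(self, grid, peptide_truth, osmolyte_truth):
        ts = make_ternary_series(peptide_truth, osmolyte_truth, x=0.4)
        eps_theor, n_theor = theoretical_affected(
            peptide_truth.eps_a(grid),
            peptide_truth.N_true,
            osmolyte_truth.eps_a(grid),
            osmolyte_truth.N_true,
            0.4,
        )
        assert ts.truth["N_exp"] == pytest.approx(n_theor)
        assert np.max(np.abs(ts.truth["eps_exp"].values - eps_theor.values)) < 1e-12
        assert ts.truth["share_pct_true"] == 0.0

    def test_shared_water_bookkeeping(self, peptide_truth, osmolyte_truth):
        shared = (PseudoVoigtBand(2420.0, 120.0, 30.0),)
        ts = make_ternary_series(
            peptide_truth, osmolyte_truth, x=0.5, shared_bands=shared, N_sh=1.0
        )
        # with full retention the shared count adds on top of the theoretical number
        n_theor = 0.5 * peptide_truth.N_true + 0.5 * osmolyte_truth.N_true
        assert ts.truth["N_exp"] == pytest.approx(n_theor + 1.0)
        assert ts.truth["share_pct_true"] > 0

    def test_share_target_solved_exactly(self, peptide_truth, osmolyte_truth):
        shared = (PseudoVoigtBand(2420.0, 120.0, 30.0),)
        nsh = n_sh_for_share(peptide_truth, osmolyte_truth, 0.5, shared, 12.5, w_o=0.3)
        ts = make_ternary_series(
            peptide_truth, osmolyte_truth, x=0.5, shared_bands=shared, N_sh=nsh, w_o=0.3
        )
        assert ts.truth["share_pct_true"] == pytest.approx(12.5, abs=1e-9)

    def test_mismatched_bulk_bands_rejected(self, peptide_truth):
        other = SpectralTruth(
            bulk_bands=(PseudoVoigtBand(2400.0, 100.0, 10.0),),
            affected_bands=default_osmolyte_truth().affected_bands,
            N_true=4.0,
        )
        with pytest.raises(DomainError):
            make_ternary_series(peptide_truth, other, x=0.5)


class TestTrajectories:
    def test_ideal_gas_coordinates_are_uniform(self):
        traj, rec = make_trajectory(
            TrajectoryTruth(box=(20, 20, 20), n_frames=200, rule="ideal_gas", params={"n_atoms": 1000}, seed=1)
        )
        flat = traj.coords.reshape(-1, 3)
        for axis in range(3):
            stat, p = kstest(flat[:, axis] / 20.0, "uniform")
            assert p > 0.01

    def test_fixed_radius_shell_exact_distances(self):
        traj, rec = make_trajectory(
            TrajectoryTruth(box=(20, 20, 20), n_frames=5, rule="fixed_radius_shell", params={"k": 12, "d": 3.0}, seed=2)
        )
        assert traj.n_atoms == 13
        center = traj.coords[:, 0:1, :]
        d = traj.coords[:, 1:, :] - center
        d -= 20.0 * np.round(d / 20.0)
        dist = np.linalg.norm(d, axis=2)
        assert np.max(np.abs(dist - 3.0)) < 1e-9

    def test_same_seed_writes_identical_files(self, tmp_path):
        from hydr.trajectory import write_xyz

        for name in ("a.xyz", "b.xyz"):
            traj, _ = make_trajectory(
                TrajectoryTruth(n_frames=3, rule="ideal_gas", params={"n_atoms": 50}, seed=9)
            )
            write_xyz(traj, tmp_path / name)
        assert filecmp.cmp(tmp_path / "a.xyz", tmp_path / "b.xyz", shallow=False)

    def test_lattice_truth_record_consistent(self):
        traj, rec = make_trajectory(
            TrajectoryTruth(n_frames=1, rule="lattice", params={"n_side": 3, "spacing": 3.1}, seed=0)
        )
        assert rec["n_waters"] == 27
        assert rec["expected_pairs"] == 54
        assert traj.n_atoms == 81

    def test_oriented_probes_delta_law_points_at_center(self):
        traj, rec = make_trajectory(
            TrajectoryTruth(
                box=(30, 30, 30),
                n_frames=2,
                rule="oriented_osmolytes",
                params={"n_probes": 20, "law": "delta", "theta0": 0.0},
                seed=3,
            )
        )
        center = np.array([15.0, 15.0, 15.0])
        for i, j in rec["bond_vectors"]:
            v_bond = traj.coords[0][j] - traj.coords[0][i]
            v_gc = center - traj.coords[0][i]
            cosang = v_bond @ v_gc / (np.linalg.norm(v_bond) * np.linalg.norm(v_gc))
            assert cosang == pytest.approx(1.0, abs=1e-9)

    def test_overfilled_box_rejected(self):
        with pytest.raises(GenerationError):
            make_trajectory(
                TrajectoryTruth(
                    box=(5, 5, 5),
                    n_frames=1,
                    rule="ideal_gas",
                    params={"n_atoms": 10000, "min_separation": 2.0},
                    seed=0,
                )
            )

    def test_unknown_rule_rejected(self):
        with pytest.raises(GenerationError):
            make_trajectory(TrajectoryTruth(rule="perpetual_motion"))

    def test_xyz_round_trip(self, tmp_path):
        from hydr.trajectory import read_xyz, write_xyz

        traj, _ = make_trajectory(
            TrajectoryTruth(n_frames=4, rule="ideal_gas", params={"n_atoms": 30}, seed=5)
        )
        write_xyz(traj, tmp_path / "t.xyz")
        back = read_xyz(tmp_path / "t.xyz")
        assert back.n_frames == traj.n_frames
        assert back.elements == traj.elements
        assert np.allclose(back.coords, traj.coords, atol=1e-8)
        assert np.allclose(back.box, traj.box, atol=1e-8)

    def test_gro_reading_matches_reference(self, tmp_path):
        # minimal single-frame GRO (nm units; MDAnalysis converts to angstrom)
        gro = (
            "toy water\n"
            "    3\n"
            "    1SOL     OW    1   0.500   0.500   0.500\n"
            "    1SOL    HW1    2   0.596   0.500   0.500\n"
            "    1SOL    HW2    3   0.500   0.596   0.500\n"
            "   2.00000   2.00000   2.00000\n"
        )
        path = tmp_path / "w.gro"
        path.write_text(gro)
        from hydr.trajectory import read_gro

        traj = read_gro(str(path))
        assert traj.n_atoms == 3
        assert np.allclose(traj.box[0], [20.0, 20.0, 20.0], atol=1e-6)
        assert np.allclose(traj.coords[0][0], [5.0, 5.0, 5.0], atol=1e-4)
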