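"""Trajectory metrics: RMSD family, Rg, secondary structure, contacts,
permeation, SASA."""

import numpy as np
import pandas as pd
import pytest

from oligopore import synth, traj
from oligopore.structio import AtomRecord, Selection, Structure
from oligopore.traj import (ContactSpec, Trajectory, beta_content,
                            contact_profile, ensemble_rmsd,
                            radius_of_gyration, rmsd_series, rmsf, sasa,
                            water_permeation)


def small_protein(n_res=8):
    atoms = []
    serial = 0
    for r in range(1, n_res + 1):
        for name, el, off in (("N", "N", -0.6), ("CA", "C", 0.0),
                              ("C", "C", 0.6), ("O", "O", 1.1)):
            serial += 1
            atoms.append(AtomRecord(serial, name, el, "ALA", r, "A",
                                    3.5 * r + off, 0.4 * (r % 2), 0.0))
    return Structure(atoms)


def static_traj(s, n_frames=4):
    return Trajectory(s, np.repeat(s.coords()[None], n_frames, axis=0))


class TestRMSD:
    def test_copies_of_reference_all_zero(self):
        s = small_protein()
        t = static_traj(s)
        assert np.allclose(rmsd_series(t, s, Selection(names="calpha")), 0.0)

    def test_rigid_translation_removed(self):
        s = small_protein()
        frames = np.stack([s.coords(), s.coords() + np.array([3.0, -1.0, 2.0])])
        t = Trajectory(s, frames)
        assert np.allclose(rmsd_series(t, s, Selection(names="calpha")), 0.0,
                           atol=1e-10)

    def test_gaussian_displacement_vs_mdtraj(self, tetramer_structure, rng,
                                             tmp_path):
        """Per-frame best-fit RMSD matches the mdtraj implementation."""
        mdtraj = pytest.importorskip("mdtraj")
        from oligopore import structio

        s = tetramer_structure
        sigma = 0.8
        frames = np.stack([s.coords() + rng.normal(scale=sigma,
                                                   size=(len(s), 3))
                           for _ in range(5)])
        t = Trajectory(s, frames)
        ours = rmsd_series(t, s, Selection(names="calpha"))
        # oracle: mdtraj superposition + RMSD on the identical data
        p = tmp_path / "top.pdb"
        structio.write_pdb(s, str(p))
        mt = mdtraj.load(str(p))
        ca = [i for i, a in enumerate(s.atoms) if a.name == "CA"]
        traj_md = mdtraj.Trajectory(frames / 10.0, mt.topology)  # Å → nm
        ref_md = mdtraj.Trajectory(s.coords()[None] / 10.0, mt.topology)
        theirs = mdtraj.rmsd(traj_md, ref_md, atom_indices=ca) * 10.0
        np.testing.assert_allclose(ours, theirs, atol=5e-3)


class TestEnsembleRMSD:
    def test_identical_models_zero(self, tetramer_structure):
        ens, _ = synth.make_ensemble(tetramer_structure, 0.0, n_models=5)
        assert ensemble_rmsd(ens) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_only_zero(self, tetramer_structure):
        m2 = tetramer_structure.copy()
        ang = 0.5
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        m2.set_coords(tetramer_structure.coords() @ R.T + np.array([5., 6., 7.]))
        from oligopore.structio import Ensemble
        ens = Ensemble([tetramer_structure.copy(), m2])
        assert ensemble_rmsd(ens) == pytest.approx(0.0, abs=1e-6)

    def test_jitter_recovery_closed_form(self, tetramer_structure):
        """σ=0.5 Å isotropic jitter over 15 models: mean RMSD-to-mean matches
        the closed-form expectation σ√3·√(1−1/n) within 5%."""
        ens, truth = synth.make_ensemble(tetramer_structure, 0.5, n_models=15,
                                         seed=21)
        got = ensemble_rmsd(ens, Selection(names="backbone"))
        assert got == pytest.approx(truth["expected_rmsd_to_mean"], rel=0.05)

    def test_single_model_rejected(self, tetramer_structure):
        from oligopore.structio import Ensemble
        ens = Ensemble([tetramer_structure.copy()])
        with pytest.raises(ValueError):
            ensemble_rmsd(ens)


class TestRMSF:
    def test_static_zero(self):
        t = static_traj(small_protein())
        out = rmsf(t)
        assert np.allclose(out["rmsf_A"], 0.0)

    def test_single_jittered_residue_peaks(self, rng):
        s = small_protein(10)
        base = s.coords()
        idx = s.select(Selection(residues=(5, 5)))
        frames = []
        for _ in range(50):
            f = base.copy()
            f[idx] += rng.normal(scale=1.0, size=(len(idx), 3))
            frames.append(f)
        t = Trajectory(s, np.stack(frames))
        out = rmsf(t, Selection(names="calpha")).set_index("residue")
        assert out["rmsf_A"].idxmax() == 5

    def test_subsampling_preserves_ordering(self, rng):
        s = small_protein(6)
        base = s.coords()
        sigmas = {r: 0.2 * r for r in range(1, 7)}
        frames = []
        for _ in range(60):
            f = base.copy()
            for r, sg in sigmas.items():
                ii = s.select(Selection(residues=(r, r)))
                f[ii] += rng.normal(scale=sg, size=(len(ii), 3))
            frames.append(f)
        t_all = Trajectory(s, np.stack(frames))
        t_half = Trajectory(s, np.stack(frames[::2]))
        o_all = rmsf(t_all, Selection(names="calpha"))["rmsf_A"].to_numpy()
        o_half = rmsf(t_half, Selection(names="calpha"))["rmsf_A"].to_numpy()
        assert list(np.argsort(o_all)) == list(np.argsort(o_half))

    def test_single_frame_warns_zero(self):
        t = static_traj(small_protein(), n_frames=1)
        with pytest.warns(UserWarning):
            out = rmsf(t)
        assert np.allclose(out["rmsf_A"], 0.0)


class TestRg:
    def test_single_atom_zero(self):
        s = Structure([AtomRecord(1, "CA", "C", "ALA", 1, "A", 1.0, 2.0, 3.0)])
        assert radius_of_gyration(s) == pytest.approx(0.0, abs=1e-12)

    def test_two_unit_masses_half_distance(self):
        coords = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        assert radius_of_gyration(coords) == pytest.approx(2.0)

    def test_homothety_exact_ratio(self, tetramer_structure):
        rg1 = radius_of_gyration(tetramer_structure)
        shrunk = tetramer_structure.copy()
        com = tetramer_structure.coords().mean(axis=0)
        shrunk.set_coords((tetramer_structure.coords() - com) * 0.7 + com)
        assert radius_of_gyration(shrunk) == pytest.approx(0.7 * rg1, rel=1e-9)

    def test_zero_mass_errors(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.zeros((2, 3)), masses=np.zeros(2))


class TestBetaContent:
    def test_tetramer_fixture_vs_reference_dssp(self, tetramer, tmp_path):
        """Kabsch–Sander β fraction matches mdtraj DSSP on the β-sheet
        fixture within one residue per strand end, and tracks the painted
        strand fraction."""
        mdtraj = pytest.importorskip("mdtraj")
        from oligopore import structio

        s, truth = tetramer
        ours = beta_content(s)
        p = tmp_path / "tet.pdb"
        structio.write_pdb(s, str(p))
        d = mdtraj.compute_dssp(mdtraj.load(str(p)), simplified=True)[0]
        ref_beta = float(np.mean(d == "E"))
        n_res = ours.n_residues
        slack = 12 / n_res            # six strands × two ends
        assert abs(ours.beta[0] - ref_beta) <= slack
        assert abs(ours.beta[0] - truth["strand_fraction"]) <= slack
        assert ours.helix[0] == pytest.approx(0.0, abs=0.02)

    def test_single_extended_chain_no_bridge(self):
        s = small_protein(10)
        out = beta_content(s)
        assert out.beta[0] == 0.0

    def test_helix_fixture_vs_reference_dssp(self, helix, tmp_path):
        mdtraj = pytest.importorskip("mdtraj")
        from oligopore import structio

        s, _ = helix
        ours = beta_content(s)
        p = tmp_path / "helix.pdb"
        structio.write_pdb(s, str(p))
        d = mdtraj.compute_dssp(mdtraj.load(str(p)), simplified=True)[0]
        assert ours.beta[0] == 0.0
        assert ours.helix[0] == pytest.approx(float(np.mean(d == "H")),
                                              abs=2 / 16)
        assert ours.helix[0] >= 12 / 16   # interior residues helical

    def test_static_trajectory_constant(self, tetramer_structure):
        t = static_traj(tetramer_structure, n_frames=3)
        out = beta_content(t)
        assert np.ptp(out.beta) == 0.0
        assert np.ptp(out.helix) == 0.0


class TestContacts:
    def test_distant_probes_zero(self):
        t, truth = synth.make_membrane_traj(n_frames=2, seed=0)
        spec = ContactSpec(target=Selection(chains=("P", "Q"), names="amide_n"),
                           probe=truth["head_idx"], cutoff=1.0)
        prof = contact_profile(t, spec)
        assert np.allclose(prof.mean, 0.0)

    def test_constructed_three_probes_at_cutoff(self):
        """Three probes pinned at 8.9 Å of one residue's amide N count as 3."""
        t, truth = synth.make_membrane_traj(
            n_frames=2, probe_near_residue=("P", 5, 8.9), seed=1)
        spec = ContactSpec(target=Selection(chains=("P",), names="amide_n"),
                           probe=truth["pinned_probe_idx"], cutoff=9.0)
        prof = contact_profile(t, spec)
        got = dict(zip(prof.residues, prof.mean))
        assert got[5] == pytest.approx(3.0)
        assert sum(v for r, v in got.items() if r != 5) == 0.0

    def test_brute_force_equality(self, rng):
        """Counts equal an O(N²) all-pairs loop on every frame."""
        t, truth = synth.make_membrane_traj(n_frames=3, jitter=0.5, seed=2)
        target = t.topology.select(Selection(chains=("P", "Q"), names="amide_n"))
        probes = truth["head_idx"]
        spec = ContactSpec(target=Selection(chains=("P", "Q"), names="amide_n"),
                           probe=probes, cutoff=20.0)
        prof = contact_profile(t, spec)
        # independent brute force
        resnums = np.array([t.topology.atoms[i].residue_number for i in target])
        acc = {}
        for f in range(len(t)):
            for k, ti in enumerate(target):
                c = 0
                for pi in probes:
                    d = np.linalg.norm(t.frames[f, ti] - t.frames[f, pi])
                    if d <= 20.0:
                        c += 1
                acc[resnums[k]] = acc.get(resnums[k], 0) + c
        brute = {r: v / len(t) for r, v in acc.items()}
        for r, m in zip(prof.residues, prof.mean):
            assert m == pytest.approx(brute[r])

    def test_replicate_spread_convention(self):
        t1, truth = synth.make_membrane_traj(n_frames=2, jitter=0.3, seed=3)
        t2, _ = synth.make_membrane_traj(n_frames=2, jitter=0.3, seed=4)
        spec = ContactSpec(target=Selection(chains=("P", "Q"), names="amide_n"),
                           probe=truth["head_idx"], cutoff=25.0,
                           spread="sd_over_n")
        prof = contact_profile(None, spec, replicates=[t1, t2])
        spec2 = ContactSpec(target=Selection(chains=("P", "Q"), names="amide_n"),
                            probe=truth["head_idx"], cutoff=25.0,
                            spread="sd_over_sqrt_n")
        prof2 = contact_profile(None, spec2, replicates=[t1, t2])
        # SD/n vs SD/√n differ by √n
        nz = prof.spread > 0
        np.testing.assert_allclose(prof2.spread[nz] / prof.spread[nz],
                                   np.sqrt(2.0))

    def test_empty_probe_errors(self):
        t, _ = synth.make_membrane_traj(n_frames=1, seed=5)
        spec = ContactSpec(target=Selection(chains=("P",), names="amide_n"),
                           probe=np.array([], dtype=int))
        with pytest.raises(ValueError):
            contact_profile(t, spec)


class TestWaterPermeation:
    def test_no_pore_empty_slab(self):
        t, truth = synth.make_membrane_traj(pore_occupancy=0, seed=6)
        prof = water_permeation(t, truth["water_idx"])
        centers = 0.5 * (prof.bin_edges[:-1] + prof.bin_edges[1:])
        in_slab = np.abs(centers) < truth["half_thickness"] - 1.0
        assert prof.mean_counts[in_slab].sum() == 0.0

    def test_pore_occupancy_recovered(self):
        t, truth = synth.make_membrane_traj(pore_radius=5.0, pore_occupancy=10,
                                            seed=7)
        prof = water_permeation(t, truth["water_idx"])
        centers = 0.5 * (prof.bin_edges[:-1] + prof.bin_edges[1:])
        in_slab = np.abs(centers) < truth["half_thickness"]
        assert prof.mean_counts[in_slab].sum() == pytest.approx(10.0)

    def test_counts_conserved_per_frame(self):
        t, truth = synth.make_membrane_traj(pore_radius=4.0, pore_occupancy=5,
                                            n_waters=100, seed=8)
        prof = water_permeation(t, truth["water_idx"])
        assert prof.mean_counts.sum() == pytest.approx(len(truth["water_idx"]))

    def test_no_waters_errors(self):
        t, _ = synth.make_membrane_traj(seed=9)
        with pytest.raises(ValueError):
            water_permeation(t, np.array([], dtype=int))


class TestSASA:
    def test_single_atom_closed_form(self):
        """r=1.4 Å atom with a 1.4 Å probe: SASA = 4π(2.8)² ≈ 98.52 Å²."""
        s = Structure([AtomRecord(1, "O", "O", "HOH", 1, "W", 0, 0, 0)])
        total, _ = sasa(s, probe=1.4, points_per_atom=2000,
                        radii={"O": 1.4})
        assert total == pytest.approx(4 * np.pi * 2.8 ** 2, rel=1e-3)

    def test_buried_atom_near_zero(self):
        # central atom caged by 26 neighbours on a 2 Å lattice
        atoms = [AtomRecord(1, "C", "C", "ALA", 1, "A", 0, 0, 0)]
        serial = 1
        for dx in (-2.0, 0.0, 2.0):
            for dy in (-2.0, 0.0, 2.0):
                for dz in (-2.0, 0.0, 2.0):
                    if dx == dy == dz == 0.0:
                        continue
                    serial += 1
                    atoms.append(AtomRecord(serial, "C", "C", "ALA", serial,
                                            "A", dx, dy, dz))
        s = Structure(atoms)
        _, per_res = sasa(s, probe=1.4, points_per_atom=500)
        central = per_res[per_res["residue"] == 1]["sasa_A2"].iloc[0]
        assert central == pytest.approx(0.0, abs=1e-6)

    def test_two_atom_vs_dense_integration(self):
        """Two-atom SASA matches dense numerical integration within 2%."""
        s = Structure([AtomRecord(1, "C", "C", "ALA", 1, "A", 0, 0, 0),
                       AtomRecord(2, "C", "C", "ALA", 2, "A", 2.5, 0, 0)])
        total, _ = sasa(s, probe=1.4, points_per_atom=1500)
        # dense oracle: exposed sphere fraction by z-slice integral (analytic
        # cap formula): for two equal spheres radius R at distance d, each
        # loses a cap of height h = R − d/2
        R = 1.7 + 1.4
        d = 2.5
        cap = 2 * np.pi * R * (R - d / 2)
        expected = 2 * (4 * np.pi * R ** 2 - cap)
        assert total == pytest.approx(expected, rel=0.02)

    def test_missing_radius_errors(self):
        s = Structure([AtomRecord(1, "X1", "SE", "ALA", 1, "A", 0, 0, 0)])
        with pytest.raises(KeyError):
            sasa(s, radii={"C": 1.7})


def test_metrics_invariant_under_global_rigid_motion(tetramer_structure, rng):
    """Applying one rigid motion to every frame leaves RMSD/RMSF/β unchanged."""
    s = tetramer_structure
    frames = np.stack([s.coords() + rng.normal(scale=0.3, size=(len(s), 3))
                       for _ in range(3)])
    t1 = Trajectory(s, frames)
    ang = 1.1
    R = np.array([[np.cos(ang), 0, np.sin(ang)], [0, 1, 0],
                  [-np.sin(ang), 0, np.cos(ang)]])
    moved = frames @ R.T + np.array([8.0, -2.0, 4.0])
    t2 = Trajectory(s, moved)
    np.testing.assert_allclose(rmsd_series(t1, s), rmsd_series(t2, s), atol=1e-8)
    np.testing.assert_allclose(rmsf(t1)["rmsf_A"], rmsf(t2)["rmsf_A"], atol=1e-8)
    np.testing.assert_allclose(beta_content(t1).beta, beta_content(t2).beta)
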