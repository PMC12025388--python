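import numpy as np
import pytest

from oracles import grid_search_rmsd, scipy_align_rmsd

from catflex.rmsd import kabsch_superpose, minimal_rmsd, rmsd_profile
from catflex.structures import ConformerEnsemble, Structure
from catflex.synthetic import make_ensemble, random_rigid_motion


class TestKabsch:
    def test_identical_inputs_give_zero_and_identity(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0.2, 0.3, 1.1]])
        res = kabsch_superpose(P, P)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-8)
        assert res.atoms_used == 4

    def test_pure_rigid_motion_gives_zero(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.5]])
        Rz = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        Q = P @ Rz.T + np.array([5.0, -2.0, 1.0])
        res = kabsch_superpose(P, Q)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_rotation_is_always_proper(self):
        """A mirrored point set must not be matched by a reflection."""
        P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        Q = P * np.array([1.0, 1.0, -1.0])
        res = kabsch_superpose(P, Q)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)
        assert res.rmsd > 0.1  # the enantiomer is NOT a perfect match

    def test_matches_grid_search_oracle_on_spec_triangle(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        Q = np.array([[0, 0, 0], [1, 0, 0], [0, 1.2, 0]], dtype=float)
        assert kabsch_superpose(P, Q).rmsd == pytest.approx(
            grid_search_rmsd(P, Q), abs=1e-3
        )

    @pytest.mark.parametrize("n_atoms", [4, 5, 6])
    def test_matches_grid_search_oracle_on_random_instances(self, n_atoms, rng):
        P = rng.normal(size=(n_atoms, 3))
        Q = P + rng.normal(scale=0.4, size=(n_atoms, 3))
        assert kabsch_superpose(P, Q).rmsd == pytest.approx(
            grid_search_rmsd(P, Q), abs=1e-3
        )

    def test_matches_scipy_align_vectors(self, rng):
        P = rng.normal(size=(12, 3))
        Q = P + rng.normal(scale=0.6, size=(12, 3))
        assert kabsch_superpose(P, Q).rmsd == pytest.approx(scipy_align_rmsd(P, Q), abs=1e-9)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError, match="3 atoms"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            kabsch_superpose(np.zeros((3, 3)), np.zeros((4, 3)))


class TestMinimalRMSDProperties:
    def test_symmetry(self, rng):
        a = Structure(["C"] * 8, rng.normal(size=(8, 3)))
        b = Structure(["C"] * 8, a.coords + rng.normal(scale=0.5, size=(8, 3)))
        assert minimal_rmsd(a, b).rmsd == pytest.approx(minimal_rmsd(b, a).rmsd, abs=1e-9)

    def test_rigid_motion_invariance_100_motions(self, rng):
        a = Structure(["C"] * 6, rng.normal(size=(6, 3)))
        b = Structure(["C"] * 6, a.coords + rng.normal(scale=0.3, size=(6, 3)))
        base = minimal_rmsd(a, b).rmsd
        for _ in range(100):
            R, t = random_rigid_motion(rng)
            moved = b.with_coords(b.coords @ R.T + t)
            assert abs(minimal_rmsd(a, moved).rmsd - base) <= 1e-8

    def test_bounded_by_max_displacement(self, rng):
        a = Structure(["C"] * 10, rng.normal(size=(10, 3)))
        b = Structure(["C"] * 10, a.coords + rng.normal(scale=0.5, size=(10, 3)))
        res = minimal_rmsd(a, b)
        # reconstruct per-atom residuals after the optimal superposition
        aligned = b.coords @ res.rotation.T + res.translation
        max_disp = np.linalg.norm(aligned - a.coords, axis=1).max()
        assert res.rmsd <= max_disp + 1e-12

    def test_hydrogens_ignored_by_default(self):
        symbols = ["C", "C", "O", "H", "H"]
        coords = np.array([[0, 0, 0], [1.5, 0, 0], [0, 1.4, 0], [2, 2, 2], [-2, 1, 0]])
        a = Structure(symbols, coords)
        perturbed = coords.copy()
        perturbed[3:] += 1.0  # move only hydrogens
        b = Structure(symbols, perturbed)
        assert minimal_rmsd(a, b).rmsd == pytest.approx(0.0, abs=1e-12)
        assert minimal_rmsd(a, b, exclude_hydrogens=False).rmsd > 0.1

    def test_too_few_heavy_atoms_raises(self):
        symbols = ["C", "H", "H", "H", "H"]
        coords = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]], float)
        a = Structure(symbols, coords)
        b = Structure(symbols, coords + 0.1)
        with pytest.raises(ValueError, match="survive"):
            minimal_rmsd(a, b)

    def test_known_torsion_matches_oracle(self, base_complex, rng):
        """Ligand-part pair differing by a known distortion agrees with the
        rotation-grid-search oracle."""
        structure = base_complex.structure
        lig = [1, 2, 3, 4, 5]  # 5 heavy ligand atoms
        P = structure.coords[lig]
        Q = P.copy()
        Q[-1] += np.array([0.4, -0.3, 0.5])
        R, t = random_rigid_motion(rng)
        a = Structure(["C"] * 5, P)
        b = Structure(["C"] * 5, Q @ R.T + t)
        assert minimal_rmsd(a, b).rmsd == pytest.approx(grid_search_rmsd(P, Q), abs=1e-3)


class TestRMSDProfile:
    def test_identical_copies_all_zero(self, base_complex):
        base = base_complex.structure
        members = [
            Structure(list(base.symbols), base.coords.copy(),
                      energy=-5.0 + 0.001 * i, energy_unit="hartree")
            for i in range(4)
        ]
        ens = ConformerEnsemble(members=members)
        profile = rmsd_profile(ens, base_complex.spec)
        assert np.allclose(profile[["rmsd_whole", "rmsd_ligand", "rmsd_substrate"]], 0.0,
                           atol=1e-9)

    def test_reference_is_lowest_energy_member(self, base_complex, rng):
        base = base_complex.structure
        coords2 = base.coords + rng.normal(scale=0.1, size=base.coords.shape)
        members = [
            Structure(list(base.symbols), base.coords.copy(), energy=-4.0,
                      energy_unit="hartree"),
            Structure(list(base.symbols), coords2, energy=-5.0, energy_unit="hartree"),
        ]
        ens = ConformerEnsemble(members=members)
        profile = rmsd_profile(ens, base_complex.spec)
        assert profile.attrs["reference_index"] == 1
        row = profile.iloc[1]
        assert row["rmsd_whole"] == pytest.approx(0.0, abs=1e-12)
        assert row["delta_e_kj"] == 0.0
        assert profile.iloc[0]["delta_e_kj"] > 0

    def test_flexible_ligand_rigid_substrate_ordering(self, small_ensemble, base_complex):
        """sigma_ligand >> sigma_substrate must show up as median ligand-part
        rmsd above median substrate-part rmsd."""
        ens, _, _ = small_ensemble
        profile = rmsd_profile(ens, base_complex.spec)
        assert profile["rmsd_ligand"].median() > profile["rmsd_substrate"].median()

    def test_missing_energy_raises(self, base_complex):
        base = base_complex.structure
        members = [Structure(list(base.symbols), base.coords.copy()) for _ in range(2)]
        ens = ConformerEnsemble(members=members)
        with pytest.raises(ValueError, match="no energy"):
            rmsd_profile(ens, base_complex.spec)


class TestSyntheticDistortionScale:
    def test_mean_part_rmsd_matches_monte_carlo_expectation(self, generator_config,
                                                            base_complex):
        """Ensemble-mean ligand/substrate part RMSDs agree with a Monte-Carlo
        oracle that simulates the generator's displacement model through
        scipy's independent superposition, within 3 combined standard errors."""
        from dataclasses import replace

        cfg = replace(generator_config, n_conformers=100)
        ens, _, _ = make_ensemble(cfg, base_complex, stream=9)
        profile = rmsd_profile(ens, base_complex.spec)
        ref = profile.attrs["reference_index"]

        from catflex.complexes import fragment_indices
        from catflex.synthetic import _role_sigmas

        sig = _role_sigmas(base_complex, cfg)
        lig_idx, sub_idx = fragment_indices(base_complex.spec)
        heavy = set(base_complex.structure.heavy_atom_indices())
        mc_rng = np.random.default_rng(5150)
        n_ref, n_mem = 80, 30  # replicate ensembles: one shared reference each
        for part_idx, col in [(lig_idx, "rmsd_ligand"), (sub_idx, "rmsd_substrate")]:
            idx = np.array([i for i in part_idx if i in heavy])
            base_part = base_complex.structure.coords[idx]
            s = sig[idx][:, None]
            draws = np.empty((n_ref, n_mem))
            for i in range(n_ref):
                d_ref = mc_rng.normal(size=base_part.shape) * s
                for j in range(n_mem):
                    d_mem = mc_rng.normal(size=base_part.shape) * s
                    draws[i, j] = scipy_align_rmsd(base_part + d_ref, base_part + d_mem)
            measured = profile.loc[profile["member"] != ref, col].to_numpy()
            # the profile mean is conditional on its single reference draw, so
            # its sampling variance carries a between-reference component
            var_between = draws.mean(axis=1).var()
            var_within = draws.var(axis=1).mean()
            var_measured = var_between + var_within / len(measured)
            var_mc = var_between / n_ref + var_within / draws.size
            se = np.sqrt(var_measured + var_mc)
            assert abs(measured.mean() - draws.mean()) <= 3 * se
        # absolute scales of the emulated system: rigid substrate, mobile ligand
        assert profile["rmsd_substrate"].mean() < 0.2
        assert profile["rmsd_ligand"].mean() > 0.5
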