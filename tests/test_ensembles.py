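import numpy as np
import pytest

from catflex.ensembles import (
    EnsembleSummary,
    apply_retention_filters,
    deduplicate,
    energy_window_filter,
    relative_energies,
    summarize_ensemble,
)
from catflex.structures import ConformerEnsemble, Structure
from catflex.synthetic import (
    GeneratorConfig,
    flip_substrate_quadrant,
    make_complex_template,
    make_dedup_fixture,
    make_ensemble,
    mirror_structure,
)
from catflex.units import HARTREE_TO_KJ_PER_MOL


def _ensemble_at(delta_kcal, base_hartree=-5.0):
    """Members offset from the minimum by the given kcal/mol values."""
    members = [
        Structure(
            ["C", "O", "N"],
            np.eye(3),
            energy=base_hartree + dk / 627.509474,
            energy_unit="hartree",
            label=f"m{i}",
        )
        for i, dk in enumerate(delta_kcal)
    ]
    baseline = Structure(["C", "O", "N"], np.eye(3), energy=base_hartree,
                         energy_unit="hartree")
    return ConformerEnsemble(members=members, baseline=baseline)


class TestRelativeEnergies:
    def test_hartree_difference_converts_to_kj(self):
        ens = _ensemble_at([0.0])
        ens.members[0].energy = -5.010000
        de = relative_energies(ens)
        assert de[0] == pytest.approx(-0.01 * HARTREE_TO_KJ_PER_MOL, abs=1e-6)
        assert de[0] == pytest.approx(-26.255, abs=1e-3)

    def test_member_equal_to_baseline_is_zero(self):
        ens = _ensemble_at([0.0])
        assert relative_energies(ens)[0] == pytest.approx(0.0, abs=1e-9)

    def test_generator_offsets_recovered(self, generator_config, base_complex):
        ens, _, truth = make_ensemble(generator_config, base_complex, stream=3)
        de = relative_energies(ens)
        expected = truth["delta_e_kj"] - generator_config.baseline_offset_kj
        assert np.allclose(de, expected, atol=1e-6)

    def test_missing_baseline_raises(self):
        ens = _ensemble_at([0.0])
        ens.baseline = None
        with pytest.raises(ValueError, match="baseline"):
            relative_energies(ens)


class TestEnergyWindow:
    def test_six_kcal_window_drops_outliers(self):
        ens = _ensemble_at([0.0, 3.0, 7.0])
        kept = energy_window_filter(ens, window_kcal=6.0)
        assert len(kept) == 2
        assert [m.label for m in kept.members] == ["m0", "m1"]

    def test_all_within_window_is_identity(self):
        ens = _ensemble_at([0.0, 1.0, 5.9])
        assert len(energy_window_filter(ens, 6.0)) == 3

    def test_zero_window_keeps_only_minimum(self):
        ens = _ensemble_at([0.0, 0.5, 2.0])
        kept = energy_window_filter(ens, 0.0)
        assert [m.label for m in kept.members] == ["m0"]

    def test_sequential_windows_equal_min_window(self):
        ens = _ensemble_at([0.0, 1.5, 3.5, 5.0, 8.0])
        twice = energy_window_filter(energy_window_filter(ens, 5.5), 4.0)
        once = energy_window_filter(ens, 4.0)
        assert [m.label for m in twice.members] == [m.label for m in once.members]


class TestDeduplicate:
    def test_exact_copies_collapse_to_one(self, base_complex):
        base = base_complex.structure
        members = [
            Structure(list(base.symbols), base.coords.copy(), energy=-5.0,
                      energy_unit="hartree")
            for _ in range(5)
        ]
        ens = ConformerEnsemble(members=members)
        assert len(deduplicate(ens)) == 1

    def test_distant_pair_stays_distinct(self, base_complex, rng):
        base = base_complex.structure
        far = base.coords.copy()
        far[base_complex.flexible_ligand_indices, :] += rng.normal(
            scale=2.0, size=(len(base_complex.flexible_ligand_indices), 3)
        )
        members = [
            Structure(list(base.symbols), base.coords.copy(), energy=-5.0,
                      energy_unit="hartree"),
            Structure(list(base.symbols), far, energy=-5.0, energy_unit="hartree"),
        ]
        ens = ConformerEnsemble(members=members)
        assert len(deduplicate(ens, rmsd_tol=0.25)) == 2

    def test_planted_well_count_recovered(self, generator_config):
        from dataclasses import replace

        cfg = replace(generator_config, n_wells=6, replicates_per_well=5)
        ens, truth = make_dedup_fixture(cfg)
        assert len(ens) == 30
        assert len(deduplicate(ens)) == truth["n_wells"] == 6

    def test_idempotent(self, generator_config):
        ens, _ = make_dedup_fixture(generator_config)
        once = deduplicate(ens)
        twice = deduplicate(once)
        assert [id(m) for m in twice.members] == [id(m) for m in once.members]

    def test_output_sorted_by_energy(self, generator_config):
        ens, _ = make_dedup_fixture(generator_config)
        out = deduplicate(ens)
        e = out.energies_in("kJ/mol")
        assert np.all(np.diff(e) >= 0)

    def test_nonpositive_tolerances_rejected(self, generator_config):
        ens, _ = make_dedup_fixture(generator_config)
        with pytest.raises(ValueError, match="positive"):
            deduplicate(ens, rmsd_tol=0.0)
        with pytest.raises(ValueError, match="positive"):
            deduplicate(ens, energy_tol_kj=-1.0)


class TestRetentionFilters:
    def _planted_ensemble(self, generator_config, n_mirrored=0, n_flipped=0):
        sc = make_complex_template(generator_config, coordination_mode="major1")
        ens, _, _ = make_ensemble(generator_config, sc, stream=4)
        members = list(ens.members)
        for i in range(n_mirrored):
            members[i] = mirror_structure(members[i])
        for i in range(n_mirrored, n_mirrored + n_flipped):
            members[i] = flip_substrate_quadrant(members[i], sc)
        return ens.replace_members(members), sc

    def test_clean_ensemble_is_identity(self, generator_config):
        ens, sc = self._planted_ensemble(generator_config)
        kept, log = apply_retention_filters(
            ens, sc.template, sc.spec, sc.anchor_indices, sc.expected_chirality_sign
        )
        assert len(kept) == len(ens)
        assert log == []

    def test_mirrored_member_removed_for_chirality(self, generator_config):
        ens, sc = self._planted_ensemble(generator_config, n_mirrored=1)
        kept, log = apply_retention_filters(
            ens, sc.template, sc.spec, sc.anchor_indices, sc.expected_chirality_sign
        )
        assert len(kept) == len(ens) - 1
        assert [r.reason for r in log] == ["chirality"]
        assert log[0].member_index == 0

    def test_two_rotated_members_removed_for_coordination(self, generator_config):
        """Conformers whose substrate migrated to another quadrant are culled,
        mirroring the removal of rotated conformers from a substrate-bound set."""
        ens, sc = self._planted_ensemble(generator_config, n_flipped=2)
        kept, log = apply_retention_filters(
            ens, sc.template, sc.spec, sc.anchor_indices, sc.expected_chirality_sign
        )
        assert len(kept) == len(ens) - 2
        reasons = [r.reason for r in log]
        assert reasons == ["coordination", "coordination"]
        assert all("minor" in r.detail for r in log)

    def test_ambiguous_member_flagged_not_removed(self, generator_config):
        ens, sc = self._planted_ensemble(generator_config)
        ref = sc.anchor_indices[2]
        coords = sc.structure.coords.copy()
        coords[ref] = [0.0, 0.0, 1.6]
        members = list(ens.members)
        members[0] = Structure(list(sc.structure.symbols), coords,
                               energy=members[0].energy, energy_unit="hartree")
        ens2 = ens.replace_members(members)
        kept, log = apply_retention_filters(
            ens2, sc.template, sc.spec, sc.anchor_indices, sc.expected_chirality_sign
        )
        assert len(kept) == len(ens2)  # retained
        assert [r.reason for r in log] == ["flagged:ambiguous-coordination"]
        assert not log[0].removed


class TestSummary:
    def test_counts_and_invariant(self, generator_config, base_complex):
        ens, _, _ = make_ensemble(generator_config, base_complex, stream=5)
        distinct = deduplicate(ens)
        summary = summarize_ensemble(ens, distinct, base_complex.spec)
        assert summary.n_distinct_dft <= summary.n_crest
        assert summary.delta_e_range_kj[0] <= summary.delta_e_range_kj[1]
        assert summary.rmsd_range_ligand[1] >= summary.rmsd_range_substrate[1]

    def test_distinct_exceeding_input_rejected(self):
        with pytest.raises(ValueError):
            EnsembleSummary("L1", "S", "major1", n_crest=3, n_distinct_dft=4,
                            delta_e_range_kj=(0.0, 1.0))
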