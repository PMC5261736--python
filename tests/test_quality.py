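"""Fnat, RMSD measures, CAPRI classification and quality weights."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import dockpot as dp
from conftest import bead_structure


def _brute_force_contacts(s, cutoff):
    out = set()
    rk = s.receptor.residue_keys()
    lk = s.ligand.residue_keys()
    for i in range(len(s.receptor)):
        if not s.receptor.heavy[i]:
            continue
        for j in range(len(s.ligand)):
            if not s.ligand.heavy[j]:
                continue
            d = np.linalg.norm(s.receptor.coords[i] - s.ligand.coords[j])
            if d < cutoff:
                out.add((rk[i], lk[j]))
    return out


class TestInterfaceContacts:
    @pytest.mark.parametrize("gap,expect", [(4.9, 1), (5.1, 0)])
    def test_single_pair_cutoff_boundary(self, gap, expect):
        s = bead_structure([[0, 0, 0]], [[gap, 0, 0]])
        assert len(dp.interface_contacts(s, cutoff=5.0)) == expect

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(4)
        s = bead_structure(rng.uniform(0, 12, (25, 3)),
                           rng.uniform(3, 15, (25, 3)))
        assert dp.interface_contacts(s, 5.0) == _brute_force_contacts(s, 5.0)


class TestFnat:
    def test_native_vs_itself_is_one(self, native):
        assert dp.compute_fnat(native, native) == 1.0

    def test_far_translated_ligand_is_zero(self, native):
        far = native.transform_ligand(np.eye(3), np.array([50.0, 0, 0]))
        assert dp.compute_fnat(far, native) == 0.0

    def test_half_preserved_contacts(self):
        """Decoy keeps 3 of 6 native contacts -> Fnat = 0.5."""
        rec = [[i * 10.0, 0, 0] for i in range(6)]
        lig = [[i * 10.0, 4.0, 0] for i in range(6)]  # 6 contacts at 4 A
        native = bead_structure(rec, lig)
        assert len(dp.interface_contacts(native, 5.0)) == 6
        decoy_lig = [r[:] for r in lig]
        for i in range(3):
            decoy_lig[i][1] += 20.0  # break 3 contacts
        decoy = bead_structure(rec, decoy_lig)
        assert dp.compute_fnat(decoy, native, 5.0) == 0.5

    def test_contactless_native_raises(self):
        native = bead_structure([[0, 0, 0]], [[100.0, 0, 0]])
        with pytest.raises(dp.UndefinedQualityError):
            dp.compute_fnat(native, native)


class TestSuperpose:
    def test_identity_on_equal_sets(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(20, 3))
        rot, trans, rmsd = dp.superpose_rmsd(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(rot, np.eye(3), atol=1e-8)

    def test_recovers_known_rigid_motion(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 3))
        r_true = Rotation.from_euler("xyz", [20, -40, 75],
                                     degrees=True).as_matrix()
        moved = x @ r_true.T + np.array([3.0, -2.0, 7.0])
        rot, trans, rmsd = dp.superpose_rmsd(moved, x)
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(rot, r_true.T, atol=1e-8)

    def test_noisy_copy_rmsd_band_and_optimality(self):
        """sigma=0.1 noise on 100 atoms: rmsd in [0.05, 0.2], and the
        superposed rmsd never exceeds the unsuperposed one."""
        rng = np.random.default_rng(2)
        x = rng.normal(scale=5.0, size=(100, 3))
        y = x + rng.normal(scale=0.1, size=x.shape)
        # displace to make the unsuperposed comparison meaningful
        y_moved = y @ Rotation.from_euler("z", 10, degrees=True).as_matrix().T \
            + np.array([1.0, 0, 0])
        _, _, rmsd = dp.superpose_rmsd(y_moved, x)
        raw = np.sqrt(np.mean(np.sum((y_moved - x) ** 2, axis=1)))
        assert 0.05 <= rmsd <= 0.2
        assert rmsd <= raw

    def test_count_mismatch_raises(self):
        with pytest.raises(ValueError):
            dp.superpose_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


class TestLrmsd:
    def test_zero_for_native(self, native):
        assert dp.compute_lrmsd(native, native) == pytest.approx(0, abs=1e-8)

    def test_pure_translation_equals_magnitude(self, native):
        decoy = native.transform_ligand(np.eye(3), np.array([0, 3.0, 0]))
        assert dp.compute_lrmsd(decoy, native) == pytest.approx(3.0, abs=1e-8)

    def test_matches_direct_enumeration_oracle(self, native):
        """Independent oracle: superpose receptors with scipy, then RMSD."""
        rng = np.random.default_rng(3)
        rot = Rotation.random(rng=rng).as_matrix()
        center = native.ligand.coords.mean(axis=0)
        moved = (native.ligand.coords - center) @ rot.T + center + [2.0, 1, 0]
        lig = native.ligand.select(np.ones(len(native.ligand), bool))
        lig.coords = moved
        decoy = native.with_ligand(lig)
        # whole-decoy global motion must not change Lrmsd
        g = Rotation.from_euler("xyz", [15, 25, -30], degrees=True).as_matrix()
        shifted = dp.TypedStructure(
            receptor=decoy.receptor.transformed(g, np.array([4.0, -1, 2])),
            ligand=decoy.ligand.transformed(g, np.array([4.0, -1, 2])),
            table=decoy.table)
        est, _ = Rotation.align_vectors(
            native.receptor.coords - native.receptor.coords.mean(axis=0),
            decoy.receptor.coords - decoy.receptor.coords.mean(axis=0))
        oracle_moved = est.as_matrix() @ (
            decoy.ligand.coords - decoy.receptor.coords.mean(axis=0)).T
        oracle_moved = oracle_moved.T + native.receptor.coords.mean(axis=0)
        oracle = np.sqrt(np.mean(np.sum(
            (oracle_moved - native.ligand.coords) ** 2, axis=1)))
        assert dp.compute_lrmsd(decoy, native) == pytest.approx(oracle,
                                                                rel=1e-6)
        assert dp.compute_lrmsd(shifted, native) == pytest.approx(
            dp.compute_lrmsd(decoy, native), abs=1e-6)


class TestIrmsd:
    def test_zero_for_native(self, native):
        assert dp.compute_irmsd(native, native) == pytest.approx(0, abs=1e-8)

    def test_translation_bounded_and_monotone(self, native):
        values = []
        for mag in (0.5, 1.0, 2.0):
            decoy = native.transform_ligand(np.eye(3),
                                            np.array([0.0, 0.0, mag]))
            v = dp.compute_irmsd(decoy, native)
            assert 0 < v <= mag
            values.append(v)
        assert values == sorted(values)

    def test_interface_grows_with_cutoff(self, native):
        from dockpot.quality import _interface_residues
        r5, l5 = _interface_residues(native, 5.0)
        r10, l10 = _interface_residues(native, 10.0)
        assert r5 <= r10 and l5 <= l10

    def test_empty_interface_raises(self):
        native = bead_structure([[0, 0, 0], [2, 0, 0], [0, 2, 0]],
                                [[100, 0, 0], [102, 0, 0], [100, 2, 0]])
        with pytest.raises(dp.UndefinedQualityError):
            dp.compute_irmsd(native, native)


class TestCapriClassify:
    @pytest.mark.parametrize("fnat,irmsd,stars", [
        (0.6, 0.9, 3),      # high
        (0.05, 0.5, 0),     # fails the 0.1 Fnat floor
        (0.35, 1.5, 2),     # medium
        (0.15, 3.0, 1),     # acceptable
        (0.4, 3.0, 1),      # high Fnat, loose Irmsd: still one star
        (0.9, 5.0, 0),      # Irmsd too large for any class
    ])
    def test_printed_threshold_examples(self, fnat, irmsd, stars):
        assert dp.capri_classify(fnat, irmsd) == stars

    @pytest.mark.parametrize("fnat,irmsd,stars", [
        (0.5, 0.5, 2),      # Fnat exactly 0.5: strict, drops to medium
        (0.6, 1.0, 2),      # Irmsd exactly 1.0: strict
        (0.3, 1.5, 1),      # Fnat exactly 0.3: strict, drops to acceptable
        (0.1, 3.0, 0),      # Fnat exactly 0.1: strict, no star
        (0.2, 4.0, 0),      # Irmsd exactly 4.0: strict
    ])
    def test_boundaries_are_strict(self, fnat, irmsd, stars):
        assert dp.capri_classify(fnat, irmsd) == stars


class TestQualityWeights:
    def _records(self, stars):
        return [dp.QualityRecord(fnat=0.0, lrmsd=0.0, irmsd=0.0, stars=s)
                for s in stars]

    def test_stars_normalised_per_complex(self):
        w, usable = dp.make_quality_weights(self._records([1, 1, 2]),
                                            "stars")
        assert usable
        assert np.allclose(w, [0.25, 0.25, 0.5])

    def test_native_only_scheme(self):
        recs = self._records([0, 0, 3])
        recs[1].is_native = True
        w, usable = dp.make_quality_weights(recs, "native-only")
        assert usable
        assert np.allclose(w, [0, 1, 0])

    def test_all_incorrect_complex_flagged_unusable(self):
        w, usable = dp.make_quality_weights(self._records([0, 0, 0]),
                                            "stars")
        assert not usable
        assert np.all(w == 0)
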