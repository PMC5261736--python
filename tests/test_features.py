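"""Feature vectors: step counts, r^-8/r^-6 sums, SASA and buried areas."""

import numpy as np
import pytest

import dockpot as dp
from dockpot.features import _sphere_points
from conftest import bead_structure


def _random_fixture(n, rng, n_types=4, spread=14.0):
    return bead_structure(
        rng.uniform(0, spread, (n, 3)), rng.uniform(2, spread + 4, (n, 3)),
        rng.integers(n_types, size=n), rng.integers(n_types, size=n),
        n_types=n_types)


def _brute_step(s, edges):
    lam = s.table.n_types
    nbins = len(edges) - 1
    out = np.zeros(nbins * dp.n_pair_types(lam))
    for i in range(len(s.receptor)):
        for j in range(len(s.ligand)):
            d = np.linalg.norm(s.receptor.coords[i] - s.ligand.coords[j])
            for b in range(nbins):
                if edges[b] <= d < edges[b + 1]:
                    p = dp.canonical_pair_index(int(s.receptor.types[i]),
                                                int(s.ligand.types[j]), lam)
                    out[p * nbins + b] += 1
    return out


def _brute_vdw(s, floor, cutoff):
    lam = s.table.n_types
    npairs = dp.n_pair_types(lam)
    out = np.zeros(2 * npairs)
    for i in range(len(s.receptor)):
        for j in range(len(s.ligand)):
            d = np.linalg.norm(s.receptor.coords[i] - s.ligand.coords[j])
            if d >= cutoff:
                continue
            r = max(d, floor)
            p = dp.canonical_pair_index(int(s.receptor.types[i]),
                                        int(s.ligand.types[j]), lam)
            out[p] += r ** -8
            out[npairs + p] += r ** -6
    return out


class TestStepFeatures:
    def test_single_pair_lands_in_first_bin(self):
        s = bead_structure([[0, 0, 0]], [[3.0, 0, 0]])
        v = dp.step_features(s, [0, 4, 6])
        assert v[0] == 1  # (pair 0, bin 0)
        assert v.sum() == 1

    def test_no_pairs_in_range_gives_zero_vector(self):
        s = bead_structure([[0, 0, 0]], [[25.0, 0, 0]])
        assert not np.any(dp.step_features(s, [0, 10]))

    def test_edge_distance_belongs_to_upper_bin(self):
        s = bead_structure([[0, 0, 0]], [[4.0, 0, 0]])
        v = dp.step_features(s, [0, 4, 6])
        assert v[0] == 0 and v[1] == 1

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(21)
        s = _random_fixture(100, rng)
        edges = [0, 4, 6, 10]
        assert np.array_equal(dp.step_features(s, edges),
                              _brute_step(s, edges))

    def test_invariant_under_atom_permutation(self):
        rng = np.random.default_rng(22)
        s = _random_fixture(40, rng)
        perm = rng.permutation(40)
        s2 = dp.TypedStructure(receptor=s.receptor.select(perm),
                               ligand=s.ligand, table=s.table)
        assert np.array_equal(dp.step_features(s, [0, 4, 6]),
                              dp.step_features(s2, [0, 4, 6]))


class TestVdwFeatures:
    def test_single_pair_at_two_angstrom(self):
        s = bead_structure([[0, 0, 0]], [[2.0, 0, 0]])
        v = dp.vdw_features(s)
        npairs = dp.n_pair_types(4)
        assert v[0] == pytest.approx(2.0 ** -8)
        assert v[npairs] == pytest.approx(2.0 ** -6)

    def test_clash_shift_to_two_angstrom(self):
        """A 1 A clash contributes exactly as a 2 A contact."""
        near = bead_structure([[0, 0, 0]], [[1.0, 0, 0]])
        at_floor = bead_structure([[0, 0, 0]], [[2.0, 0, 0]])
        assert np.allclose(dp.vdw_features(near), dp.vdw_features(at_floor))

    def test_matches_brute_force_to_1e10_relative(self):
        rng = np.random.default_rng(23)
        s = _random_fixture(100, rng)
        got = dp.vdw_features(s, 2.0, 12.0)
        ref = _brute_vdw(s, 2.0, 12.0)
        nz = ref != 0
        assert np.allclose(got[nz], ref[nz], rtol=1e-10)
        assert np.array_equal(got == 0, ref == 0)

    def test_invariant_under_global_rigid_motion(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(24)
        s = _random_fixture(40, rng)
        rot = Rotation.random(rng=rng).as_matrix()
        t = np.array([5.0, -3.0, 2.0])
        s2 = dp.TypedStructure(receptor=s.receptor.transformed(rot, t),
                               ligand=s.ligand.transformed(rot, t),
                               table=s.table)
        assert np.allclose(dp.vdw_features(s), dp.vdw_features(s2),
                           rtol=1e-9)


class TestSasa:
    def test_isolated_sphere_matches_analytic_area(self):
        area = dp.sasa(np.zeros((1, 3)), np.array([1.8]), probe=1.4)
        assert area[0] == pytest.approx(4 * np.pi * 3.2 ** 2, rel=0.01)

    def test_far_apart_spheres_keep_isolated_areas(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        area = dp.sasa(coords, np.array([1.8, 1.2]), probe=1.4)
        assert area[0] == pytest.approx(4 * np.pi * 3.2 ** 2, rel=0.01)
        assert area[1] == pytest.approx(4 * np.pi * 2.6 ** 2, rel=0.01)

    def test_overlapping_pair_matches_refined_quadrature(self):
        """Coarse quadrature within 2% of a much finer one."""
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        radii = np.array([1.8, 1.8])
        coarse = dp.sasa(coords, radii, 1.4, n_points=960)
        fine = dp.sasa(coords, radii, 1.4, n_points=20000)
        assert np.allclose(coarse, fine, rtol=0.02)

    def test_quadrature_points_are_unit_and_deterministic(self):
        pts = _sphere_points(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        assert np.array_equal(pts, _sphere_points(960))


class TestBsaFeatures:
    def test_far_apart_partners_give_zero_vector(self):
        rng = np.random.default_rng(25)
        s = bead_structure(rng.uniform(0, 8, (10, 3)),
                           rng.uniform(100, 108, (10, 3)),
                           rng.integers(4, size=10), rng.integers(4, size=10))
        assert np.allclose(dp.bsa_features(s, n_points=400), 0.0)

    def test_burial_is_local_to_contacting_types(self):
        s = bead_structure([[0, 0, 0], [40, 0, 0]], [[3.0, 0, 0]],
                           rec_types=[1, 2], lig_types=[3])
        v = dp.bsa_features(s, n_points=960)
        # only types 1 (receptor contact) and 3 (ligand) are buried
        assert v[1] > 0 and v[3] > 0
        assert v[0] == 0 and v[2] == 0

    def test_total_equals_global_bsa_identity(self, native):
        """Sum over types == SASA_R + SASA_L - SASA_complex."""
        v = dp.bsa_features(native, n_points=400)
        r = np.full(len(native.receptor), 1.8)
        l = np.full(len(native.ligand), 1.8)
        sr = dp.sasa(native.receptor.coords, r, 1.4, 400).sum()
        sl = dp.sasa(native.ligand.coords, l, 1.4, 400).sum()
        sc = dp.sasa(np.vstack([native.receptor.coords,
                                native.ligand.coords]),
                     np.concatenate([r, l]), 1.4, 400).sum()
        assert v.sum() == pytest.approx(sr + sl - sc, rel=1e-9)


class TestFeatureGrid:
    def test_shape_for_step_form(self, decoy_set, bead_table4):
        decoys, _ = decoy_set
        grid = dp.build_feature_grid(decoys[:10], dp.StepForm((0, 4, 6)))
        assert grid.matrix.shape == (10, 2 * dp.n_pair_types(4))

    def test_save_load_round_trip_bit_identical(self, tmp_path, decoy_set):
        decoys, _ = decoy_set
        grid = dp.build_feature_grid(decoys[:10], dp.StepForm((0, 4, 6)))
        path = tmp_path / "grid.npz"
        grid.save(path)
        back = dp.FeatureGrid.load(path)
        assert np.array_equal(grid.matrix, back.matrix)
        assert back.table_hash == grid.table_hash
        assert back.decoy_ids == grid.decoy_ids

    def test_append_with_different_table_raises(self, decoy_set):
        decoys, _ = decoy_set
        grid = dp.build_feature_grid(decoys[:5], dp.StepForm((0, 4, 6)))
        other = bead_structure([[0, 0, 0]], [[3.0, 0, 0]], n_types=5)
        grid5 = dp.build_feature_grid([other], dp.StepForm((0, 4, 6)))
        with pytest.raises(dp.LayoutError):
            grid.append(grid5)

    def test_rescoring_from_grid_row_is_stable(self, decoy_set):
        decoys, _ = decoy_set
        form = dp.StepForm((0, 4, 6))
        grid = dp.build_feature_grid(decoys[:5], form)
        again = np.vstack([dp.compute_features(d, form) for d in decoys[:5]])
        assert np.array_equal(grid.matrix, again)
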