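import numpy as np
import pytest

from domaindyn import geometry
from domaindyn.geometry import (SeriesPerFrame, com_distance, center_of_mass,
                                combine_fes, fes_2d, fit_equilibration,
                                radius_of_gyration, rmsd, site_distance, superpose)
from tests.conftest import toy_ensemble

rng = np.random.default_rng(42)


def brute_com(coords, masses, sel):
    """Independent COM arithmetic: explicit python loop."""
    out = []
    for frame in coords:
        acc = np.zeros(3)
        for i in sel:
            acc += masses[i] * frame[i]
        out.append(acc / sum(masses[i] for i in sel))
    return np.array(out)


class TestCenterOfMass:
    def test_unit_masses_midpoint(self):
        ens = toy_ensemble([[[0, 0, 0], [2, 0, 0]]])
        np.testing.assert_allclose(center_of_mass(ens, [0, 1]).values, [[1, 0, 0]])

    def test_mass_weighting(self):
        ens = toy_ensemble([[[0, 0, 0], [4, 0, 0]]], masses=[1, 3])
        np.testing.assert_allclose(center_of_mass(ens, [0, 1]).values, [[3, 0, 0]])

    def test_single_atom_is_own_com(self):
        ens = toy_ensemble([[[1.0, 2.0, 3.0]]])
        np.testing.assert_allclose(center_of_mass(ens, [0]).values, [[1, 2, 3]])

    def test_empty_selection_raises(self):
        ens = toy_ensemble([[[0, 0, 0]]])
        with pytest.raises(ValueError, match="empty"):
            center_of_mass(ens, [])


class TestComDistance:
    def test_3_4_5(self):
        ens = toy_ensemble([[[0, 0, 0], [3, 4, 0]]])
        np.testing.assert_allclose(com_distance(ens, [0], [1]).values, [5.0])

    def test_identical_selections_zero(self):
        ens = toy_ensemble(rng.normal(size=(4, 6, 3)))
        np.testing.assert_allclose(com_distance(ens, [0, 1, 2], [0, 1, 2]).values, 0, atol=1e-14)

    def test_symmetric(self):
        ens = toy_ensemble(rng.normal(size=(3, 8, 3)), masses=rng.uniform(1, 5, 8))
        a, b = [0, 2, 4], [1, 3, 5, 7]
        np.testing.assert_allclose(com_distance(ens, a, b).values,
                                   com_distance(ens, b, a).values)

    def test_matches_brute_force_on_random_selections(self):
        ens = toy_ensemble(rng.normal(size=(5, 10, 3)), masses=rng.uniform(1, 3, 10))
        a, b = [0, 3, 5, 9], [1, 2, 8]
        expect = np.linalg.norm(
            brute_com(ens.coords, ens.masses, a) - brute_com(ens.coords, ens.masses, b),
            axis=1)
        np.testing.assert_allclose(com_distance(ens, a, b).values, expect)


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        ens = toy_ensemble([[[5, 5, 5]]])
        np.testing.assert_allclose(radius_of_gyration(ens, [0]).values, [0.0])

    def test_two_unit_masses_2nm_apart_is_1nm(self):
        ens = toy_ensemble([[[0, 0, 0], [2, 0, 0]]])
        np.testing.assert_allclose(radius_of_gyration(ens, [0, 1]).values, [1.0])

    def test_matches_brute_force_formula(self):
        coords = rng.normal(size=(3, 50, 3))
        masses = rng.uniform(1, 14, 50)
        ens = toy_ensemble(coords, masses=masses)
        sel = list(range(50))
        for f in range(3):
            com = sum(masses[i] * coords[f, i] for i in sel) / masses.sum()
            rg2 = sum(masses[i] * np.dot(coords[f, i] - com, coords[f, i] - com)
                      for i in sel) / masses.sum()
            np.testing.assert_allclose(radius_of_gyration(ens, sel).values[f],
                                       np.sqrt(rg2))

    def test_invariant_under_rigid_transform(self):
        coords = rng.normal(size=(2, 20, 3))
        ens = toy_ensemble(coords)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved = toy_ensemble(coords @ R.T + np.array([3.0, -1.0, 2.0]))
        np.testing.assert_allclose(radius_of_gyration(ens, range(20)).values,
                                   radius_of_gyration(moved, range(20)).values)


class TestSuperposeRmsd:
    def _pair(self, n=12):
        ref = toy_ensemble(rng.normal(size=(1, n, 3)))
        return ref

    def test_identity_when_already_aligned(self):
        ref = self._pair()
        out = superpose(ref, ref, np.arange(12))
        np.testing.assert_allclose(out.coords, ref.coords, atol=1e-12)

    def test_rotated_copy_recovers_zero_rmsd(self):
        ref = self._pair()
        R = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])  # 90 deg about z
        moved = toy_ensemble(ref.coords[0] @ R.T + 2.0)
        aligned = superpose(moved, ref, np.arange(12))
        assert rmsd(aligned, ref, np.arange(12)).values[0] < 1e-10

    def test_alignment_never_increases_rmsd(self):
        ref = self._pair()
        for _ in range(10):
            moved = toy_ensemble(ref.coords[0] + rng.normal(0, 0.3, (12, 3)))
            before = rmsd(moved, ref, np.arange(12)).values[0]
            after = rmsd(superpose(moved, ref, np.arange(12)), ref, np.arange(12)).values[0]
            assert after <= before + 1e-12

    def test_beats_random_rotation_search_on_toy(self):
        # brute-force search over many random rotations cannot beat Kabsch
        ref = toy_ensemble(rng.normal(size=(1, 4, 3)))
        moved = toy_ensemble(ref.coords[0] + rng.normal(0, 0.5, (4, 3)))
        kab = rmsd(superpose(moved, ref, np.arange(4)), ref, np.arange(4)).values[0]
        P = moved.coords[0] - moved.coords[0].mean(0)
        Q = ref.coords[0] - ref.coords[0].mean(0)
        best = np.inf
        search = np.random.default_rng(0)
        for _ in range(2000):
            A = search.normal(size=(3, 3))
            Rr, _ = np.linalg.qr(A)
            if np.linalg.det(Rr) < 0:
                Rr[:, 0] *= -1
            best = min(best, np.sqrt((((P @ Rr) - Q) ** 2).sum(1).mean()))
        assert kab <= best + 1e-9

    def test_superpose_idempotent(self):
        ref = self._pair()
        moved = toy_ensemble(ref.coords[0] @ np.eye(3) + rng.normal(0, 0.2, (12, 3)))
        once = superpose(moved, ref, np.arange(12))
        twice = superpose(once, ref, np.arange(12))
        np.testing.assert_allclose(twice.coords, once.coords, atol=1e-9)

    def test_degenerate_fit_rejected(self):
        ref = toy_ensemble(np.array([[[0, 0, 0], [1, 0, 0], [2, 0, 0.0]]]))
        with pytest.raises(ValueError, match="degenerate|collinear"):
            superpose(ref, ref, np.arange(3))

    def test_translation_without_refit_gives_shift(self):
        ref = self._pair()
        moved = toy_ensemble(ref.coords[0] + np.array([1.0, 0, 0]))
        np.testing.assert_allclose(rmsd(moved, ref, np.arange(12)).values, [1.0])

    def test_hand_computed_5_atom_rmsd(self):
        ref = toy_ensemble(np.zeros((1, 5, 3)))
        disp = np.array([[0.1, 0, 0], [0, 0.2, 0], [0, 0, 0.2], [0.3, 0, 0], [0, 0, 0]])
        moved = toy_ensemble(disp[None])
        # RMSD = sqrt((0.01+0.04+0.04+0.09+0)/5) = sqrt(0.036)
        np.testing.assert_allclose(rmsd(moved, ref, np.arange(5)).values,
                                   [np.sqrt(0.036)])


class TestFes:
    def test_all_samples_in_one_bin(self):
        x = SeriesPerFrame(np.full(10, 1.0))
        y = SeriesPerFrame(np.full(10, 2.0))
        fes = fes_2d(x, y, bins=5)
        occ = fes.occupied
        assert occ.sum() == 1
        assert fes.free_energy[occ] == 0.0
        assert np.all(np.isinf(fes.free_energy[~occ]))

    def test_two_equal_bins_both_zero(self):
        x = SeriesPerFrame(np.array([0.0] * 5 + [1.0] * 5))
        y = SeriesPerFrame(np.zeros(10))
        fes = fes_2d(x, y, bins=2)
        np.testing.assert_allclose(fes.free_energy[fes.occupied], 0.0)

    def test_renormalized_probabilities_match_histogram(self):
        g = np.random.default_rng(7)
        x = SeriesPerFrame(g.normal(size=5000))
        y = SeriesPerFrame(g.normal(size=5000))
        fes = fes_2d(x, y, bins=20)
        np.testing.assert_allclose(fes.probabilities(),
                                   fes.counts / fes.counts.sum(), rtol=1e-12)

    def test_uniform_samples_flatten(self):
        g = np.random.default_rng(8)
        n = 400_000
        x = SeriesPerFrame(g.uniform(0, 1, n))
        y = SeriesPerFrame(g.uniform(0, 1, n))
        fes = fes_2d(x, y, bins=2, ranges=((0, 1), (0, 1)))
        assert fes.free_energy.max() < 0.02  # all four bins F -> 0

    def test_combine_equals_concatenation(self):
        g = np.random.default_rng(9)
        xs = [SeriesPerFrame(g.normal(size=100)) for _ in range(3)]
        ys = [SeriesPerFrame(g.normal(size=100)) for _ in range(3)]
        combined = combine_fes(xs, ys, bins=8)
        concat = fes_2d(SeriesPerFrame(np.concatenate([s.values for s in xs])),
                        SeriesPerFrame(np.concatenate([s.values for s in ys])), bins=8)
        np.testing.assert_array_equal(combined.counts, concat.counts)

    def test_duplication_leaves_relative_f_unchanged(self):
        g = np.random.default_rng(10)
        x = SeriesPerFrame(g.normal(size=200))
        y = SeriesPerFrame(g.normal(size=200))
        one = fes_2d(x, y, bins=6)
        two = combine_fes([x, x], [y, y], bins=6)
        np.testing.assert_allclose(two.free_energy[two.occupied],
                                   one.free_energy[one.occupied])

    def test_zero_samples_raises(self):
        with pytest.raises(ValueError):
            fes_2d(SeriesPerFrame([]), SeriesPerFrame([]))


class TestSiteDistance:
    def test_singletons(self):
        ens = toy_ensemble([[[0, 0, 0], [2, 0, 0]]], resids=[1, 2],
                           names=["SG", "CB"], elements=["S", "C"])
        np.testing.assert_allclose(site_distance(ens, [0], 2).values, [2.0])

    def test_symmetric_sulfur_pair_measures_to_midpoint(self):
        ens = toy_ensemble([[[0, 1, 0], [0, -1, 0], [3, 0, 0]]], resids=[1, 1, 2],
                           names=["SG", "SG", "CB"], elements=["S", "S", "C"])
        np.testing.assert_allclose(site_distance(ens, [0, 1], 2).values, [3.0])

    def test_backbone_excluded_from_side_chain(self):
        ens = toy_ensemble(
            [[[0, 0, 0], [10, 0, 0], [2, 0, 0], [2.4, 0, 0]]],
            resids=[1, 2, 2, 2], names=["SG", "CA", "CB", "CG"],
            elements=["S", "C", "C", "C"], masses=[1, 1, 1, 1])
        # side chain of residue 2 = CB, CG only -> COM at x=2.2
        np.testing.assert_allclose(site_distance(ens, [0], 2).values, [2.2])

    def test_no_side_chain_raises(self):
        ens = toy_ensemble([[[0, 0, 0], [1, 0, 0]]], resids=[1, 2],
                           names=["SG", "CA"], elements=["S", "C"])
        with pytest.raises(ValueError, match="side-chain"):
            site_distance(ens, [0], 2)


class TestFitEquilibration:
    def test_recovers_known_logarithmic_parameters(self):
        t = np.arange(200.0) * 10
        a_true, b_true = 0.12, 0.3
        vals = a_true * np.log(t + 10.0) + b_true  # t0 = frame interval
        fit = fit_equilibration(SeriesPerFrame(vals, times=t))
        assert abs(fit["a"] - a_true) < 1e-6
        assert abs(fit["b"] - b_true) < 1e-6
        assert np.abs(fit["residuals"]).max() < 1e-8

    def test_constant_series_equilibrated_immediately(self):
        t = np.arange(50.0)
        fit = fit_equilibration(SeriesPerFrame(np.full(50, 1.5), times=t))
        assert abs(fit["a"]) < 1e-8
        assert fit["equilibration_time"] == 0.0

    def test_zero_threshold_never_equilibrates(self):
        t = np.arange(100.0)
        vals = 0.1 * np.log(t + 1) + 0.2
        fit = fit_equilibration(SeriesPerFrame(vals, times=t),
                                derivative_threshold_nm_per_ns=0.0)
        assert fit["equilibration_time"] is None

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError, match="10 samples"):
            fit_equilibration(SeriesPerFrame(np.ones(5), times=np.arange(5.0)))
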