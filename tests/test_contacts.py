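import numpy as np
import pandas as pd
import pytest

from domaindyn import contacts
from domaindyn.contacts import (brute_force_frame_contacts, cb_reference_map,
                                contact_frequency, difference_map,
                                frame_contacts, overlay_predictions,
                                residue_profile, threshold_map)
from domaindyn.domains import DomainMap, Segment
from domaindyn.ensembles import ReplicaSet
from tests.conftest import flat_map, toy_ensemble


def two_residue_ens(gap_nm, n_frames=1):
    """Two single-atom residues separated by gap_nm along x."""
    coords = np.tile(np.array([[0, 0, 0], [gap_nm, 0, 0.0]]), (n_frames, 1, 1))
    return toy_ensemble(coords, resids=[1, 2], names=["CA", "CA"], elements=["C", "C"])


class TestFrameContacts:
    def test_pair_within_cutoff_detected(self):
        ens = two_residue_ens(0.40)
        assert frame_contacts(ens, 0, flat_map(2)) == {(1, 2)}

    def test_pair_beyond_cutoff_absent(self):
        ens = two_residue_ens(0.46)
        assert frame_contacts(ens, 0, flat_map(2)) == set()

    def test_cutoff_is_strict_less_than(self):
        ens = two_residue_ens(0.45)
        assert frame_contacts(ens, 0, flat_map(2)) == set()

    def test_hydrogens_ignored_by_heavy_filter(self):
        ens = toy_ensemble([[[0, 0, 0], [0.2, 0, 0], [1.0, 0, 0]]],
                           resids=[1, 2, 2], names=["CA", "HA", "CA"],
                           elements=["C", "H", "C"])
        assert frame_contacts(ens, 0, flat_map(2)) == set()

    def test_same_segment_pairs_excluded(self):
        dmap = DomainMap([Segment("one", ((1, 2),))])
        ens = two_residue_ens(0.3)
        assert frame_contacts(ens, 0, dmap) == set()

    @pytest.mark.parametrize("seed", range(25))
    @pytest.mark.parametrize("cutoff", [0.45, 0.8])
    def test_tree_search_equals_brute_force(self, seed, cutoff):
        g = np.random.default_rng(seed)
        n_res = 30
        coords = g.uniform(0, 2.5, (1, n_res * 2, 3))
        resids = np.repeat(np.arange(1, n_res + 1), 2)
        ens = toy_ensemble(coords, resids=resids,
                           names=["CA", "CB"] * n_res, elements=["C", "C"] * n_res)
        dmap = flat_map(n_res, segment_size=3)
        assert (frame_contacts(ens, 0, dmap, cutoff=cutoff)
                == brute_force_frame_contacts(ens, 0, dmap, cutoff=cutoff))


class TestContactFrequency:
    def test_always_present_is_one(self):
        ens = two_residue_ens(0.3, n_frames=7)
        cm = contact_frequency(ens, flat_map(2))
        assert cm.get(1, 2) == 1.0

    def test_one_in_twenty_is_five_percent(self):
        coords = np.tile(np.array([[0, 0, 0], [2.0, 0, 0]]), (20, 1, 1))
        coords[4, 1] = [0.3, 0, 0]  # in contact in exactly one frame
        ens = toy_ensemble(coords, resids=[1, 2])
        cm = contact_frequency(ens, flat_map(2))
        assert cm.get(1, 2) == pytest.approx(0.05)

    def test_replica_pooling_weights_frames_equally(self):
        a = two_residue_ens(0.3, n_frames=10)   # always in contact
        b = two_residue_ens(2.0, n_frames=30)   # never
        a = a.with_frames(a.coords, None)
        rs = ReplicaSet("c", [
            toy_ensemble(a.coords, resids=[1, 2], condition="c", run="reA", replica="r1"),
            toy_ensemble(b.coords, resids=[1, 2], condition="c", run="reA", replica="r2"),
        ])
        cm = contact_frequency(rs, flat_map(2))
        assert cm.get(1, 2) == pytest.approx(10 / 40)

    def test_concatenation_is_frame_weighted_average(self):
        g = np.random.default_rng(3)
        c1 = g.uniform(0, 1.2, (6, 8, 3))
        c2 = g.uniform(0, 1.2, (18, 8, 3))
        mk = lambda c: toy_ensemble(c, resids=np.repeat([1, 2, 3, 4], 2))
        dmap = flat_map(4)
        f1 = contact_frequency(mk(c1), dmap).freq
        f2 = contact_frequency(mk(c2), dmap).freq
        fcat = contact_frequency(mk(np.concatenate([c1, c2])), dmap).freq
        np.testing.assert_allclose(fcat, (6 * f1 + 18 * f2) / 24)

    def test_programmed_occupancy_recovered(self, fixture_spec, fixture_sets):
        ov = fixture_spec.contact_overrides[1]  # MBD2-MBD3, apo p=0.5
        cm = contact_frequency(fixture_sets["apo"], fixture_spec.dmap)
        n = fixture_sets["apo"].n_frames_total
        p = ov.probability["apo"]
        tol = 4 * np.sqrt(p * (1 - p) / n)
        assert cm.get(ov.res_i, ov.res_j) == pytest.approx(p, abs=tol)


class TestThreshold:
    def _map_with(self, value):
        freq = np.array([[np.nan, value], [value, np.nan]])
        return contacts.ContactMap(np.array([1, 2]), freq)

    def test_exactly_at_threshold_removed(self):
        assert threshold_map(self._map_with(0.05)).get(1, 2) == 0.0

    def test_just_above_retained(self):
        assert threshold_map(self._map_with(0.051)).get(1, 2) == 0.051

    def test_zero_threshold_keeps_nonzero(self):
        assert threshold_map(self._map_with(0.01), 0.0).get(1, 2) == 0.01


class TestDifferenceMap:
    def test_identical_maps_give_zero(self):
        m = contact_frequency(two_residue_ens(0.3, 5), flat_map(2))
        d = difference_map(m, m)
        assert d.get(1, 2) == 0.0

    def test_missing_entry_counts_as_zero(self):
        holo = contact_frequency(two_residue_ens(0.3, 5), flat_map(2))
        apo = contact_frequency(two_residue_ens(2.0, 5), flat_map(2))
        assert difference_map(holo, apo).get(1, 2) == 1.0

    def test_antisymmetry(self):
        g = np.random.default_rng(4)
        mk = lambda s: toy_ensemble(g.uniform(0, 1.5, (10, 6, 3)),
                                    resids=np.repeat([1, 2, 3], 2))
        dmap = flat_map(3)
        a, b = contact_frequency(mk(0), dmap), contact_frequency(mk(1), dmap)
        dab, dba = difference_map(a, b), difference_map(b, a)
        np.testing.assert_allclose(np.nan_to_num(dab.diff), -np.nan_to_num(dba.diff))

    def test_axis_mismatch_raises(self):
        a = contact_frequency(two_residue_ens(0.3), flat_map(2))
        ens3 = toy_ensemble(np.zeros((1, 3, 3)), resids=[1, 2, 3])
        b = contact_frequency(ens3, flat_map(3))
        with pytest.raises(ValueError, match="axes"):
            difference_map(a, b)


class TestResidueProfile:
    def _toy_map(self):
        # residues 1-2 in segA, 3-4 in segB; single contact (2, 3) at 0.8
        dmap = DomainMap([Segment("A", ((1, 2),)), Segment("B", ((3, 4),))])
        freq = np.zeros((4, 4))
        freq[1, 2] = freq[2, 1] = 0.8
        ex = np.array([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]], bool)
        freq[ex] = np.nan
        return contacts.ContactMap(np.arange(1, 5), freq), dmap

    def test_single_pair_profiles(self):
        cm, dmap = self._toy_map()
        prof = residue_profile(cm, dmap, "A", "B")
        assert prof["A"].loc[2] == 0.8 and prof["A"].loc[1] == 0.0
        assert prof["B"].loc[3] == 0.8 and prof["B"].loc[4] == 0.0

    def test_sum_aggregation(self):
        cm, dmap = self._toy_map()
        cm.freq[1, 3] = cm.freq[3, 1] = 0.1
        prof = residue_profile(cm, dmap, "A", "B", agg="sum")
        assert prof["A"].loc[2] == pytest.approx(0.9)

    def test_no_contacts_all_zero(self):
        cm, dmap = self._toy_map()
        cm.freq[~np.isnan(cm.freq)] = 0.0
        prof = residue_profile(cm, dmap, "A", "B")
        assert (prof["A"] == 0).all() and (prof["B"] == 0).all()


class TestCbReferenceMap:
    def _ens(self, gap):
        return toy_ensemble(
            [[[0, 0, 0], [0, 0, 0.01], [gap, 0, 0], [gap, 0, 0.01]]],
            resids=[1, 1, 2, 2], names=["CA", "CB", "CA", "CB"],
            elements=["C", "C", "C", "C"])

    def test_within_8A_present(self):
        cm = cb_reference_map(self._ens(0.79), flat_map(2))
        assert cm.get(1, 2) == 1.0

    def test_beyond_8A_absent(self):
        cm = cb_reference_map(self._ens(0.81), flat_map(2))
        assert cm.get(1, 2) == 0.0

    def test_cutoff_inclusive(self):
        ens = toy_ensemble([[[0, 0, 0], [0.8, 0, 0]]], resids=[1, 2],
                           names=["CB", "CB"], elements=["C", "C"])
        cm = cb_reference_map(ens, flat_map(2))
        assert cm.get(1, 2) == 1.0

    def test_ca_fallback_for_missing_cb(self):
        ens = toy_ensemble([[[0, 0, 0], [0.5, 0, 0]]], resids=[1, 2],
                           names=["CA", "CB"], elements=["C", "C"])
        cm = cb_reference_map(ens, flat_map(2))
        assert cm.get(1, 2) == 1.0

    def test_matches_brute_force_scan(self):
        g = np.random.default_rng(6)
        n_res = 25
        ens = toy_ensemble(g.uniform(0, 3, (1, n_res, 3)),
                           resids=np.arange(1, n_res + 1),
                           names=["CB"] * n_res, elements=["C"] * n_res)
        dmap = flat_map(n_res, segment_size=4)
        cm = cb_reference_map(ens, dmap)
        expect = brute_force_frame_contacts(ens, 0, dmap, cutoff=0.8,
                                            atom_filter="c_beta", strict=False)
        got = {(i, j) for i, j in zip(*np.where(np.triu(np.nan_to_num(cm.freq)) > 0))}
        got = {(cm.resids[i], cm.resids[j]) for i, j in got}
        assert got == expect


class TestOverlayPredictions:
    # the four high-probability coevolution pairs reported for the MBD6/core interface
    TABLE = "i j probability\n581 726 0.995\n602 785 0.993\n603 904 0.996\n605 905 0.991\n577 900 0.5\n"

    def test_probability_threshold_and_annotation(self, tmp_path):
        p = tmp_path / "pred.txt"
        p.write_text(self.TABLE)
        freq = np.full((4, 4), np.nan)
        resids = np.array([581, 603, 726, 904])
        freq[np.eye(4) == 0] = 0.0
        freq[1, 3] = freq[3, 1] = 1.0  # 603-904 always in contact
        cm = contacts.ContactMap(resids, freq)
        rep = overlay_predictions(cm, str(p), min_probability=0.99)
        assert len(rep) == 4  # the 0.5-probability row is excluded
        row = rep[(rep.i == 603) & (rep.j == 904)].iloc[0]
        assert row.observed and row.sim_frequency == 1.0
        assert not rep[(rep.i == 581) & (rep.j == 726)].iloc[0].observed

    def test_malformed_table_raises(self):
        with pytest.raises(ValueError, match="columns"):
            overlay_predictions(
                contacts.ContactMap(np.array([1, 2]),
                                    np.array([[np.nan, 0], [0, np.nan]])),
                pd.DataFrame({"x": [1]}))
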