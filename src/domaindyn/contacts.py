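"""Residue-residue contact detection and frequency maps.

A contact between residues i and j exists in a frame when any pair of
heavy (non-hydrogen) atoms, one from each residue, lies within the
cutoff (default 0.45 nm, strict `<`).  Pairs whose two residues fall in
the same segment — domain or linker — of the active domain map are
excluded, so the maps report inter-segment contacts only.  Frequencies
are the fraction of counted frames containing the pair.

Candidate atom pairs come from a KD-tree range query; correctness
against a brute-force all-pairs scan is enforced by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .domains import DomainMap, heavy_mask
from .ensembles import Ensemble, ReplicaSet

__all__ = [
    "ContactMap",
    "DifferenceMap",
    "frame_contacts",
    "contact_frequency",
    "threshold_map",
    "difference_map",
    "residue_profile",
    "cb_reference_map",
    "overlay_predictions",
    "brute_force_frame_contacts",
]

DEFAULT_CUTOFF_NM = 0.45       # heavy-atom contact cutoff (4.5 A)
CB_CUTOFF_NM = 0.8             # Cbeta-Cbeta reference-map cutoff (8 A)
DEFAULT_THRESHOLD = 0.05       # render maps only above 5% occupancy


@dataclass
class ContactMap:
    """Symmetric residue x residue contact-frequency matrix.

    ``freq[i, j]`` is the fraction of frames with a contact between
    ``resids[i]`` and ``resids[j]``; the diagonal and all same-segment
    pairs are NaN (excluded by construction).
    """

    resids: np.ndarray            # (n,) residue numbers, sorted
    freq: np.ndarray              # (n, n) in [0, 1], NaN where excluded
    cutoff: float = DEFAULT_CUTOFF_NM
    atom_filter: str = "heavy"
    n_frames: int = 0
    threshold: float | None = None
    condition: str = ""

    def __post_init__(self):
        self.resids = np.asarray(self.resids)
        self.freq = np.asarray(self.freq, dtype=float)
        valid = ~np.isnan(self.freq)
        if not np.allclose(self.freq[valid], self.freq.T[valid], atol=1e-12):
            raise ValueError("contact-frequency matrix must be symmetric")
        if np.any((self.freq[valid] < 0) | (self.freq[valid] > 1)):
            raise ValueError("frequencies must lie in [0, 1]")

    def _pos(self, resid: int) -> int:
        i = int(np.searchsorted(self.resids, resid))
        if i >= len(self.resids) or self.resids[i] != resid:
            raise KeyError(f"residue {resid} not on contact-map axis")
        return i

    def get(self, res_i: int, res_j: int) -> float:
        return float(self.freq[self._pos(res_i), self._pos(res_j)])

    def pairs(self, min_freq: float = 0.0) -> pd.DataFrame:
        """Upper-triangle nonzero entries as a tidy table (res_i < res_j)."""
        iu, ju = np.triu_indices(len(self.resids), k=1)
        vals = self.freq[iu, ju]
        keep = ~np.isnan(vals) & (vals > min_freq)
        return pd.DataFrame({
            "res_i": self.resids[iu[keep]],
            "res_j": self.resids[ju[keep]],
            "frequency": vals[keep],
        })

    def to_csv(self, path) -> None:
        """Sparse (res_i, res_j, frequency) CSV plus a JSON metadata sidecar."""
        import json
        from pathlib import Path

        path = Path(path)
        self.pairs().to_csv(path, index=False)
        meta = {"cutoff_nm": self.cutoff, "atom_filter": self.atom_filter,
                "n_frames": self.n_frames, "threshold": self.threshold,
                "condition": self.condition, "n_residues": int(len(self.resids))}
        with open(path.with_suffix(".meta.json"), "w") as fh:
            json.dump(meta, fh, indent=2)


@dataclass
class DifferenceMap:
    """Signed per-pair frequency difference between two conditions."""

    resids: np.ndarray
    diff: np.ndarray              # (n, n) in [-1, 1], NaN where excluded
    label: str = "holo-apo"
    cutoff: float = DEFAULT_CUTOFF_NM
    atom_filter: str = "heavy"

    def get(self, res_i: int, res_j: int) -> float:
        i = int(np.searchsorted(self.resids, res_i))
        j = int(np.searchsorted(self.resids, res_j))
        return float(self.diff[i, j])

    def pairs(self, min_abs: float = 0.0) -> pd.DataFrame:
        iu, ju = np.triu_indices(len(self.resids), k=1)
        vals = self.diff[iu, ju]
        keep = ~np.isnan(vals) & (np.abs(vals) > min_abs)
        return pd.DataFrame({
            "res_i": self.resids[iu[keep]],
            "res_j": self.resids[ju[keep]],
            "difference": vals[keep],
        })


def _contact_atoms(top, dmap: DomainMap, atom_filter: str):
    """Atom indices eligible for contact counting + their residue/segment ids."""
    resids = np.asarray(top.resids)
    seg = dmap.segment_index_of(resids)
    mask = seg >= 0
    if atom_filter == "heavy":
        mask &= heavy_mask(top)
    elif atom_filter == "c_beta":
        names = np.asarray(top.names)
        cb_res = set(resids[names == "CB"].tolist())
        mask &= (names == "CB") | ((names == "CA") & ~np.isin(resids, list(cb_res) or [-1]))
    elif atom_filter != "all":
        raise ValueError(f"unknown atom_filter {atom_filter!r}")
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("no atoms eligible for contact detection")
    return idx, resids[idx], seg[idx]


def _pairs_from_frame(xyz, resid_of, seg_of, cutoff, strict):
    """Residue pairs (i<j, different segments) with any atom pair in range."""
    if not np.all(np.isfinite(xyz)):
        raise ValueError("non-finite coordinates in frame")
    tree = cKDTree(xyz)
    ap = tree.query_pairs(r=cutoff, output_type="ndarray")
    if ap.size == 0:
        return set()
    if strict:
        d = np.linalg.norm(xyz[ap[:, 0]] - xyz[ap[:, 1]], axis=1)
        ap = ap[d < cutoff]
    ri, rj = resid_of[ap[:, 0]], resid_of[ap[:, 1]]
    si, sj = seg_of[ap[:, 0]], seg_of[ap[:, 1]]
    keep = (ri != rj) & (si != sj)
    lo = np.minimum(ri[keep], rj[keep])
    hi = np.maximum(ri[keep], rj[keep])
    return set(zip(lo.tolist(), hi.tolist()))


def frame_contacts(ens: Ensemble, frame: int, dmap: DomainMap,
                   cutoff: float = DEFAULT_CUTOFF_NM,
                   atom_filter: str = "heavy",
                   strict: bool = True) -> set[tuple[int, int]]:
    """Residue pairs in contact in one frame (inter-segment only).

    ``strict`` uses `<` for the cutoff comparison (the convention for the
    0.45 nm heavy-atom maps); the Cbeta reference map uses `<=`.
    """
    idx, resid_of, seg_of = _contact_atoms(ens, dmap, atom_filter)
    return _pairs_from_frame(ens.coords[frame][idx], resid_of, seg_of, cutoff, strict)


def brute_force_frame_contacts(ens: Ensemble, frame: int, dmap: DomainMap,
                               cutoff: float = DEFAULT_CUTOFF_NM,
                               atom_filter: str = "heavy",
                               strict: bool = True) -> set[tuple[int, int]]:
    """O(N^2) all-pairs reference used to validate the tree-based search."""
    idx, resid_of, seg_of = _contact_atoms(ens, dmap, atom_filter)
    xyz = ens.coords[frame][idx]
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
    hit = (d < cutoff) if strict else (d <= cutoff)
    out = set()
    n = len(idx)
    for a in range(n):
        for b in range(a + 1, n):
            if hit[a, b] and resid_of[a] != resid_of[b] and seg_of[a] != seg_of[b]:
                out.add((min(resid_of[a], resid_of[b]), max(resid_of[a], resid_of[b])))
    return out


def _excluded_mask(resids: np.ndarray, dmap: DomainMap) -> np.ndarray:
    seg = dmap.segment_index_of(resids)
    same_seg = seg[:, None] == seg[None, :]
    return same_seg | np.eye(len(resids), dtype=bool)


def contact_frequency(data: Ensemble | ReplicaSet, dmap: DomainMap,
                      cutoff: float = DEFAULT_CUTOFF_NM,
                      atom_filter: str = "heavy",
                      per_replica: bool = False):
    """Contact frequencies over all frames of an ensemble or replica set.

    For a :class:`ReplicaSet`, frames are pooled with equal weight across
    replicas by default; ``per_replica=True`` instead returns one
    :class:`ContactMap` per member (used for replica-level statistics).
    """
    members = list(data) if isinstance(data, ReplicaSet) else [data]
    condition = data.condition if isinstance(data, ReplicaSet) else data.condition
    if per_replica:
        return [contact_frequency(m, dmap, cutoff, atom_filter) for m in members]

    top = members[0]
    idx, resid_of, seg_of = _contact_atoms(top, dmap, atom_filter)
    resids = np.unique(resid_of)
    pos = {r: i for i, r in enumerate(resids.tolist())}
    counts = np.zeros((len(resids), len(resids)))
    n_frames = 0
    for ens in members:
        if ens.n_frames == 0:
            raise ValueError("ensemble has no frames")
        for f in range(ens.n_frames):
            for (ri, rj) in _pairs_from_frame(ens.coords[f][idx], resid_of, seg_of, cutoff, True):
                counts[pos[ri], pos[rj]] += 1
        n_frames += ens.n_frames
    counts = counts + counts.T
    freq = counts / n_frames
    freq[_excluded_mask(resids, dmap)] = np.nan
    return ContactMap(resids, freq, cutoff, atom_filter, n_frames, None, condition)


def threshold_map(cmap: ContactMap, min_fraction: float = DEFAULT_THRESHOLD) -> ContactMap:
    """Keep only entries strictly above ``min_fraction`` (others set to 0).

    The strict `>` means a pair occupied in exactly 5% of frames is
    dropped at the default threshold.
    """
    freq = cmap.freq.copy()
    valid = ~np.isnan(freq)
    freq[valid & ~(freq > min_fraction)] = 0.0
    return ContactMap(cmap.resids, freq, cmap.cutoff, cmap.atom_filter,
                      cmap.n_frames, min_fraction, cmap.condition)


def difference_map(holo: ContactMap, apo: ContactMap) -> DifferenceMap:
    """Entrywise holo − apo on raw (un-thresholded) frequencies.

    Residue axes must agree; a pair missing from one map counts as
    frequency 0 there (NaN is kept only where both maps exclude the pair).
    """
    if not np.array_equal(holo.resids, apo.resids):
        raise ValueError("contact maps have different residue axes")
    if holo.cutoff != apo.cutoff or holo.atom_filter != apo.atom_filter:
        raise ValueError("contact maps computed with different cutoff/filter")
    h = np.nan_to_num(holo.freq, nan=0.0)
    a = np.nan_to_num(apo.freq, nan=0.0)
    diff = h - a
    both_nan = np.isnan(holo.freq) & np.isnan(apo.freq)
    diff[both_nan] = np.nan
    return DifferenceMap(holo.resids, diff,
                         f"{holo.condition or 'B'}-{apo.condition or 'A'}",
                         holo.cutoff, holo.atom_filter)


def residue_profile(cmap: ContactMap | DifferenceMap, dmap: DomainMap,
                    seg_a: str, seg_b: str, agg: str = "max") -> dict[str, pd.Series]:
    """Per-residue contact profile between two segments.

    For every residue of ``seg_a``, aggregate (max by default, or sum) its
    frequency over all partners in ``seg_b``, and vice versa.  On a
    difference map the aggregation is applied to signed values by largest
    magnitude.
    """
    mat = cmap.freq if isinstance(cmap, ContactMap) else cmap.diff
    out = {}
    for name, other in ((seg_a, seg_b), (seg_b, seg_a)):
        ia = _axis_indices(cmap.resids, dmap, name)
        ib = _axis_indices(cmap.resids, dmap, other)
        if ia.size == 0 or ib.size == 0:
            raise ValueError(f"segment {name if ia.size == 0 else other!r} has no residues on the map axis")
        sub = np.nan_to_num(mat[np.ix_(ia, ib)], nan=0.0)
        if agg == "max":
            vals = sub[np.arange(len(ia)), np.abs(sub).argmax(axis=1)]
        elif agg == "sum":
            vals = sub.sum(axis=1)
        else:
            raise ValueError("agg must be 'max' or 'sum'")
        out[name] = pd.Series(vals, index=cmap.resids[ia], name=f"{name}→{other}")
    return out


def _axis_indices(resids: np.ndarray, dmap: DomainMap, group: str) -> np.ndarray:
    mask = np.zeros(len(resids), dtype=bool)
    for a, b in dmap.group_intervals(group):
        mask |= (resids >= a) & (resids <= b)
    return np.flatnonzero(mask)


def cb_reference_map(structure: Ensemble, dmap: DomainMap,
                     cutoff: float = CB_CUTOFF_NM) -> ContactMap:
    """Binary Cβ–Cβ map of a single structure (Cα fallback, `<=` cutoff).

    The conventional starting-structure overlay: residue pairs whose
    beta carbons are within 0.8 nm, same-segment pairs excluded.
    """
    idx, resid_of, seg_of = _contact_atoms(structure, dmap, "c_beta")
    pairs = _pairs_from_frame(structure.coords[0][idx], resid_of, seg_of, cutoff, strict=False)
    resids = np.unique(resid_of)
    pos = {r: i for i, r in enumerate(resids.tolist())}
    freq = np.zeros((len(resids), len(resids)))
    for ri, rj in pairs:
        freq[pos[ri], pos[rj]] = freq[pos[rj], pos[ri]] = 1.0
    freq[_excluded_mask(resids, dmap)] = np.nan
    return ContactMap(resids, freq, cutoff, "c_beta", 1, None, structure.condition)


def overlay_predictions(cmap: ContactMap, predictions: pd.DataFrame | str,
                        reference: ContactMap | None = None,
                        min_probability: float = 0.99) -> pd.DataFrame:
    """Annotate high-probability predicted contacts with simulation data.

    ``predictions`` is a table (or path to a whitespace/comma-delimited
    file with a header) of columns (i, j, probability) — the export
    format of common coupling-prediction servers.  Rows with probability
    > ``min_probability`` are kept and annotated with the simulated
    contact frequency and, if a reference map is given, presence in the
    starting structure.
    """
    if not isinstance(predictions, pd.DataFrame):
        predictions = pd.read_csv(predictions, sep=None, engine="python")
    cols = {c.lower().strip(): c for c in predictions.columns}
    try:
        tab = predictions.rename(columns={cols["i"]: "i", cols["j"]: "j",
                                          cols["probability"]: "probability"})
    except KeyError as exc:
        raise ValueError("predictions table needs columns i, j, probability") from exc
    tab = tab[tab["probability"] > min_probability].copy()

    def _freq(m, i, j):
        try:
            v = m.get(int(i), int(j))
        except KeyError:
            return np.nan
        return v

    tab["sim_frequency"] = [_freq(cmap, i, j) for i, j in zip(tab["i"], tab["j"])]
    tab["observed"] = tab["sim_frequency"].fillna(0) > 0
    if reference is not None:
        tab["in_reference"] = [
            (_freq(reference, i, j) or 0) > 0 for i, j in zip(tab["i"], tab["j"])
        ]
    return tab.reset_index(drop=True)
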