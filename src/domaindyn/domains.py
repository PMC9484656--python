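"""Named residue-segment definitions of protein domains and linkers.

A :class:`DomainMap` partitions a contiguous stretch of protein sequence
(1-based residue numbering, inclusive intervals) into named segments, each
either a ``domain`` or a ``linker``.  The default map is the 17-segment
decomposition of human ATP7B: the N-terminal peptide, the six metal-binding
domains (MBD1-6) with their linkers, and the catalytic core (M, A, P, N
domains; the M and P domains are discontinuous in sequence).

Composite groups ("MBD1-3", "N-terminal tail", "core", ...) resolve to
unions of member segments plus the linkers between them, because the
aggregate observables of interest (tail radius of gyration, core alignment
selections) span linkers as well as domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "Segment",
    "DomainMap",
    "default_atp7b_map",
    "resolve_selection",
]


@dataclass(frozen=True)
class Segment:
    """A named stretch of sequence: one or more inclusive residue intervals."""

    name: str
    ranges: tuple[tuple[int, int], ...]
    category: str = "domain"  # "domain" | "linker"

    def __post_init__(self):
        if self.category not in ("domain", "linker"):
            raise ValueError(f"category must be 'domain' or 'linker', got {self.category!r}")
        rs = tuple((int(a), int(b)) for a, b in self.ranges)
        object.__setattr__(self, "ranges", rs)
        for a, b in rs:
            if a > b:
                raise ValueError(f"segment {self.name!r}: interval ({a}, {b}) has start > end")
        for (a1, b1), (a2, b2) in zip(sorted(rs), sorted(rs)[1:]):
            if a2 <= b1:
                raise ValueError(f"segment {self.name!r}: overlapping intervals")

    def __contains__(self, resid: int) -> bool:
        return any(a <= resid <= b for a, b in self.ranges)

    @property
    def n_residues(self) -> int:
        return sum(b - a + 1 for a, b in self.ranges)

    def residues(self) -> np.ndarray:
        return np.concatenate([np.arange(a, b + 1) for a, b in sorted(self.ranges)])


class DomainMap:
    """An ordered, gap-free, non-overlapping set of segments.

    Parameters
    ----------
    segments:
        Segments in sequence order.  Their union must tile
        ``sequence_span`` exactly (no gaps, no overlaps).
    sequence_span:
        Inclusive residue interval covered by the map.
    composites:
        Optional named composite groups, each a list of inclusive
        intervals (typically unions of member segments plus intervening
        linkers).
    """

    def __init__(
        self,
        segments: list[Segment],
        sequence_span: tuple[int, int] | None = None,
        composites: dict[str, tuple[tuple[int, int], ...]] | None = None,
    ):
        self.segments = list(segments)
        covered = sorted(
            (a, b) for seg in self.segments for (a, b) in seg.ranges
        )
        if not covered:
            raise ValueError("DomainMap needs at least one segment")
        if sequence_span is None:
            sequence_span = (covered[0][0], covered[-1][1])
        self.sequence_span = (int(sequence_span[0]), int(sequence_span[1]))
        # validate tiling: no overlaps, no gaps over the span
        pos = self.sequence_span[0]
        for a, b in covered:
            if a < pos:
                raise ValueError(f"overlapping segments at residue {a}")
            if a > pos:
                raise ValueError(f"gap in domain map: residues {pos}..{a - 1} unassigned")
            pos = b + 1
        if pos != self.sequence_span[1] + 1:
            raise ValueError(
                f"domain map covers up to {pos - 1}, span declared to {self.sequence_span[1]}"
            )
        self.composites: dict[str, tuple[tuple[int, int], ...]] = dict(composites or {})
        self._by_name = {s.name: s for s in self.segments}
        if len(self._by_name) != len(self.segments):
            raise ValueError("duplicate segment names")

    # -- lookup -----------------------------------------------------------

    def segment_of(self, resid: int) -> str:
        """Name of the segment containing residue ``resid``."""
        for seg in self.segments:
            if resid in seg:
                return seg.name
        raise KeyError(f"residue {resid} outside map span {self.sequence_span}")

    def segment_index_of(self, resids: np.ndarray) -> np.ndarray:
        """Vectorized segment index per residue (-1 outside the map)."""
        resids = np.asarray(resids)
        out = np.full(resids.shape, -1, dtype=int)
        for i, seg in enumerate(self.segments):
            for a, b in seg.ranges:
                out[(resids >= a) & (resids <= b)] = i
        return out

    def group_intervals(self, group: str) -> tuple[tuple[int, int], ...]:
        """Inclusive residue intervals for a segment or composite name."""
        if group in self._by_name:
            return self._by_name[group].ranges
        if group in self.composites:
            return self.composites[group]
        raise KeyError(
            f"unknown group {group!r}; known segments: "
            f"{[s.name for s in self.segments]}, composites: {list(self.composites)}"
        )

    def group_names(self) -> list[str]:
        return [s.name for s in self.segments] + list(self.composites)

    def domain_names(self) -> list[str]:
        return [s.name for s in self.segments if s.category == "domain"]

    # -- config round-trip ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "sequence_span": list(self.sequence_span),
            "segments": [
                {
                    "name": s.name,
                    "category": s.category,
                    "ranges": [list(r) for r in s.ranges],
                }
                for s in self.segments
            ],
            "composites": {
                k: [list(r) for r in v] for k, v in self.composites.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DomainMap":
        segs = [
            Segment(
                name=s["name"],
                ranges=tuple(tuple(r) for r in s["ranges"]),
                category=s.get("category", "domain"),
            )
            for s in d["segments"]
        ]
        comps = {
            k: tuple(tuple(r) for r in v)
            for k, v in d.get("composites", {}).items()
        }
        span = d.get("sequence_span")
        return cls(segs, tuple(span) if span else None, comps)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DomainMap":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DomainMap)
            and self.to_dict() == other.to_dict()
        )

    def __repr__(self) -> str:
        return (
            f"DomainMap({len(self.segments)} segments, "
            f"span {self.sequence_span[0]}-{self.sequence_span[1]})"
        )


# The ATP7B decomposition used throughout: residues 5-1378, UniProt numbering.
_ATP7B_SEGMENTS = [
    ("N-terminal peptide", "domain", [(5, 56)]),
    ("MBD1", "domain", [(57, 125)]),
    ("MBD1-MBD2 linker", "linker", [(126, 142)]),
    ("MBD2", "domain", [(143, 210)]),
    ("MBD2-MBD3 linker", "linker", [(211, 256)]),
    ("MBD3", "domain", [(257, 327)]),
    ("MBD3-MBD4 linker", "linker", [(328, 358)]),
    ("MBD4", "domain", [(359, 426)]),
    ("MBD4-MBD5 linker", "linker", [(427, 487)]),
    ("MBD5", "domain", [(488, 555)]),
    ("MBD5-MBD6 linker", "linker", [(556, 563)]),
    ("MBD6", "domain", [(564, 631)]),
    ("MBD6-M linker", "linker", [(632, 642)]),
    ("M domain", "domain", [(643, 785), (915, 1002), (1305, 1378)]),
    ("A domain", "domain", [(786, 914)]),
    ("P domain", "domain", [(1003, 1034), (1195, 1304)]),
    ("N domain", "domain", [(1035, 1194)]),
]

_ATP7B_COMPOSITES = {
    "MBD1-3": ((57, 327),),
    "MBD1-4": ((57, 426),),
    "MBD1-6": ((57, 631),),
    # whether the tail includes the N-terminal peptide and the MBD6-M linker
    # is a modelling choice; the default includes both (residues 5-642)
    "N-terminal tail": ((5, 642),),
    "core": ((643, 1378),),  # M + A + P + N, contiguous in sequence
    # the alignment selection: M and P domain intervals only
    "M+P": ((643, 785), (915, 1002), (1003, 1034), (1195, 1304), (1305, 1378)),
}


def default_atp7b_map() -> DomainMap:
    """The 17-segment ATP7B domain/linker map (residues 5-1378).

    Domains: N-terminal peptide, MBD1-6, and the catalytic M, A, P, N
    domains; the M domain spans three sequence intervals and the P domain
    two.  Composite groups MBD1-3/1-4/1-6, "N-terminal tail" and "core"
    are included for aggregate observables.
    """
    segs = [Segment(n, tuple(tuple(r) for r in rs), c) for n, c, rs in _ATP7B_SEGMENTS]
    return DomainMap(segs, (5, 1378), _ATP7B_COMPOSITES)


def resolve_selection(
    dmap: DomainMap,
    group: str,
    topology,
    atom_filter: str = "all",
    names: list[str] | None = None,
    exclude_intervals: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Atom indices of ``topology`` whose residue lies in ``group``.

    Parameters
    ----------
    dmap, group:
        Domain map and the segment/composite name to resolve.
    topology:
        Any object exposing ``resids`` (per-atom residue numbers),
        ``elements`` and ``names`` arrays — an :class:`~domaindyn.ensembles.Ensemble`.
    atom_filter:
        ``all`` | ``heavy`` (element not hydrogen) | ``c_beta`` (CB, CA
        fallback for glycine-like residues without CB) | ``named`` (use
        ``names``).
    exclude_intervals:
        Optional residue intervals dropped from the selection, e.g. the
        flexible loops excluded from alignment/RMSD fits.

    Returns
    -------
    Sorted integer atom indices; raises if the selection is empty, which
    almost always signals a residue-numbering mismatch.
    """
    intervals = dmap.group_intervals(group)
    resids = np.asarray(topology.resids)
    mask = np.zeros(resids.shape, dtype=bool)
    for a, b in intervals:
        mask |= (resids >= a) & (resids <= b)
    if exclude_intervals:
        for a, b in exclude_intervals:
            mask &= ~((resids >= a) & (resids <= b))

    if atom_filter == "all":
        pass
    elif atom_filter == "heavy":
        mask &= heavy_mask(topology)
    elif atom_filter == "c_beta":
        atom_names = np.asarray(topology.names)
        cb = mask & (atom_names == "CB")
        # residues with no CB fall back to CA
        cb_resids = set(resids[cb].tolist())
        ca = mask & (atom_names == "CA") & ~np.isin(resids, list(cb_resids) or [-1])
        mask = cb | ca
    elif atom_filter == "named":
        if not names:
            raise ValueError("atom_filter='named' requires a names list")
        mask &= np.isin(np.asarray(topology.names), names)
    else:
        raise ValueError(f"unknown atom_filter {atom_filter!r}")

    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(
            f"selection {group!r} with filter {atom_filter!r} matched no atoms "
            "(residue-numbering mismatch between map and topology?)"
        )
    return idx


def heavy_mask(topology) -> np.ndarray:
    """Boolean mask of non-hydrogen atoms.

    Judged from the element field; atoms without an element fall back to
    the first alphabetic character of the atom name.
    """
    elements = np.asarray(topology.elements)
    names = np.asarray(topology.names)
    out = np.empty(elements.shape, dtype=bool)
    for i, (el, nm) in enumerate(zip(elements, names)):
        el = (el or "").strip()
        if not el:
            el = next((c for c in nm if c.isalpha()), "")
        out[i] = el.upper() != "H"
    return out
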