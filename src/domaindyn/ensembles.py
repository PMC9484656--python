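"""Topology + trajectory containers and standard-format I/O.

The in-memory carrier is :class:`Ensemble`: a flat topology (per-atom
name, element, residue number/name, mass, optional partial charge) plus a
``(n_frames, n_atoms, 3)`` coordinate array in nanometres and optional
frame times in picoseconds.  Reading goes through MDAnalysis, so any
structure/trajectory pair it understands (PDB, GRO, XTC, DCD, TRR, ...)
works; MDAnalysis' Angstrom convention is converted to nm on the way in.

Replica organization is declared, not inferred: a YAML manifest maps
condition -> run -> replica -> file paths, and :func:`load_manifest`
returns one :class:`ReplicaSet` per condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "Ensemble",
    "ReplicaSet",
    "read_structure",
    "read_trajectory",
    "subsample",
    "load_manifest",
    "write_structure",
    "write_trajectory",
]

A_PER_NM = 10.0


@dataclass
class Ensemble:
    """Atoms + frames, tagged with condition/run/replica labels.

    Coordinates are in nm; times in ps.  ``charges`` is None unless the
    source format carried partial charges or they were attached later
    (e.g. by the copper-center patcher).
    """

    names: np.ndarray           # (n_atoms,) str
    elements: np.ndarray        # (n_atoms,) str ('' if unknown)
    resids: np.ndarray          # (n_atoms,) int
    resnames: np.ndarray        # (n_atoms,) str
    masses: np.ndarray          # (n_atoms,) float, amu
    coords: np.ndarray          # (n_frames, n_atoms, 3) float, nm
    charges: np.ndarray | None = None   # (n_atoms,) float, e
    times: np.ndarray | None = None     # (n_frames,) float, ps
    condition: str = ""
    run: str = ""
    replica: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (n_frames, n_atoms, 3), got {self.coords.shape}")
        if self.coords.shape[1] != len(self.names):
            raise ValueError(
                f"frame atom count {self.coords.shape[1]} != topology {len(self.names)}"
            )
        self.masses = np.asarray(self.masses, dtype=float)
        if np.any(self.masses <= 0):
            raise ValueError("all atom masses must be positive")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != self.n_frames:
                raise ValueError("times length != frame count")
            if self.n_frames > 1 and np.any(np.diff(self.times) <= 0):
                raise ValueError("frame times must be strictly increasing")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def label(self) -> str:
        return "/".join(x for x in (self.condition, self.run, self.replica) if x)

    def with_frames(self, coords, times=None) -> "Ensemble":
        return replace(self, coords=np.asarray(coords, dtype=float), times=times)

    def topology_equal(self, other: "Ensemble") -> bool:
        return (
            self.n_atoms == other.n_atoms
            and np.array_equal(self.resids, other.resids)
            and np.array_equal(self.names, other.names)
        )


@dataclass
class ReplicaSet:
    """All trajectories of one condition, sharing a topology."""

    condition: str
    members: list[Ensemble] = field(default_factory=list)

    def __post_init__(self):
        if self.members:
            ref = self.members[0]
            keys = set()
            for m in self.members:
                if not ref.topology_equal(m):
                    raise ValueError(
                        f"replica {m.label!r} topology differs from {ref.label!r}"
                    )
                key = (m.run, m.replica)
                if key in keys:
                    raise ValueError(f"duplicate replica id {key} in condition {self.condition!r}")
                keys.add(key)

    def __iter__(self):
        return iter(self.members)

    def __len__(self):
        return len(self.members)

    @property
    def n_frames_total(self) -> int:
        return sum(m.n_frames for m in self.members)

    def pooled_coords(self) -> np.ndarray:
        return np.concatenate([m.coords for m in self.members], axis=0)


# -- reading ---------------------------------------------------------------


def _universe_topology(u):
    n = len(u.atoms)
    names = u.atoms.names.astype(str)
    try:
        elements = u.atoms.elements.astype(str)
    except Exception:
        elements = np.array([""] * n, dtype=object).astype(str)
    try:
        masses = u.atoms.masses.astype(float)
    except Exception:
        masses = np.ones(n)
    if np.any(~np.isfinite(masses)) or np.any(masses <= 0):
        masses = np.where(np.isfinite(masses) & (masses > 0), masses, 12.0)
    try:
        charges = u.atoms.charges.astype(float)
    except Exception:
        charges = None
    return names, elements, u.atoms.resids.astype(int), u.atoms.resnames.astype(str), masses, charges


def read_structure(path, condition: str = "", run: str = "", replica: str = "") -> Ensemble:
    """Read a single-frame structure file (PDB/GRO/...) into an Ensemble."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    if len(u.atoms) == 0:
        raise ValueError(f"{path}: no atoms")
    names, elements, resids, resnames, masses, charges = _universe_topology(u)
    coords = u.atoms.positions[None].astype(float) / A_PER_NM
    return Ensemble(
        names=names, elements=elements, resids=resids, resnames=resnames,
        masses=masses, coords=coords, charges=charges,
        condition=condition, run=run, replica=replica,
    )


def read_trajectory(topology: Ensemble, path, condition=None, run=None, replica=None) -> Ensemble:
    """Attach a multi-frame trajectory file to an existing topology.

    Frame atom counts must match the topology; frames are appended in
    file order, coordinates converted to nm, times (if the format has
    them) to ps.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(topology.n_atoms, trajectory=True)
        try:
            u.load_new(str(path))
        except Exception as exc:
            raise ValueError(f"{path}: could not read trajectory ({exc})") from exc
        if len(u.atoms) != topology.n_atoms:
            raise ValueError(
                f"{path}: {len(u.atoms)} atoms per frame, topology has {topology.n_atoms}"
            )
        frames, times = [], []
        for ts in u.trajectory:
            frames.append(ts.positions.astype(float) / A_PER_NM)
            times.append(float(ts.time))
    coords = np.stack(frames)
    times = np.asarray(times)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        times = None  # format without real time stamps
    return replace(
        topology, coords=coords, times=times,
        condition=topology.condition if condition is None else condition,
        run=topology.run if run is None else run,
        replica=topology.replica if replica is None else replica,
    )


def subsample(ens: Ensemble, stride: int | None = None,
              time_window: tuple[float, float] | None = None) -> Ensemble:
    """Select frames by stride and/or time window [t0, t1] (ps, inclusive)."""
    idx = np.arange(ens.n_frames)
    if time_window is not None:
        if ens.times is None:
            raise ValueError("time window requested but ensemble has no frame times")
        t0, t1 = time_window
        idx = idx[(ens.times[idx] >= t0) & (ens.times[idx] <= t1)]
    if stride is not None:
        if stride < 1:
            raise ValueError("stride must be >= 1")
        idx = idx[::stride]
    if idx.size == 0:
        raise ValueError("subsample selected no frames")
    times = ens.times[idx] if ens.times is not None else None
    return replace(ens, coords=ens.coords[idx], times=times)


# -- writing (used by the synthetic generator) -----------------------------


def write_structure(ens: Ensemble, path, frame: int = 0) -> None:
    """Write one frame as a PDB file (coordinates nm -> A)."""
    import MDAnalysis as mda

    u = mda.Universe.empty(
        ens.n_atoms, n_residues=len(np.unique(ens.resids)),
        atom_resindex=np.unique(ens.resids, return_inverse=True)[1],
        trajectory=True,
    )
    u.add_TopologyAttr("names", ens.names)
    u.add_TopologyAttr("elements", ens.elements)
    u.add_TopologyAttr("resids", np.unique(ens.resids))
    u.add_TopologyAttr("resnames", [
        ens.resnames[np.searchsorted(ens.resids, r)] for r in np.unique(ens.resids)
    ])
    u.add_TopologyAttr("masses", ens.masses)
    u.atoms.positions = ens.coords[frame] * A_PER_NM
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(ens: Ensemble, path, dt_ps: float = 100.0) -> None:
    """Write all frames as an XTC (or any MDAnalysis-writable) trajectory."""
    import MDAnalysis as mda

    u = mda.Universe.empty(ens.n_atoms, trajectory=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=ens.n_atoms) as w:
            for i in range(ens.n_frames):
                u.atoms.positions = ens.coords[i] * A_PER_NM
                u.trajectory.ts.time = float(ens.times[i]) if ens.times is not None else i * dt_ps
                u.trajectory.ts.frame = i
                w.write(u.atoms)


# -- manifest --------------------------------------------------------------


def load_manifest(path, time_window=None, stride=None) -> dict[str, ReplicaSet]:
    """Load a replica-organization manifest into ReplicaSets per condition.

    Manifest layout (paths relative to the manifest file)::

        structure: structure.pdb
        conditions:
          apo:
            reA: {r1: apo_reA_r1.xtc, r2: ...}
          holo:
            reA: {...}
    """
    from pathlib import Path

    path = Path(path)
    with open(path) as fh:
        man = yaml.safe_load(fh)
    base = path.parent
    top = read_structure(base / man["structure"])
    out = {}
    for cond, runs in man["conditions"].items():
        members = []
        for run, reps in runs.items():
            for rep, traj in reps.items():
                traj_path = base / traj
                if not traj_path.exists():
                    raise FileNotFoundError(f"manifest references missing trajectory {traj_path}")
                ens = read_trajectory(top, traj_path, condition=cond, run=run, replica=str(rep))
                if time_window is not None or stride is not None:
                    ens = subsample(ens, stride=stride, time_window=time_window)
                members.append(ens)
        out[cond] = ReplicaSet(cond, members)
    return out
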