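"""Synthetic multi-domain ensembles with controllable condition effects.

The generator emulates the statistical structure of a two-condition
(apo/holo) replica-MD study of a multi-domain protein: rigid-ish domains
connected by flexible linkers, whose centers of mass fluctuate around
anchors with AR(1) frame-to-frame autocorrelation; a second condition can
shift per-domain mean positions, rescale the spread of the regulatory
tail (the compact-vs-extended radius-of-gyration regimes), and override
the contact propensity of designated residue pairs.  Each condition is
sampled as ``n_runs x n_replicas`` independent trajectories, mirroring
the two replica-exchange rounds of six replicas each used in the study
design this package targets (12 trajectories per condition).

Every stochastic choice flows from one integer seed, so a fixed spec
regenerates bit-identical coordinates and files.

The default fixture is a ~1/7-scale miniature of the 17-segment ATP7B
layout with the same segment names, small enough to run the full
pipeline in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .domains import DomainMap, Segment
from .ensembles import Ensemble, ReplicaSet, write_structure, write_trajectory

__all__ = [
    "SyntheticSpec",
    "ContactOverride",
    "scaled_atp7b_map",
    "atp7b_fixture",
    "build_topology",
    "domain_com_series",
    "generate_replica",
    "generate_ensembles",
    "generate",
]

CONTACT_PLACEMENT_NM = 0.35   # inter-atom distance realized for a programmed contact


@dataclass(frozen=True)
class ContactOverride:
    """Force residue pair (res_i, res_j) into contact with per-condition probability."""

    res_i: int
    res_j: int
    probability: dict  # condition -> per-frame contact probability


@dataclass
class SyntheticSpec:
    """Full parameterization of a two-condition synthetic ensemble."""

    dmap: DomainMap
    anchors: dict                 # segment name -> (3,) anchor position, nm (domains only)
    sigma: dict | float = 0.2     # per-domain COM fluctuation, nm
    phi: float = 0.8              # AR(1) frame autocorrelation of domain COMs
    linker_sigma: float = 0.1     # linker bead jitter, nm
    offsets: dict = field(default_factory=dict)      # condition -> {domain: (3,) mean shift, nm}
    tail_scale: dict = field(default_factory=dict)   # condition -> radial scale of tail anchors
    tail_domains: tuple = ()      # domains whose anchors the tail scale applies to
    contact_overrides: tuple[ContactOverride, ...] = ()
    conditions: tuple = ("apo", "holo")
    n_runs: int = 2
    n_replicas: int = 6
    n_frames: int = 200
    dt_ps: float = 100.0
    atom_mass: float = 12.0
    seed: int = 0

    def __post_init__(self):
        if abs(self.phi) >= 1:
            raise ValueError("|phi| must be < 1")
        if min(self.n_runs, self.n_replicas, self.n_frames) < 1:
            raise ValueError("counts must be >= 1")
        if isinstance(self.sigma, dict):
            if any(s < 0 for s in self.sigma.values()):
                raise ValueError("sigma must be >= 0")
        elif self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def sigma_of(self, segment: str) -> float:
        if isinstance(self.sigma, dict):
            return float(self.sigma.get(segment, 0.2))
        return float(self.sigma)

    def run_names(self):
        return [f"re{chr(ord('A') + i)}" for i in range(self.n_runs)]


# -- scaled domain map -----------------------------------------------------

# segment intervals of the full-size map in sequence order (name, length)
_SEQUENCE_ORDER = [
    ("N-terminal peptide", 52), ("MBD1", 69), ("MBD1-MBD2 linker", 17),
    ("MBD2", 68), ("MBD2-MBD3 linker", 46), ("MBD3", 71),
    ("MBD3-MBD4 linker", 31), ("MBD4", 68), ("MBD4-MBD5 linker", 61),
    ("MBD5", 68), ("MBD5-MBD6 linker", 8), ("MBD6", 68),
    ("MBD6-M linker", 11), ("M domain", 143), ("A domain", 129),
    ("M domain", 88), ("P domain", 32), ("N domain", 160),
    ("P domain", 110), ("M domain", 74),
]

_LINKERS = {n for n, _ in _SEQUENCE_ORDER if "linker" in n}


def scaled_atp7b_map(scale: float = 7.0) -> DomainMap:
    """ATP7B-like 17-segment map with every interval shrunk ~``scale``-fold.

    Keeps segment names, sequence order and the discontinuous M (3
    intervals) and P (2 intervals) domains; residues are renumbered
    consecutively from 1.  Composite groups are rebuilt on the scaled
    numbering.
    """
    intervals: dict[str, list] = {}
    pos = 1
    for name, length in _SEQUENCE_ORDER:
        n = max(3, round(length / scale))
        intervals.setdefault(name, []).append((pos, pos + n - 1))
        pos += n
    segs = []
    seen = []
    for name, _ in _SEQUENCE_ORDER:
        if name in seen:
            continue
        seen.append(name)
        segs.append(Segment(name, tuple(intervals[name]),
                            "linker" if name in _LINKERS else "domain"))
    first = {n: rs[0][0] for n, rs in intervals.items()}
    last = {n: rs[-1][1] for n, rs in intervals.items()}
    comps = {
        "MBD1-3": ((first["MBD1"], last["MBD3"]),),
        "MBD1-4": ((first["MBD1"], last["MBD4"]),),
        "MBD1-6": ((first["MBD1"], last["MBD6"]),),
        "N-terminal tail": ((first["N-terminal peptide"], last["MBD6-M linker"]),),
        "core": ((first["M domain"], pos - 1),),
        "M+P": tuple(sorted(intervals["M domain"] + intervals["P domain"])),
    }
    return DomainMap(segs, (1, pos - 1), comps)


# -- topology --------------------------------------------------------------

# per-residue pseudo-atoms: backbone carbon, side-chain carbon, one hydrogen
_ATOM_TEMPLATE = [
    ("CA", "C", np.array([0.0, 0.0, 0.0])),
    ("CB", "C", np.array([0.10, 0.05, 0.0])),
    ("HB", "H", np.array([0.05, -0.08, 0.08])),
]


def build_topology(dmap: DomainMap, atom_mass: float = 12.0) -> Ensemble:
    """Flat pseudo-atom topology (3 atoms/residue) over a domain map."""
    names, elements, resids, resnames = [], [], [], []
    lo, hi = dmap.sequence_span
    for r in range(lo, hi + 1):
        seg = dmap.segment_of(r)
        rn = "GLY" if "linker" in seg else "ALA"
        for an, el, _off in _ATOM_TEMPLATE:
            names.append(an)
            elements.append(el)
            resids.append(r)
            resnames.append(rn)
    n = len(names)
    return Ensemble(
        names=np.array(names), elements=np.array(elements),
        resids=np.array(resids), resnames=np.array(resnames),
        masses=np.full(n, atom_mass),
        coords=np.zeros((1, n, 3)),
    )


def _residue_grid(n: int, spacing: float = 0.5) -> np.ndarray:
    """Compact cubic-lattice layout of n residues, centered on the origin."""
    side = math.ceil(n ** (1 / 3))
    pts = []
    for i in range(n):
        pts.append((i % side, (i // side) % side, i // (side * side)))
    pts = np.asarray(pts, float) * spacing
    return pts - pts.mean(axis=0)


# -- stochastic core -------------------------------------------------------


def domain_com_series(rng: np.random.Generator, n_frames: int,
                      anchor: np.ndarray, sigma: float, phi: float) -> np.ndarray:
    """Stationary AR(1) center-of-mass track around an anchor.

    Each coordinate follows x_t = phi * x_{t-1} + sqrt(1-phi^2) * sigma * eps,
    initialized from the stationary distribution, so the marginal spread
    is ``sigma`` at every frame and the lag-1 autocorrelation is ``phi``.
    This process is the stochastic core of the generator: the atomic
    frames are rigid placements around exactly these tracks.
    """
    anchor = np.asarray(anchor, float)
    if sigma == 0:
        return np.tile(anchor, (n_frames, 1))
    x = np.empty((n_frames, 3))
    x[0] = rng.normal(0.0, sigma, 3)
    innov = rng.normal(0.0, sigma * math.sqrt(1 - phi * phi), (n_frames - 1, 3))
    for t in range(1, n_frames):
        x[t] = phi * x[t - 1] + innov[t - 1]
    return anchor + x


def _effective_anchors(spec: SyntheticSpec, condition: str) -> dict:
    """Anchors after applying tail scaling and per-domain condition offsets."""
    scale = float(spec.tail_scale.get(condition, 1.0))
    offsets = spec.offsets.get(condition, {})
    core_names = [n for n in spec.anchors if n not in spec.tail_domains]
    centroid = (np.mean([spec.anchors[n] for n in core_names], axis=0)
                if core_names else np.zeros(3))
    out = {}
    for name, anchor in spec.anchors.items():
        a = np.asarray(anchor, float)
        if name in spec.tail_domains and scale != 1.0:
            a = centroid + scale * (a - centroid)
        out[name] = a + np.asarray(offsets.get(name, (0.0, 0.0, 0.0)), float)
    return out


def generate_replica(spec: SyntheticSpec, condition: str, run: str, replica: str,
                     topology: Ensemble | None = None) -> Ensemble:
    """Generate one trajectory (all frames) for one (condition, run, replica)."""
    top = topology if topology is not None else build_topology(spec.dmap, spec.atom_mass)
    ci = list(spec.conditions).index(condition)
    ri = spec.run_names().index(run)
    pi = int(replica.lstrip("r")) if str(replica).startswith("r") else int(replica)
    rng = np.random.default_rng([int(spec.seed) % (2 ** 31), ci, ri, pi])

    dmap = spec.dmap
    anchors = _effective_anchors(spec, condition)
    nf = spec.n_frames
    coords = np.zeros((nf, top.n_atoms, 3))

    atom_off = np.array([off for _, _, off in _ATOM_TEMPLATE])
    domains = [s for s in dmap.segments if s.category == "domain"]

    # per-domain rigid placement around AR(1) COM tracks
    ca_pos: dict[int, np.ndarray] = {}   # residue -> (nf, 3) CA track
    for seg in domains:
        track = domain_com_series(rng, nf, anchors[seg.name],
                                  spec.sigma_of(seg.name), spec.phi)
        res = seg.residues()
        grid = _residue_grid(len(res))
        for k, r in enumerate(res):
            ca = track + grid[k]
            ca_pos[int(r)] = ca

    # linkers: interpolate between the CA tracks of the flanking residues
    for seg in dmap.segments:
        if seg.category != "linker":
            continue
        for a, b in seg.ranges:
            left, right = a - 1, b + 1
            if left not in ca_pos or right not in ca_pos:
                raise ValueError(f"linker {seg.name!r} is not flanked by domains")
            for r in range(a, b + 1):
                f = (r - left) / (right - left)
                base = (1 - f) * ca_pos[left] + f * ca_pos[right]
                ca_pos[r] = base + rng.normal(0.0, spec.linker_sigma, (nf, 3))

    for r, ca in ca_pos.items():
        base = 3 * (r - dmap.sequence_span[0])
        for k in range(3):
            coords[:, base + k, :] = ca + atom_off[k]

    # programmed contacts: move residue j next to residue i in chosen frames
    for ov in spec.contact_overrides:
        p = float(ov.probability.get(condition, 0.0))
        hit = rng.random(nf) < p
        if not hit.any():
            continue
        bi = 3 * (ov.res_i - dmap.sequence_span[0])
        bj = 3 * (ov.res_j - dmap.sequence_span[0])
        target = coords[hit, bi, :] + np.array([CONTACT_PLACEMENT_NM, 0.0, 0.0])
        shift = target - coords[hit, bj, :]
        for k in range(3):
            coords[hit, bj + k, :] += shift

    times = np.arange(nf) * spec.dt_ps
    return replace(top, coords=coords, times=times,
                   condition=condition, run=run, replica=str(replica))


def generate_ensembles(spec: SyntheticSpec) -> dict[str, ReplicaSet]:
    """All trajectories of all conditions, in memory, as ReplicaSets."""
    top = build_topology(spec.dmap, spec.atom_mass)
    out = {}
    for cond in spec.conditions:
        members = [
            generate_replica(spec, cond, run, f"r{p + 1}", top)
            for run in spec.run_names()
            for p in range(spec.n_replicas)
        ]
        out[cond] = ReplicaSet(cond, members)
    return out


def generate(spec: SyntheticSpec, outdir) -> dict:
    """Write structure + per-replica trajectories + manifest to ``outdir``.

    Emits ``structure.pdb``, one XTC per (condition, run, replica) and a
    ``manifest.yaml`` in the layout :func:`domaindyn.ensembles.load_manifest`
    reads.  Returns the manifest dict.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sets = generate_ensembles(spec)
    first = next(iter(sets.values())).members[0]
    write_structure(first, outdir / "structure.pdb")
    manifest: dict = {"structure": "structure.pdb", "conditions": {}}
    for cond, rset in sets.items():
        conds = manifest["conditions"].setdefault(cond, {})
        for ens in rset:
            fname = f"{cond}_{ens.run}_{ens.replica}.xtc"
            write_trajectory(ens, outdir / fname, spec.dt_ps)
            conds.setdefault(ens.run, {})[ens.replica] = fname
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


# -- default fixture -------------------------------------------------------

# anchor layout (nm): catalytic core around the origin, the regulatory tail
# fanned out; adjacent anchors are far enough apart that baseline contacts
# across segments are rare
_FIXTURE_ANCHORS = {
    "M domain": (0.0, 0.0, 0.0),
    "A domain": (3.0, 0.0, 0.5),
    "P domain": (0.0, 3.0, 0.5),
    "N domain": (3.0, 3.0, 1.0),
    "MBD6": (-3.0, 0.0, 1.0),
    "MBD5": (-3.0, 3.0, 1.5),
    "MBD4": (-4.5, 4.5, 2.0),
    "MBD3": (-6.0, 6.0, 2.5),
    "MBD2": (-7.5, 7.5, 3.0),
    "MBD1": (-9.0, 9.0, 3.5),
    "N-terminal peptide": (-10.5, 10.5, 4.0),
}

_TAIL_DOMAINS = ("N-terminal peptide", "MBD1", "MBD2", "MBD3", "MBD4", "MBD5", "MBD6")

# holo-like preset: MBD2/MBD3 move away from the core, MBD5 toward the
# M domain, and the tail extends — the qualitative effect pattern the
# study design probes
_HOLO_OFFSETS = {
    "MBD2": (-1.0, 1.0, 0.0),
    "MBD3": (-1.0, 1.0, 0.0),
    "MBD5": (1.0, -1.0, -0.5),
}


def atp7b_fixture(n_frames: int = 200, n_replicas: int = 6, n_runs: int = 2,
                  seed: int = 0, effects: bool = True, phi: float = 0.8,
                  sigma: float = 0.2, scale: float = 7.0) -> SyntheticSpec:
    """Miniature ATP7B-like spec: 17 segments, ~200 residues, ~600 atoms.

    ``effects=True`` applies the holo-like preset (MBD2/MBD3 further from
    the core, MBD5 closer, extended tail, shifted contact propensities);
    ``effects=False`` makes the two conditions statistically exchangeable
    (the null configuration used for calibration).
    """
    dmap = scaled_atp7b_map(scale)

    def mid(seg: str) -> int:
        a, b = dmap.group_intervals(seg)[0]
        return (a + b) // 2

    overrides = ()
    offsets: dict = {}
    tail_scale: dict = {}
    if effects:
        offsets = {"holo": {k: np.asarray(v) for k, v in _HOLO_OFFSETS.items()}}
        tail_scale = {"holo": 1.25}
        overrides = (
            # MBD5–A domain interface strengthens with copper bound
            ContactOverride(mid("MBD5"), mid("A domain"), {"apo": 0.1, "holo": 0.6}),
            # MBD2–MBD3 interface weakens
            ContactOverride(mid("MBD2"), mid("MBD3"), {"apo": 0.5, "holo": 0.15}),
        )
    return SyntheticSpec(
        dmap=dmap,
        anchors={k: np.asarray(v, float) for k, v in _FIXTURE_ANCHORS.items()},
        sigma=sigma, phi=phi,
        offsets=offsets, tail_scale=tail_scale, tail_domains=_TAIL_DOMAINS,
        contact_overrides=overrides,
        n_runs=n_runs, n_replicas=n_replicas, n_frames=n_frames, seed=seed,
    )
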