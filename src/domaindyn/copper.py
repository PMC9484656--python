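"""Cu(I)-bis-cysteinate center construction and geometry validation.

Each metal-binding domain carries a CXXC motif whose two cysteine
sulfurs bi-coordinate a Cu(I) ion linearly.  :func:`build_center` patches
a topology: it strips thiol hydrogens, adds a Cu pseudo-atom midway
between the two SG atoms, assigns S and Cu partial charges from a
user-supplied parameter block, and redistributes the residual charge
uniformly over all remaining atoms of the two cysteinates so that the
complete center carries a total charge of exactly −1 e.

The numeric bond/angle force-field parameters of such centers are not
re-derived here; the charge table defaults shipped in
:data:`DEFAULT_CENTER_PARAMS` are placeholders for pipeline testing and
are not authoritative — supply a parameter config for production use.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .ensembles import Ensemble
from .geometry import SeriesPerFrame

__all__ = [
    "CopperCenter",
    "CenterGeometrySeries",
    "build_center",
    "validate_geometry",
    "DEFAULT_CENTER_PARAMS",
    "CENTER_TOTAL_CHARGE",
]

CENTER_TOTAL_CHARGE = -1.0

# Placeholder electrostatics for pipeline testing (not authoritative):
# S and Cu point charges of a linear Cu(I)-bis-thiolate center.
DEFAULT_CENTER_PARAMS = {
    "q_S": -0.60,
    "q_Cu": 0.40,
    "cu_name": "CU",
    "cu_element": "Cu",
    "cu_mass": 63.546,
}


@dataclass
class CopperCenter:
    """Bookkeeping for one patched Cu(I)-bis-cysteinate center."""

    label: str
    cys_a: int
    cys_b: int
    cu_index: int                 # atom index of the Cu pseudo-atom
    atom_indices: np.ndarray      # all atoms of the center (both Cys + Cu)
    s_indices: tuple[int, int]    # the two SG atoms

    def total_charge(self, charges: np.ndarray) -> float:
        return float(charges[self.atom_indices].sum())


@dataclass
class CenterGeometrySeries:
    """Per-frame Cu–S distances (nm) and the S–Cu–S angle (degrees)."""

    label: str
    d_cu_s1: np.ndarray
    d_cu_s2: np.ndarray
    angle_deg: np.ndarray

    def __post_init__(self):
        for d in (self.d_cu_s1, self.d_cu_s2):
            if np.any(d <= 0):
                raise ValueError("Cu–S distances must be positive")
        if np.any((self.angle_deg < 0) | (self.angle_deg > 180)):
            raise ValueError("angles must lie in [0, 180] degrees")

    def is_linear(self, tolerance_deg: float = 30.0) -> bool:
        """True when the mean S–Cu–S angle is within tolerance of 180 deg."""
        return bool(abs(180.0 - self.angle_deg.mean()) <= tolerance_deg)


_THIOL_H = {"HG", "HG1", "HSG"}


def _sg_index(ens: Ensemble, resid: int) -> int:
    resnames_ok = {"CYS", "CYM", "CYX", "CYS2"}
    mask = (ens.resids == resid) & (ens.names == "SG")
    idx = np.flatnonzero(mask)
    if idx.size != 1:
        raise ValueError(f"residue {resid}: expected exactly one SG atom, found {idx.size}")
    rn = str(ens.resnames[idx[0]]).upper()
    if rn not in resnames_ok:
        raise ValueError(f"residue {resid} ({rn}) is not a cysteine/cysteinate")
    return int(idx[0])


def build_center(ens: Ensemble, cys_a: int, cys_b: int,
                 params: dict | None = None, label: str = "",
                 existing: list[CopperCenter] | None = None,
                 spread: str = "uniform",
                 ) -> tuple[Ensemble, CopperCenter]:
    """Patch two cysteine(ate) residues into a Cu(I)-bis-cysteinate center.

    Thiol hydrogens (if any) are removed, a Cu atom is appended bonded
    midway between the two SG atoms, S and Cu charges come from
    ``params``, and the residual is spread over the remaining atoms of
    the two residues so the center totals exactly −1 e — uniformly by
    default, or proportionally to each atom's |charge| with
    ``spread="proportional"`` (falls back to uniform when all eligible
    charges are zero).

    Returns the patched ensemble (topology + all frames) and the
    :class:`CopperCenter` record.  Residues already used by a center in
    ``existing`` are rejected.
    """
    p = {**DEFAULT_CENTER_PARAMS, **(params or {})}
    if existing:
        used = {r for c in existing for r in (c.cys_a, c.cys_b)}
        if cys_a in used or cys_b in used:
            raise ValueError(f"residue {cys_a if cys_a in used else cys_b} already in a copper center")
    if cys_a == cys_b:
        raise ValueError("a center needs two distinct cysteines")

    # drop thiol hydrogens of the two residues (cysteinates are deprotonated)
    drop = np.flatnonzero(np.isin(ens.resids, [cys_a, cys_b]) & np.isin(ens.names, list(_THIOL_H)))
    keep = np.setdiff1d(np.arange(ens.n_atoms), drop)
    charges = ens.charges if ens.charges is not None else np.zeros(ens.n_atoms)
    ens = replace(
        ens,
        names=ens.names[keep], elements=ens.elements[keep],
        resids=ens.resids[keep], resnames=ens.resnames[keep],
        masses=ens.masses[keep], charges=charges[keep],
        coords=ens.coords[:, keep, :],
    )

    sg_a, sg_b = _sg_index(ens, cys_a), _sg_index(ens, cys_b)
    n = ens.n_atoms
    cu_xyz = 0.5 * (ens.coords[:, sg_a, :] + ens.coords[:, sg_b, :])

    patched = replace(
        ens,
        names=np.append(ens.names, p["cu_name"]),
        elements=np.append(ens.elements, p["cu_element"]),
        resids=np.append(ens.resids, ens.resids[sg_a]),
        resnames=np.append(ens.resnames, ens.resnames[sg_a]),
        masses=np.append(ens.masses, p["cu_mass"]),
        charges=np.append(ens.charges, p["q_Cu"]),
        coords=np.concatenate([ens.coords, cu_xyz[:, None, :]], axis=1),
    )
    patched.charges[[sg_a, sg_b]] = p["q_S"]

    member = np.isin(patched.resids, [cys_a, cys_b])
    member[n] = True  # the Cu atom
    center_idx = np.flatnonzero(member)
    spread_idx = np.setdiff1d(center_idx, [sg_a, sg_b, n])
    if spread_idx.size == 0:
        raise ValueError("center has no atoms to carry the redistributed charge")
    residual = CENTER_TOTAL_CHARGE - patched.charges[center_idx].sum() \
        + patched.charges[spread_idx].sum()
    if spread == "proportional" and np.abs(patched.charges[spread_idx]).sum() > 0:
        w = np.abs(patched.charges[spread_idx])
        patched.charges[spread_idx] = residual * w / w.sum()
    elif spread in ("uniform", "proportional"):
        patched.charges[spread_idx] = residual / spread_idx.size
    else:
        raise ValueError("spread must be 'uniform' or 'proportional'")

    center = CopperCenter(label or f"Cys{cys_a}-Cys{cys_b}", cys_a, cys_b,
                          n, center_idx, (sg_a, sg_b))
    assert abs(center.total_charge(patched.charges) - CENTER_TOTAL_CHARGE) < 1e-10
    return patched, center


def validate_geometry(ens: Ensemble, center: CopperCenter) -> CenterGeometrySeries:
    """Cu–S distances and S–Cu–S angle for every frame of a patched ensemble."""
    s1, s2 = center.s_indices
    cu = center.cu_index
    if cu >= ens.n_atoms:
        raise ValueError("center atoms missing from ensemble")
    v1 = ens.coords[:, s1, :] - ens.coords[:, cu, :]
    v2 = ens.coords[:, s2, :] - ens.coords[:, cu, :]
    d1 = np.linalg.norm(v1, axis=1)
    d2 = np.linalg.norm(v2, axis=1)
    cosang = np.einsum("fs,fs->f", v1, v2) / (d1 * d2)
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return CenterGeometrySeries(center.label, d1, d2, angle)
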