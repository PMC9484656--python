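"""Coordinate geometry over ensembles.

Centers of mass, inter-selection COM distances, mass-weighted radius of
gyration, selective Kabsch superposition, RMSD, 2D free-energy surfaces
over collective-variable pairs (e.g. Rg vs RMSD of the regulatory tail),
site distances (e.g. copper-binding cysteine sulfurs to a candidate
ligand side chain), and logarithmic-fit equilibration detection.

All lengths are nm, times ps; free energies are in units of kT at the
recorded temperature and are relative to the global minimum of the
surface (min over occupied bins = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

from .ensembles import Ensemble

__all__ = [
    "SeriesPerFrame",
    "FreeEnergySurface",
    "center_of_mass",
    "com_distance",
    "radius_of_gyration",
    "superpose",
    "rmsd",
    "fes_2d",
    "combine_fes",
    "site_distance",
    "fit_equilibration",
]

SIM_TEMPERATURE_K = 303.15


@dataclass
class SeriesPerFrame:
    """One scalar or 3-vector per frame, with units and source labels."""

    values: np.ndarray
    units: str = "nm"
    name: str = ""
    times: np.ndarray | None = None
    condition: str = ""
    run: str = ""
    replica: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self):
        return len(self.values)

    @property
    def label(self) -> str:
        return "/".join(x for x in (self.condition, self.run, self.replica) if x)

    def mean(self):
        return self.values.mean(axis=0)

    @classmethod
    def from_ensemble(cls, values, ens: Ensemble, name="", units="nm"):
        return cls(values=values, units=units, name=name, times=ens.times,
                   condition=ens.condition, run=ens.run, replica=ens.replica)


@dataclass
class FreeEnergySurface:
    """-ln of a 2D empirical density, in kT, zeroed at its minimum.

    Unoccupied bins are +inf; ``counts`` keeps the raw histogram so the
    surface can be renormalized or combined losslessly.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray   # (nx, ny), kT; +inf where unoccupied
    counts: np.ndarray        # (nx, ny) raw sample counts
    temperature: float = SIM_TEMPERATURE_K
    x_name: str = "x"
    y_name: str = "y"

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    def probabilities(self) -> np.ndarray:
        """exp(-F) over occupied bins, renormalized to sum to 1."""
        p = np.where(self.occupied, np.exp(-np.where(self.occupied, self.free_energy, 0.0)), 0.0)
        return p / p.sum()


def _selection_com(coords: np.ndarray, masses: np.ndarray, sel: np.ndarray) -> np.ndarray:
    sel = np.asarray(sel)
    if sel.size == 0:
        raise ValueError("empty selection")
    m = masses[sel]
    tot = m.sum()
    if tot <= 0:
        raise ValueError("selection has zero total mass")
    return np.einsum("fas,a->fs", coords[:, sel, :], m) / tot


def center_of_mass(ens: Ensemble, selection: np.ndarray) -> SeriesPerFrame:
    """Mass-weighted mean coordinate of ``selection``, per frame."""
    com = _selection_com(ens.coords, ens.masses, selection)
    return SeriesPerFrame.from_ensemble(com, ens, name="com", units="nm")


def com_distance(ens: Ensemble, sel_a: np.ndarray, sel_b: np.ndarray) -> SeriesPerFrame:
    """Euclidean distance between the COMs of two selections, per frame."""
    a = _selection_com(ens.coords, ens.masses, sel_a)
    b = _selection_com(ens.coords, ens.masses, sel_b)
    d = np.linalg.norm(a - b, axis=1)
    return SeriesPerFrame.from_ensemble(d, ens, name="com_distance")


def radius_of_gyration(ens: Ensemble, selection: np.ndarray) -> SeriesPerFrame:
    """Mass-weighted Rg = sqrt(sum m_i |r_i - r_com|^2 / sum m_i), per frame."""
    sel = np.asarray(selection)
    m = ens.masses[sel]
    com = _selection_com(ens.coords, ens.masses, sel)
    dr = ens.coords[:, sel, :] - com[:, None, :]
    rg = np.sqrt(np.einsum("fas,fas,a->f", dr, dr, m) / m.sum())
    return SeriesPerFrame.from_ensemble(rg, ens, name="rg")


def _kabsch(P: np.ndarray, Q: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted least-squares rotation R, translation pair mapping P -> Q.

    Returns (R, com_P, com_Q) such that (x - com_P) @ R + com_Q minimizes
    the weighted RMSD of P to Q.
    """
    wsum = w.sum()
    cP = (w[:, None] * P).sum(0) / wsum
    cQ = (w[:, None] * Q).sum(0) / wsum
    H = (P - cP).T @ (w[:, None] * (Q - cQ))
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    return R, cP, cQ


def superpose(ens: Ensemble, reference: Ensemble, fit_selection: np.ndarray,
              ref_frame: int = 0, mass_weighted: bool = True) -> Ensemble:
    """Rigid-body align every frame onto the reference by ``fit_selection``.

    The optimal (Kabsch) rotation+translation is computed on the fit
    selection and applied to all atoms of the frame.  Degenerate fits
    (fewer than 3 atoms, or collinear/coincident positions) are rejected.
    """
    sel = np.asarray(fit_selection)
    if sel.size < 3:
        raise ValueError("fit selection needs at least 3 atoms")
    ref = reference.coords[ref_frame][sel]
    if np.linalg.matrix_rank(ref - ref.mean(0), tol=1e-10) < 2:
        raise ValueError("degenerate (collinear/coincident) fit selection")
    w = ens.masses[sel] if mass_weighted else np.ones(sel.size)
    out = np.empty_like(ens.coords)
    for f in range(ens.n_frames):
        R, cP, cQ = _kabsch(ens.coords[f][sel], ref, w)
        out[f] = (ens.coords[f] - cP) @ R + cQ
    return replace(ens, coords=out)


def rmsd(ens: Ensemble, reference: Ensemble, measure_selection: np.ndarray,
         ref_frame: int = 0, fit_selection: np.ndarray | None = None,
         mass_weighted: bool = True) -> SeriesPerFrame:
    """Coordinate RMSD to a reference frame, per frame (nm).

    If ``fit_selection`` is given the ensemble is superposed on it first;
    otherwise coordinates are compared as-is (alignment assumed done).
    """
    if fit_selection is not None:
        ens = superpose(ens, reference, fit_selection, ref_frame, mass_weighted)
    sel = np.asarray(measure_selection)
    if sel.size == 0:
        raise ValueError("empty measure selection")
    ref = reference.coords[ref_frame][sel]
    d = ens.coords[:, sel, :] - ref[None]
    if mass_weighted:
        w = ens.masses[sel]
        vals = np.sqrt(np.einsum("fas,fas,a->f", d, d, w) / w.sum())
    else:
        vals = np.sqrt((d ** 2).sum(axis=(1, 2)) / sel.size)
    return SeriesPerFrame.from_ensemble(vals, ens, name="rmsd")


def fes_2d(x: SeriesPerFrame, y: SeriesPerFrame, bins: int | tuple = 50,
           temperature: float = SIM_TEMPERATURE_K,
           ranges=None, pad: float = 0.02) -> FreeEnergySurface:
    """2D free-energy surface F = -ln(p / p_max) in kT over two observables.

    Bins default to 50x50 over the observed data range padded by 2% per
    side; occupied-bin probabilities renormalize back to the empirical
    histogram exactly, and the global minimum is exactly 0.
    """
    xv, yv = np.asarray(x.values, float), np.asarray(y.values, float)
    if xv.shape != yv.shape:
        raise ValueError("x and y series must have equal length")
    if xv.size == 0:
        raise ValueError("no samples")
    if np.isscalar(bins):
        bins = (int(bins), int(bins))
    if bins[0] < 1 or bins[1] < 1:
        raise ValueError("bin counts must be positive")
    if ranges is None:
        def _pad(v):
            lo, hi = v.min(), v.max()
            span = (hi - lo) or 1e-9
            return lo - pad * span, hi + pad * span
        ranges = (_pad(xv), _pad(yv))
    counts, xe, ye = np.histogram2d(xv, yv, bins=bins, range=ranges)
    occ = counts > 0
    F = np.full_like(counts, np.inf)
    F[occ] = -np.log(counts[occ] / counts.max())
    return FreeEnergySurface(xe, ye, F, counts, temperature, x.name or "x", y.name or "y")


def combine_fes(xs: list[SeriesPerFrame], ys: list[SeriesPerFrame],
                bins: int | tuple = 50, temperature: float = SIM_TEMPERATURE_K,
                ranges=None) -> FreeEnergySurface:
    """Pool frames from several ensembles (each frame weight 1) and histogram."""
    if len(xs) != len(ys) or not xs:
        raise ValueError("need matching, non-empty lists of x and y series")
    units = {s.units for s in xs} | {s.units for s in ys}
    xcat = SeriesPerFrame(np.concatenate([s.values for s in xs]), name=xs[0].name, units=xs[0].units)
    ycat = SeriesPerFrame(np.concatenate([s.values for s in ys]), name=ys[0].name, units=ys[0].units)
    return fes_2d(xcat, ycat, bins=bins, temperature=temperature, ranges=ranges)


def site_distance(ens: Ensemble, atoms_a: np.ndarray, residue_b: int,
                  heavy_only: bool = True) -> SeriesPerFrame:
    """Distance from COM of an atom set to the COM of a residue's side chain.

    ``atoms_a`` is an explicit atom-index set (e.g. the copper-binding
    cysteine SG atoms of one MBD); the side chain of ``residue_b`` is all
    its atoms except backbone (N, CA, C, O, and hydrogens when
    ``heavy_only``).
    """
    from .domains import heavy_mask

    backbone = {"N", "CA", "C", "O", "H", "HA", "OXT"}
    mask = (np.asarray(ens.resids) == residue_b) & ~np.isin(ens.names, list(backbone))
    if heavy_only:
        mask &= heavy_mask(ens)
    sel_b = np.flatnonzero(mask)
    if sel_b.size == 0:
        raise ValueError(f"residue {residue_b} has no side-chain atoms")
    a = _selection_com(ens.coords, ens.masses, np.asarray(atoms_a))
    b = _selection_com(ens.coords, ens.masses, sel_b)
    d = np.linalg.norm(a - b, axis=1)
    return SeriesPerFrame.from_ensemble(d, ens, name=f"site_distance_{residue_b}")


def fit_equilibration(series: SeriesPerFrame,
                      derivative_threshold_nm_per_ns: float = 0.005):
    """Fit RMSD(t) = a*ln(t + t0) + b and locate the equilibration time.

    The time axis is shifted by one frame interval (t0) so the first frame
    does not sit at ln(0).  Equilibration is declared at the earliest time
    where the fitted derivative a/(t + t0) drops below the threshold
    (default 0.005 nm/ns, i.e. under 0.05 nm of drift per 10 ns); if the
    derivative never falls below it within positive time, None is
    returned for the equilibration time.

    Returns a dict with ``a``, ``b``, ``t0`` (ps), ``equilibration_time``
    (ps or None) and the fit ``residuals``.
    """
    v = np.asarray(series.values, float)
    if v.size < 10:
        raise ValueError("need at least 10 samples to fit equilibration")
    t = series.times
    if t is None:
        t = np.arange(v.size, dtype=float)
    t = np.asarray(t, float) - t[0]
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("times must be strictly increasing")
    t0 = float(np.median(dt))

    def model(tt, a, b):
        return a * np.log(tt + t0) + b

    import warnings
    from scipy.optimize import OptimizeWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OptimizeWarning)  # flat series: singular covariance
        (a, b), _ = curve_fit(model, t, v, p0=[0.1, float(v[0])], maxfev=10000)
    residuals = v - model(t, a, b)
    # earliest t with fitted derivative a/(t+t0) below threshold; the
    # derivative is monotone in t, so this is closed-form
    thr = derivative_threshold_nm_per_ns / 1000.0  # nm/ns -> nm/ps
    if thr <= 0:
        t_eq = float(t[0]) if a < 0 else None
    elif a <= 0:
        t_eq = float(t[0])  # flat or decreasing: equilibrated from the start
    else:
        t_star = a / thr - t0
        t_eq = float(max(t_star, t[0])) if t_star <= t[-1] else None
    return {"a": float(a), "b": float(b), "t0": t0,
            "equilibration_time": t_eq, "residuals": residuals}
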