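"""Replica-level condition comparison statistics.

The unit of statistical independence is the replica trajectory, not the
frame: frames within a trajectory are autocorrelated, so every test here
first reduces each replica to its trajectory-average value and then
compares the two groups of replica means (e.g. 12 apo vs 12 holo).

Two-sample comparisons are gated on Levene's test for equal variances
(Brown–Forsythe median-centred variant by default): when the variances
are compatible (Levene p >= alpha) a pooled-variance independent t-test
is used, otherwise Welch's t-test.  Both the branch taken and all
intermediate statistics are recorded in the output table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .domains import DomainMap, resolve_selection
from .ensembles import Ensemble, ReplicaSet
from . import geometry

__all__ = [
    "ReplicaSample",
    "replica_means",
    "compare",
    "all_pairs_distance_test",
    "axis_position_test",
    "cross_correlations",
    "DEFAULT_TEST_GROUPS",
]

# the ten groups compared pairwise: the six metal-binding domains + core domains
DEFAULT_TEST_GROUPS = ["MBD1", "MBD2", "MBD3", "MBD4", "MBD5", "MBD6",
                       "M domain", "A domain", "P domain", "N domain"]


@dataclass(frozen=True)
class ReplicaSample:
    """One trajectory-average value of one observable for one replica."""

    condition: str
    run: str
    replica: str
    observable: str
    value: float
    units: str = "nm"


def replica_means(series_list, observable: str = "",
                  time_window: tuple[float, float] | None = None) -> list[ReplicaSample]:
    """Trajectory-average of each replica's series -> one sample per replica."""
    out = []
    for s in series_list:
        vals = np.asarray(s.values, float)
        if time_window is not None:
            if s.times is None:
                raise ValueError("time window requested but series has no times")
            keep = (s.times >= time_window[0]) & (s.times <= time_window[1])
            vals = vals[keep]
        if vals.size == 0:
            raise ValueError(f"series {s.label!r}: empty after windowing")
        out.append(ReplicaSample(s.condition, s.run, s.replica,
                                 observable or s.name, float(vals.mean()), s.units))
    return out


def compare(apo: np.ndarray | list, holo: np.ndarray | list,
            alpha: float = 0.05, observable: str = "",
            levene_center: str = "median") -> dict:
    """Levene-gated two-sample t-test on replica means.

    Returns one comparison-table row: group means, difference
    (holo − apo), Levene p, the t branch used ("pooled" or "welch"),
    t statistic, two-sided p-value and the significance flag at alpha.
    """
    a = np.asarray([s.value if isinstance(s, ReplicaSample) else s for s in apo], float)
    h = np.asarray([s.value if isinstance(s, ReplicaSample) else s for s in holo], float)
    if a.size < 2 or h.size < 2:
        raise ValueError("need at least 2 replica samples per group")
    if np.ptp(a) == 0 and np.ptp(h) == 0 and a.mean() == h.mean():
        # identical constant groups: no variance, no difference
        lev_p, t, p, branch = 1.0, 0.0, 1.0, "pooled"
    else:
        lev_p = float(sps.levene(a, h, center=levene_center).pvalue)
        equal_var = lev_p >= alpha
        branch = "pooled" if equal_var else "welch"
        t, p = sps.ttest_ind(h, a, equal_var=equal_var)
        t, p = float(t), float(p)
    return {
        "observable": observable,
        "mean_apo": float(a.mean()),
        "mean_holo": float(h.mean()),
        "difference": float(h.mean() - a.mean()),
        "levene_p": lev_p,
        "t_branch": branch,
        "t": t,
        "p": p,
        "n_apo": int(a.size),
        "n_holo": int(h.size),
        "significant": bool(p < alpha),
        "alpha": alpha,
    }


def _replica_distance_means(rset: ReplicaSet, dmap: DomainMap, group_a: str, group_b: str,
                            time_window=None) -> list[ReplicaSample]:
    series = []
    for ens in rset:
        sel_a = resolve_selection(dmap, group_a, ens)
        sel_b = resolve_selection(dmap, group_b, ens)
        series.append(geometry.com_distance(ens, sel_a, sel_b))
    return replica_means(series, f"{group_a}–{group_b}", time_window)


def all_pairs_distance_test(apo: ReplicaSet, holo: ReplicaSet, dmap: DomainMap,
                            groups: list[str] | None = None, alpha: float = 0.05,
                            time_window=None) -> pd.DataFrame:
    """Replica-mean t-tests on COM distances for every unordered group pair.

    With the default ten groups (MBD1-6 and the M, A, P, N core domains)
    this yields 45 rows; ``significant`` flags raw p < alpha (no
    multiple-testing correction, matching the reporting convention of
    raw per-pair significance; apply BH downstream if desired).
    """
    groups = groups or DEFAULT_TEST_GROUPS
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            sa = _replica_distance_means(apo, dmap, ga, gb, time_window)
            sh = _replica_distance_means(holo, dmap, ga, gb, time_window)
            row = compare(sa, sh, alpha, observable=f"{ga}–{gb}")
            row["group_a"], row["group_b"] = ga, gb
            rows.append(row)
    return pd.DataFrame(rows)


def axis_position_test(apo: ReplicaSet, holo: ReplicaSet, dmap: DomainMap,
                       groups: list[str] | None = None, alpha: float = 0.05,
                       reference: Ensemble | None = None,
                       align_group: str = "M+P", time_window=None) -> pd.DataFrame:
    """Per-axis (x, y, z) COM position tests after shared superposition.

    Every trajectory is rigidly aligned onto one shared reference (the
    first apo replica's first frame by default) using ``align_group``
    (default "M+P", the membrane-embedded M domain plus the P domain, so
    x/y span the membrane plane and z its normal in the reference), then
    per-replica mean COM coordinates are compared axis by axis.
    """
    groups = groups or DEFAULT_TEST_GROUPS
    reference = reference or apo.members[0]
    fit_ref = resolve_selection(dmap, align_group, reference)
    rows = []
    samples: dict[tuple[str, str], list] = {}
    for rset in (apo, holo):
        for ens in rset:
            fit = resolve_selection(dmap, align_group, ens)
            aligned = geometry.superpose(ens, reference, fit)
            for g in groups:
                sel = resolve_selection(dmap, g, aligned)
                com = geometry.center_of_mass(aligned, sel)
                vals = com.values
                if time_window is not None and com.times is not None:
                    keep = (com.times >= time_window[0]) & (com.times <= time_window[1])
                    vals = vals[keep]
                mean = vals.mean(axis=0)
                for ax, name in enumerate("xyz"):
                    samples.setdefault((g, name), []).append(
                        ReplicaSample(ens.condition, ens.run, ens.replica,
                                      f"{g}:{name}", float(mean[ax])))
    for g in groups:
        for ax in "xyz":
            ss = samples[(g, ax)]
            sa = [s for s in ss if s.condition == apo.condition]
            sh = [s for s in ss if s.condition == holo.condition]
            row = compare(sa, sh, alpha, observable=f"{g}:{ax}")
            row["group"], row["axis"] = g, ax
            rows.append(row)
    return pd.DataFrame(rows)


def cross_correlations(position_samples: pd.DataFrame, rg_samples: pd.DataFrame,
                       alpha: float = 0.05):
    """Pearson cross-correlation of replica-average observables.

    ``position_samples``: tidy frame with columns (replica_key, observable,
    value) where observables are per-domain axis coordinates ("MBD2:x", ...);
    ``rg_samples``: same layout for radius-of-gyration observables
    ("Rg MBD1-3", ...).  All replicas of both conditions are pooled (the
    24-trajectory convention), one point per replica.  Returns (r, p,
    masked) DataFrames, ``masked`` holding r only where p < alpha.
    """
    pos = position_samples.pivot(index="replica_key", columns="observable", values="value")
    rg = rg_samples.pivot(index="replica_key", columns="observable", values="value")
    if not pos.index.equals(rg.index):
        rg = rg.loc[pos.index]
    if len(pos) < 3:
        raise ValueError("need at least 3 paired replica averages")
    r = pd.DataFrame(index=pos.columns, columns=rg.columns, dtype=float)
    p = r.copy()
    for po in pos.columns:
        for ro in rg.columns:
            x, y = pos[po].to_numpy(), rg[ro].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                raise ValueError(f"zero variance in observable {po if np.ptp(x) == 0 else ro!r}")
            res = sps.pearsonr(x, y)
            r.loc[po, ro] = float(res.statistic)
            p.loc[po, ro] = float(res.pvalue)
    masked = r.where(p < alpha)
    return r, p, masked


def benjamini_hochberg(pvals: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """BH step-up rejection mask; offered alongside the raw per-pair flags."""
    p = np.asarray(pvals, float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    thresh = np.flatnonzero(p[order] <= (np.arange(n) + 1) / n * alpha)
    out = np.zeros(n, dtype=bool)
    if thresh.size:
        out[order[: thresh.max() + 1]] = True
    return out
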