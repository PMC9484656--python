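"""Pipeline orchestration: manifest -> per-condition artifacts -> report.

``analyze`` drives the full comparison on a replica manifest: per
condition it computes tail Rg/RMSD series, the pooled free-energy
surface and the contact map; across conditions it computes the contact
difference map, the all-pairs COM-distance comparison table, the
per-axis position tests and the position/Rg cross-correlation matrix.
Every artifact is written as CSV plus a JSON summary that embeds the
full configuration, so any number in the output is traceable to the
parameters that produced it.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contacts, geometry, stats
from .domains import DomainMap, default_atp7b_map, resolve_selection
from .ensembles import ReplicaSet, load_manifest

__all__ = ["RunConfig", "analyze", "report"]

log = logging.getLogger("domaindyn")


@dataclass
class RunConfig:
    """Everything `analyze` needs, serializable into output metadata."""

    manifest: str
    domain_map: str = "default-atp7b"   # or a YAML path
    outdir: str = "artifacts"
    tail_group: str = "N-terminal tail"
    align_group: str = "M+P"
    contact_cutoff: float = contacts.DEFAULT_CUTOFF_NM
    contact_threshold: float = contacts.DEFAULT_THRESHOLD
    alpha: float = 0.05
    fes_bins: int = 50
    time_window: tuple | None = None
    test_groups: list = field(default_factory=lambda: list(stats.DEFAULT_TEST_GROUPS))
    seed: int = 0

    def load_map(self) -> DomainMap:
        if self.domain_map == "default-atp7b":
            return default_atp7b_map()
        return DomainMap.from_yaml(self.domain_map)


def _fes_to_csv(fes, path: Path) -> None:
    df = pd.DataFrame(fes.free_energy)
    df.index = pd.Index(0.5 * (fes.x_edges[:-1] + fes.x_edges[1:]), name=fes.x_name)
    df.columns = pd.Index(0.5 * (fes.y_edges[:-1] + fes.y_edges[1:]), name=fes.y_name)
    df.replace(np.inf, np.nan).to_csv(path)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            t0 = time.time()
            try:
                out = fn(*a, **k)
            except Exception as exc:
                raise RuntimeError(f"[stage:{name}] {exc}") from exc
            log.info("stage %s done in %.1fs", name, time.time() - t0)
            return out
        return wrapped
    return deco


@_stage("load")
def _load(cfg: RunConfig):
    tw = tuple(cfg.time_window) if cfg.time_window else None
    return load_manifest(cfg.manifest, time_window=tw)


@_stage("geometry")
def _geometry(cfg, dmap, sets, outdir):
    summary = {}
    rg_samples, pos_rows = [], []
    reference = next(iter(sets.values())).members[0]
    for cond, rset in sets.items():
        rows = []
        rg_series, rmsd_series = [], []
        for ens in rset:
            tail = resolve_selection(dmap, cfg.tail_group, ens)
            fit = resolve_selection(dmap, cfg.align_group, ens)
            rg = geometry.radius_of_gyration(ens, tail)
            rd = geometry.rmsd(ens, reference, tail, fit_selection=fit)
            rg_series.append(rg)
            rmsd_series.append(rd)
            rows.append(pd.DataFrame({
                "time_ps": ens.times if ens.times is not None else np.arange(ens.n_frames),
                "run": ens.run, "replica": ens.replica,
                "rg_nm": rg.values, "rmsd_nm": rd.values,
            }))
        pd.concat(rows).to_csv(outdir / f"series_{cond}.csv", index=False)
        fes = geometry.combine_fes(rg_series, rmsd_series, bins=cfg.fes_bins)
        _fes_to_csv(fes, outdir / f"fes_{cond}.csv")
        summary[cond] = {
            "n_trajectories": len(rset),
            "n_frames_total": rset.n_frames_total,
            "rg_mean_nm": float(np.mean([s.mean() for s in rg_series])),
            "fes_min_kT": 0.0,
        }
        for ens, s in zip(rset, rg_series):
            rg_samples.append({
                "replica_key": f"{cond}/{ens.run}/{ens.replica}",
                "observable": f"Rg {cfg.tail_group}", "value": float(s.mean()),
            })
    return summary, pd.DataFrame(rg_samples)


@_stage("contacts")
def _contacts(cfg, dmap, sets, outdir):
    maps = {}
    for cond, rset in sets.items():
        cmap = contacts.contact_frequency(rset, dmap, cutoff=cfg.contact_cutoff)
        contacts.threshold_map(cmap, cfg.contact_threshold).to_csv(
            outdir / f"contacts_{cond}.csv")
        maps[cond] = cmap
    conds = list(maps)
    diff = None
    if len(conds) == 2:
        diff = contacts.difference_map(maps[conds[1]], maps[conds[0]])
        diff.pairs().to_csv(outdir / "contacts_difference.csv", index=False)
        _plot_difference_map(diff, outdir / "contacts_difference.png")
    return maps, diff


def _plot_difference_map(diff, path: Path) -> None:
    """Render the signed contact-difference matrix (numbers live in the CSV)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    m = np.nan_to_num(diff.diff, nan=0.0)
    lim = max(np.abs(m).max(), 1e-6)
    extent = [diff.resids[0], diff.resids[-1]] * 2
    im = ax.imshow(m.T, origin="lower", cmap="seismic", vmin=-lim, vmax=lim,
                   extent=extent, interpolation="nearest")
    ax.set_xlabel("residue")
    ax.set_ylabel("residue")
    ax.set_title(f"contact frequency difference ({diff.label})")
    fig.colorbar(im, ax=ax, label="Δ frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@_stage("compare")
def _compare(cfg, dmap, sets, outdir):
    conds = list(sets)
    if len(conds) != 2:
        return None, None, None
    a, b = sets[conds[0]], sets[conds[1]]
    tw = tuple(cfg.time_window) if cfg.time_window else None
    dist = stats.all_pairs_distance_test(a, b, dmap, cfg.test_groups, cfg.alpha, tw)
    dist.to_csv(outdir / "distance_tests.csv", index=False)
    axis = stats.axis_position_test(a, b, dmap, cfg.test_groups, cfg.alpha,
                                    align_group=cfg.align_group, time_window=tw)
    axis.to_csv(outdir / "axis_tests.csv", index=False)
    return dist, axis, (a, b)


@_stage("xcorr")
def _xcorr(cfg, dmap, sets, rg_samples, outdir):
    pos_rows = []
    reference = next(iter(sets.values())).members[0]
    fit_ref = resolve_selection(dmap, cfg.align_group, reference)
    mbds = [g for g in cfg.test_groups if g.startswith("MBD")]
    rg_groups = [g for g in ("MBD1-3", "MBD1-4", "MBD1-6") if g in dmap.group_names()]
    rg_rows = []
    for cond, rset in sets.items():
        for ens in rset:
            fit = resolve_selection(dmap, cfg.align_group, ens)
            aligned = geometry.superpose(ens, reference, fit)
            key = f"{cond}/{ens.run}/{ens.replica}"
            for g in mbds:
                sel = resolve_selection(dmap, g, aligned)
                m = geometry.center_of_mass(aligned, sel).mean()
                for ax, name in enumerate("xyz"):
                    pos_rows.append({"replica_key": key, "observable": f"{g}:{name}",
                                     "value": float(m[ax])})
            for g in rg_groups:
                sel = resolve_selection(dmap, g, aligned)
                rg_rows.append({"replica_key": key, "observable": f"Rg {g}",
                                "value": float(geometry.radius_of_gyration(aligned, sel).mean())})
    if not rg_rows:
        return None
    r, p, masked = stats.cross_correlations(pd.DataFrame(pos_rows),
                                            pd.DataFrame(rg_rows), cfg.alpha)
    r.to_csv(outdir / "xcorr_r.csv")
    p.to_csv(outdir / "xcorr_p.csv")
    masked.to_csv(outdir / "xcorr_masked.csv")
    return r


def analyze(cfg: RunConfig) -> Path:
    """Run the full pipeline; returns the artifact directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dmap = cfg.load_map()
    sets = _load(cfg)
    geo_summary, rg_samples = _geometry(cfg, dmap, sets, outdir)
    maps, diff = _contacts(cfg, dmap, sets, outdir)
    dist, axis, _ = _compare(cfg, dmap, sets, outdir)
    _xcorr(cfg, dmap, sets, rg_samples, outdir)

    findings = []
    if dist is not None:
        for _, row in dist[dist["significant"]].iterrows():
            findings.append({
                "kind": "com_distance", "observable": row["observable"],
                "difference_nm": row["difference"], "t": row["t"], "p": row["p"],
            })
        for _, row in axis[axis["significant"]].iterrows():
            findings.append({
                "kind": "axis_position", "observable": row["observable"],
                "difference_nm": row["difference"], "t": row["t"], "p": row["p"],
            })
    summary = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "conditions": geo_summary,
        "n_significant": len(findings),
        "significant": sorted(findings, key=lambda f: (f["kind"], f["observable"])),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return outdir


def report(artifact_dir) -> str:
    """Render a plain-text summary of an artifact directory."""
    d = Path(artifact_dir)
    if not (d / "summary.json").exists():
        raise FileNotFoundError(f"no summary.json in {d}")
    with open(d / "summary.json") as fh:
        summary = json.load(fh)
    lines = ["domaindyn analysis report", "=" * 30]
    for cond, info in summary["conditions"].items():
        lines.append(f"{cond}: {info['n_trajectories']} trajectories, "
                     f"{info['n_frames_total']} frames, "
                     f"mean tail Rg {info['rg_mean_nm']:.2f} nm")
    sig = summary.get("significant", [])
    if sig:
        lines.append(f"\nSignificant condition differences ({len(sig)}):")
        lines.append(f"{'observable':<28}{'diff (nm)':>10}{'t':>8}{'p':>10}")
        for f in sig:
            lines.append(f"{f['observable']:<28}{f['difference_nm']:>10.3f}"
                         f"{f['t']:>8.2f}{f['p']:>10.2g}")
    else:
        lines.append("\nNo significant condition differences at the chosen alpha.")
    try:
        diff = pd.read_csv(d / "contacts_difference.csv")
        top = diff.reindex(diff["difference"].abs().sort_values(ascending=False).index).head(5)
        lines.append("\nLargest contact-frequency changes:")
        for _, r in top.iterrows():
            lines.append(f"  {int(r.res_i)}–{int(r.res_j)}: {r.difference:+.2f}")
    except FileNotFoundError:
        pass
    return "\n".join(lines)
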