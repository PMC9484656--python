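"""Monte-Carlo self-diagnostics of the replica-mean statistical machinery.

These experiments answer two questions any ensemble-comparison pipeline
must face before its p-values can be trusted:

* **Calibration** — with autocorrelated frames (AR(1), phi ~ 0.8) and no
  real condition difference, does the Levene-gated replica-mean t-test
  reject at its nominal rate?  Frame-level tests fail this badly; the
  replica-mean design is supposed to pass because whole trajectories,
  not frames, are the independent units.
* **Recovery** — is an injected effect (a mean COM shift, a contact
  propensity change) detected with high power and estimated without
  bias?

Both are driven by the synthetic generator's stochastic core
(:func:`domaindyn.synthetic.domain_com_series`, the process that places
every atom) so that what is being calibrated is exactly the statistics
the full pipeline computes.
"""

from __future__ import annotations

import math

import numpy as np

from . import contacts, stats, synthetic

__all__ = [
    "null_rejection_rate",
    "offset_recovery",
    "contact_difference_recovery",
    "expected_distance_differences",
]


def _replica_distance_mean(rng, n_frames, anchor_a, anchor_b, sigma, phi):
    a = synthetic.domain_com_series(rng, n_frames, anchor_a, sigma, phi)
    b = synthetic.domain_com_series(rng, n_frames, anchor_b, sigma, phi)
    return float(np.linalg.norm(a - b, axis=1).mean())


def null_rejection_rate(n_reps: int = 2000, n_frames: int = 200,
                        n_replicas: int = 6, n_runs: int = 2,
                        sigma: float = 0.2, phi: float = 0.8,
                        anchor_distance: float = 3.0, alpha: float = 0.05,
                        seed: int = 0) -> dict:
    """Type-I error of the Levene-gated replica-mean t-test under the null.

    Each repetition simulates the full replica layout (two conditions x
    n_runs x n_replicas trajectories) of a two-domain COM-distance
    observable with identical parameters in both conditions, reduces
    each trajectory to its mean, and runs :func:`domaindyn.stats.compare`.
    Returns the empirical rejection rate and its 95% binomial CI.
    """
    rng = np.random.default_rng(seed)
    anchor_a = np.zeros(3)
    anchor_b = np.array([anchor_distance, 0.0, 0.0])
    n_per = n_runs * n_replicas
    rejections = 0
    for _ in range(n_reps):
        means = [
            _replica_distance_mean(rng, n_frames, anchor_a, anchor_b, sigma, phi)
            for _ in range(2 * n_per)
        ]
        row = stats.compare(means[:n_per], means[n_per:], alpha)
        rejections += row["significant"]
    rate = rejections / n_reps
    half = 1.96 * math.sqrt(alpha * (1 - alpha) / n_reps)
    return {"rate": rate, "n_reps": n_reps, "alpha": alpha,
            "ci_low": alpha - half, "ci_high": alpha + half}


def offset_recovery(n_reps: int = 300, n_frames: int = 200,
                    n_replicas: int = 6, n_runs: int = 2,
                    sigma: float = 0.2, phi: float = 0.8,
                    anchor_distance: float = 3.0, offset: float = 1.0,
                    alpha: float = 0.05, seed: int = 1) -> dict:
    """Power and bias for an injected mean COM shift along x.

    Condition B places the second domain ``offset`` nm further along x,
    so the true COM-distance difference is ``offset``.  Returns the
    empirical detection power, the mean estimated difference, and the
    standard error of that mean across repetitions.
    """
    rng = np.random.default_rng(seed)
    anchor_a = np.zeros(3)
    anchor_b0 = np.array([anchor_distance, 0.0, 0.0])
    anchor_b1 = np.array([anchor_distance + offset, 0.0, 0.0])
    n_per = n_runs * n_replicas
    detected, diffs = 0, []
    for _ in range(n_reps):
        m0 = [_replica_distance_mean(rng, n_frames, anchor_a, anchor_b0, sigma, phi)
              for _ in range(n_per)]
        m1 = [_replica_distance_mean(rng, n_frames, anchor_a, anchor_b1, sigma, phi)
              for _ in range(n_per)]
        row = stats.compare(m0, m1, alpha)
        detected += row["significant"] and row["difference"] > 0
        diffs.append(row["difference"])
    diffs = np.asarray(diffs)
    return {
        "power": detected / n_reps,
        "mean_difference": float(diffs.mean()),
        "se_difference": float(diffs.std(ddof=1) / math.sqrt(n_reps)),
        "true_difference": offset,
        "n_reps": n_reps,
    }


def contact_difference_recovery(prob_a: float = 0.1, prob_b: float = 0.6,
                                n_frames: int = 100, n_replicas: int = 3,
                                seed: int = 2) -> dict:
    """Recover a programmed contact-propensity difference through the full
    atomic pipeline (generation -> contact detection -> difference map).

    Returns the recovered difference-map entry for the programmed pair,
    the true difference, and the binomial standard error implied by the
    pooled frame counts.
    """
    spec = synthetic.atp7b_fixture(n_frames=n_frames, n_replicas=n_replicas,
                                   seed=seed, effects=True)
    pair = spec.contact_overrides[0]
    spec = synthetic.SyntheticSpec(
        dmap=spec.dmap, anchors=spec.anchors, sigma=spec.sigma, phi=spec.phi,
        tail_domains=spec.tail_domains,
        contact_overrides=(synthetic.ContactOverride(
            pair.res_i, pair.res_j, {"apo": prob_a, "holo": prob_b}),),
        n_runs=spec.n_runs, n_replicas=n_replicas, n_frames=n_frames, seed=seed,
    )
    sets = synthetic.generate_ensembles(spec)
    cm_a = contacts.contact_frequency(sets["apo"], spec.dmap)
    cm_h = contacts.contact_frequency(sets["holo"], spec.dmap)
    diff = contacts.difference_map(cm_h, cm_a)
    n_pool = n_frames * spec.n_runs * n_replicas
    se = math.sqrt(prob_a * (1 - prob_a) / n_pool + prob_b * (1 - prob_b) / n_pool)
    return {
        "recovered": diff.get(pair.res_i, pair.res_j),
        "true_difference": prob_b - prob_a,
        "binomial_se": se,
        "n_frames_pooled": n_pool,
    }


def expected_distance_differences(spec: "synthetic.SyntheticSpec",
                                  groups: list[str] | None = None) -> dict:
    """Ground-truth anchor-based COM-distance differences of a spec.

    For each unordered domain pair, the difference between the
    effective-anchor distances of the two conditions — the value the
    pipeline's ComparisonTable should estimate (up to fluctuation-induced
    convexity bias, small when sigma << distances).
    """
    groups = groups or [s.name for s in spec.dmap.segments
                        if s.category == "domain" and s.name in spec.anchors]
    eff = {c: synthetic._effective_anchors(spec, c) for c in spec.conditions}
    c0, c1 = spec.conditions
    out = {}
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            d0 = float(np.linalg.norm(eff[c0][ga] - eff[c0][gb]))
            d1 = float(np.linalg.norm(eff[c1][ga] - eff[c1][gb]))
            out[f"{ga}–{gb}"] = d1 - d0
    return out
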