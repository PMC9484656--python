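#!/usr/bin/env python
"""Generate the two-condition synthetic dataset the later steps analyze.

Emulates the study layout — two conditions (apo/holo), two replica-
exchange rounds of six replicas each, so 12 trajectories per condition —
with the holo-like effect preset: MBD2/MBD3 shifted away from the
catalytic core, MBD5 toward it, an extended tail, and shifted contact
propensities at the MBD5–A-domain and MBD2–MBD3 interfaces.

Trajectory files (binary XTC) go to scratch/data/; the manifest there is
the input of every subsequent step.
"""

from pathlib import Path

from domaindyn.synthetic import atp7b_fixture, generate
from domaindyn import validation

OUT = Path(__file__).resolve().parents[1] / "scratch" / "data"
SEED = 1


def main():
    spec = atp7b_fixture(n_frames=100, n_replicas=6, seed=SEED, effects=True)
    generate(spec, OUT)
    spec.dmap.to_yaml(OUT / "domain_map.yaml")
    n_traj = len(spec.conditions) * spec.n_runs * spec.n_replicas
    print(f"wrote {n_traj} trajectories x {spec.n_frames} frames to {OUT}")
    print("\nEncoded ground-truth COM-distance differences (holo - apo, nm),")
    print("the values steps 04's comparison table should recover:")
    for pair, d in sorted(validation.expected_distance_differences(spec).items(),
                          key=lambda kv: -abs(kv[1]))[:8]:
        print(f"  {pair:<24}{d:+.2f}")


if __name__ == "__main__":
    main()
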