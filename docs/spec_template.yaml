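# Overrides for the synthetic-ensemble fixture, consumed by
#   domaindyn simulate --spec this_file.yaml --out dir/
# Every key is optional; omitted keys keep the fixture defaults shown.

# trajectory layout: 2 conditions x n_runs x n_replicas trajectories
n_frames: 200        # frames per trajectory (100 ps apart)
n_replicas: 6        # replicas per run
n_runs: 2            # independent runs per condition (reA, reB, ...)

seed: 0              # master seed; fixed seed => bit-identical output

# dynamics of the domain center-of-mass tracks
sigma: 0.2           # per-domain COM fluctuation, nm
phi: 0.8             # AR(1) lag-1 frame autocorrelation, |phi| < 1

# condition effects
effects: true        # true: apply the holo-like preset (MBD2/MBD3 away
                     # from the core, MBD5 toward it, tail extended,
                     # contact propensities shifted); false: the two
                     # conditions are statistically exchangeable (null)

# domain-map scale: residue counts of the full-size 17-segment ATP7B
# map divided by this factor (7 -> ~200 residues, ~600 atoms)
scale: 7.0
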