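# domaindyn

Domain-resolved comparison of replicated molecular-dynamics ensembles,
built around the question: *when a multi-domain protein is simulated in
two conditions (e.g. with and without a bound metal ion), which
differences in domain geometry and contacts are statistically real?*

The motivating system is the human copper transporter ATP7B: a P-type
ATPase core (M, A, P, N domains) preceded by a regulatory N-terminal
tail of six metal-binding domains (MBD1–6) joined by flexible linkers.
Copper binding to the MBD CXXC motifs changes the tail's dynamics — the
kind of effect that only shows up as shifted distributions across many
replica trajectories, never in a single run.

## What it computes

Given a topology, trajectories organized as *conditions × runs ×
replicas* (declared in a YAML manifest), and a named domain map
(the 17-segment ATP7B decomposition ships as the default):

- **Geometry** — per-frame centers of mass, domain–domain COM distances,
  mass-weighted radius of gyration
  $R_g = \sqrt{\sum_i m_i \lVert r_i - r_\mathrm{com}\rVert^2 / \sum_i m_i}$,
  selective Kabsch superposition, RMSD, and logarithmic-fit
  equilibration detection ($\mathrm{RMSD}(t) = a\ln(t+t_0)+b$).
- **Free-energy surfaces** — $F(x,y) = -\ln\big(p(x,y)/p_\mathrm{max}\big)$
  in units of $k_BT$ over any pair of collective variables (typically
  tail $R_g$ vs RMSD), pooled across replicas and runs.
- **Contacts** — residue–residue contact frequencies (any heavy-atom
  pair within 4.5 Å, strict `<`, same-segment pairs excluded), 5%
  rendering threshold, holo−apo difference maps, per-residue interface
  profiles, Cβ–Cβ 8 Å starting-structure reference maps, and overlays
  of predicted-contact tables.
- **Statistics** — the unit of independence is the *replica*, not the
  frame: each trajectory is reduced to its average, and the two groups
  of replica means (e.g. 12 vs 12) are compared with an independent
  t-test gated on Levene's test for equal variances (pooled variance if
  compatible, Welch otherwise). Applied to all 45 domain-pair distances,
  per-axis (x, y, z) domain positions after alignment on the M+P
  domains, and Pearson cross-correlations between MBD positions and
  tail $R_g$ over all 24 replica averages.
- **Copper centers** — patches CXXC cysteine pairs into linear
  bi-coordinated Cu(I) centers, redistributing charge so each center
  totals exactly −1 e (spread over all center atoms except S and Cu),
  and validates Cu–S distances and S–Cu–S angles from trajectories.
- **Synthetic ensembles** — a seeded generator of multi-domain
  trajectories (rigid domains on AR(1)-autocorrelated COM tracks,
  interpolated linkers, programmable per-domain shifts, tail extension
  and contact propensities) so every stage of the pipeline is testable
  against known ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (ground truth known by construction). `python analysis/01_simulate.py`
generates 24 trajectories (2 conditions × 2 runs × 6 replicas, 100
frames each) of a 1/7-scale ATP7B-like layout in which the holo
condition encodes MBD2/MBD3 moving away from the core, MBD5 moving
toward it, an extended tail, and two shifted contact propensities.
Subsequent steps then recover these effects:

```
$ python analysis/02_tail_geometry.py
apo: mean tail Rg 4.14 nm, FES minimum at Rg ~ 4.10 nm (485 occupied bins)
holo: mean tail Rg 5.61 nm, FES minimum at Rg ~ 5.62 nm (439 occupied bins)

$ python analysis/04_replica_statistics.py
41/45 domain-pair distances differ at p < 0.05
       observable  difference          t            p t_branch
        MBD1–MBD2   -0.805919 -28.977899 5.111725e-19   pooled
    MBD5–M domain   -0.353107  -8.193978 3.957010e-08   pooled
    MBD5–A domain   -0.300725  -8.044188 5.386729e-08   pooled
...
        MBD2–MBD5    4.484010 156.671215 4.995518e-35   pooled

$ python analysis/05_calibration_and_copper.py
null rejection rate: 0.047 (nominal 0.05, 95% CI [0.040, 0.060])
1 nm offset: power 1.00, estimate 0.994 ± 0.001 nm
0.5 contact-propensity difference recovered as 0.508 (binomial SE 0.023)
copper center: total charge -1.0000000000 e, S–Cu–S angle 180.0°, linear=True
```

Reading: the holo tail samples a visibly larger radius of gyration
(5.61 vs 4.14 nm); MBD5 gets significantly *closer* to the M and A
domains (negative differences) while MBD2/MBD3 move away (large
positive differences) — exactly the sign pattern the generator encoded.
Step 05 shows the statistics are trustworthy: under a true null with
strongly autocorrelated frames the test rejects at 4.7% (nominal 5%),
and injected effects are recovered without bias.

The same machinery is scriptable (`domaindyn simulate|geom|contacts|compare|analyze|report`)
or importable (`import domaindyn`).

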