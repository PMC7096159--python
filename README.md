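# pullgeom

Analysis toolkit for **pulling-geometry-resolved single-molecule force
spectroscopy**: how strongly a receptor–ligand bond resists force depends on
*where* the complex is held. The motivating system is the
streptavidin/biotin tetramer: when streptavidin is anchored by the C
terminus of one subunit and biotin is pulled out of a binding pocket, the
measured unbinding force ranges from ~100 pN to ~450 pN depending on which
subunit carries the anchor. `pullgeom` implements the full analysis chain
that turns raw AFM retraction curves and steered-MD pulling trajectories
into that finding, together with synthetic-data generators that emulate
both data types with known ground truth.

## What it computes

**Bell–Evans rupture kinetics.** A bond loaded at rate *r* (pN/s) with
force-dependent off-rate *k(F) = k₀·exp(F·x‡/k_BT)* ruptures at a force
distributed as

    p(F) = (k₀/r) · exp(F·x‡/k_BT) · exp[ (k₀·k_BT)/(x‡·r) · (1 − exp(F·x‡/k_BT)) ]

with most probable rupture force *F\* = (k_BT/x‡)·ln(x‡·r/(k₀·k_BT))*,
linear in ln *r* — the dynamic force spectrum. `rupture_stats` provides the
density, modal force, maximum-likelihood mixtures of 1–3 components (EM
with an exact profiled M-step), BIC model-order selection, and the
straight-line spectrum fit that recovers (x‡, k₀).

**AFM trace analysis** (`trace_analysis`): raw-channel conversion with
cantilever-bending correction, per-trace force/distance zeroing, boxcar
denoising, transformation into contour-length space by pointwise inversion
of the Marko–Siggia worm-like chain

    F(x; L_c, L_p) = (k_BT/L_p) · [ 1/(4(1−x/L_c)²) − 1/4 + x/L_c ],

detection of unfolding events as force peaks with contour-length
increments ΔL_c, certification of the two-step ddFLN4 fingerprint (ΔL_c ≈
15 nm then 16 nm) that proves a specific single tether was loaded, and
extraction of the terminal rupture force with its loading rate (linear fit
immediately before rupture).

**SMD trajectory metrics** (`trajectory_metrics`): rupture force/frame as
the maximum of the pulling-force series, binding-pocket lid-opening metrics
(the Cα(Gly48)–Cα(Leu124) distance across the L3/4 loop, or a configurable
three-atom angle), histograms of the metric in the unloaded first 10 ns
versus the 10 ns before rupture, and replica-ensemble summary tables.

**Force-propagation networks** (`force_network`): nodes (residue Cα's plus
ligand atoms) joined when heavy atoms come within 4.5 Å in ≥ 75% of frames,
edges weighted *w_ij = −log |C_ij|* with *C* the motional cross-correlation;
optimal and suboptimal source→sink paths (all simple paths within
−log(0.5) = 0.69 of the optimum, enumerated by DFS pruned with
Floyd–Warshall bounds) with per-edge usage counts, over 10-ns windows
sampled every 400 ps.

**Synthetic data** (`synthetic_data`): a cantilever + serial-WLC tether
simulator with stochastic unfolding substeps and Bell-kinetics terminal
bonds (per-variant streptavidin datasets: 0SA/1SA/3SA/4SA), a
multivariate-Gaussian trajectory generator with programmed correlation
structure, and an overdamped-Langevin pulled chain with a load-triggered
loop-opening event. Every generator attaches a ground-truth event log and
is bitwise reproducible from its seed.

## Worked example

Fit a three-component Bell–Evans mixture to rupture forces pooled over the
four pulling geometries (modal forces 100/100/210/440 pN, mixed
0.4/0.4/0.2 at a loading rate of 5×10⁴ pN/s):

```python
import numpy as np
from pullgeom import rupture_stats as rs, synthetic_data as sd

r = 5e4  # pN/s
design = {"A/C": (100.0, 0.50), "B": (210.0, 0.35), "D": (440.0, 0.19)}
rng = np.random.default_rng(0)
forces = np.concatenate([
    sd.sample_rupture_forces_constant_rate(
        rs.BellEvansParams.from_modal_force(m, x, r), r, n, rng=rng)
    for (m, x), n in zip(design.values(), (1200, 1200, 600))
])
fit = rs.fit_mixture(forces, loading_rate=r, n_components=3, seed=0)
for (p, w), mode in zip(fit.components, fit.modal_forces):
    print(f"mode {mode:6.1f} pN   weight {w:.2f}   "
          f"k0 {p.k0:.2e}/s   x_dagger {p.x_dagger:.2f} nm")
```

prints

```
mode   99.7 pN   weight 0.40   k0 4.27e-02/s   x_dagger 0.49 nm
mode  210.8 pN   weight 0.40   k0 8.87e-05/s   x_dagger 0.35 nm
mode  439.9 pN   weight 0.20   k0 2.19e-06/s   x_dagger 0.20 nm
```

— the three generating modal forces are recovered within 0.5%, and the
weights exactly. The low mode is the weak pulling geometries (anchoring
far from the probed pocket), the high mode the strong one (pocket probed
through the anchored subunit).

The same workflow runs end-to-end from the shell:

```sh
pullgeom simulate-traces --variant 1SA --n 500 --seed 7 --out traces/
pullgeom analyze-traces --traces traces/ --out results/
pullgeom simulate-traj --frames 1500 --seed 7 --out replica_00/
pullgeom loop-metric --traj-dir replica_00/
```

`analyze-traces` logs the record counts at every stage (input, above the
50 pN interaction filter, with rupture, fingerprint-certified) and writes
the rupture table plus per-spot mixture fits; `loop-metric` prints the
rupture frame and the lid-opening shift in nm.

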