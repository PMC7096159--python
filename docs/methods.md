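# Methods

This note documents the models behind `pullgeom`, the defaults and why they
were chosen, what the synthetic-data generators do and do not emulate, and
the numerical choices that matter.

## Bell–Evans rupture kinetics

A single bond under force ruptures thermally with rate
k(F) = k₀·exp(F·x‡/k_BT), where k₀ (1/s) is the intrinsic off-rate and x‡
(nm) the distance to the transition state. Under a constant loading rate
r (pN/s) the rupture-force density is the Evans–Ritchie form

    p(F) = (k₀/r)·exp(bF)·exp[(k₀/(b·r))·(1 − exp(bF))],  b = x‡/k_BT,

whose mode is F\* = (k_BT/x‡)·ln(x‡·r/(k₀·k_BT)) when x‡·r > k₀·k_BT and 0
otherwise. k_BT defaults to 4.1419 pN·nm (300 K). All densities are
computed in log space with the exponent clipped at 700 to avoid overflow;
the clip only affects parameter regions whose likelihood is effectively
−∞ anyway.

**Sampling** uses the exact inverse transform of the survival function,
F = (k_BT/x‡)·ln(1 − (x‡·r/(k₀·k_BT))·ln u) with u ~ U(0,1) (`log1p` for
accuracy near u → 1).

**Mixture fitting** is maximum likelihood on the raw forces — the
histograms one draws are a visualization, not the estimator. EM is used
with an exact M-step: for fixed b the weighted-likelihood-optimal k₀ is
closed-form, k₀ = b·r·Σγ / Σγ(exp(bF)−1), which reduces each component
update to a bounded 1-D search over log x‡ on [10⁻³, 3] nm. Initialization
splits the sorted forces into contiguous quantile groups; 10 seeded
restarts with jittered group boundaries guard against local optima, and
the best log-likelihood wins. Components are reported sorted by modal
force; weights are renormalized every step and floored at 10⁻¹². A
zero-variance sample is reported `degenerate` rather than fitted. Model
order, when not forced, is chosen by BIC over 1–3 components.

**Dynamic force spectrum.** Events are binned by log loading rate; each
populated bin (≥ 50 events) gets a single-component fit at the bin-median
rate, and the (ln r, F\*) points are fitted by least squares. The slope
gives x‡ = k_BT/slope and the intercept k₀ at the r₀ = 1 pN/s reference.
x‡ recovery is accurate to a few percent at the tested designs; k₀ is
exponentially sensitive to the intercept, so its tolerance is ~50%.

## The SMFS trace model and its analysis

**Forward model.** One retraction cycle is a cantilever spring (default
0.15 N/m) in series with a worm-like-chain tether. The WLC uses the
Marko–Siggia interpolation; the tether is a PEG linker (default
L_c = 30 nm, L_p = 0.38 nm — the PEG5000 values are not sharply defined in
the literature and are configuration, not constants) plus a fingerprint
domain contributing two stochastic unfolding substeps (ΔL_c = 15 and 16 nm
by default, mimicking the two-step ddFLN4 signature). At each 12,000 Hz
sample the tip–surface separation advances at 800 nm/s and the tension
solves tether_extension(F) + F/k_c = z. Rupture hazards of the next
pending unfolding step and of the terminal bond are integrated on the
sampling grid via per-step probabilities 1 − exp(−k(F)·Δt), which
correctly handles the non-constant loading a WLC imposes. Gaussian force
noise (default 6 pN) is added last; the noiseless event log (index, force,
ΔL_c, loading rate) is stored as ground truth.

Unfolding-step kinetics default to k₀ = 1.5×10⁻⁴/s, x‡ = 1.5 nm, placing
the unfolding forces at ~45–55 pN with a tight spread. The large x‡/small
k₀ combination is deliberate: it makes unfolding strongly force-triggered
(negligible spontaneous unfolding at low force, where a peak would be
undetectable) and lets the two-step fingerprint complete before even the
weakest pulling geometry ruptures near 100 pN.

Subunit terminal-bond kinetics are derived from target modal forces
100/100/210/440 pN (subunits A/C/B/D) at a 5×10⁴ pN/s reference rate with
x‡ = 0.50/0.45/0.35/0.19 nm. Because the WLC loading rate at the actual
rupture point is itself force-dependent (≈ 6×10³–6×10⁴ pN/s along a
trace), the realized per-trace modal forces sit slightly below the design
targets; parameter-recovery claims are therefore made against the
constant-rate sampler, and pipeline tests assert mixture *order*, not
exact modes.

**Variant datasets.** A trace is a specific tether with probability
`fingerprint_attach_rate` (default 0.025; the subunit is drawn from the
variant's accessible set — 1SA exposes only D, 3SA exposes A/B/C, 4SA all
four). Otherwise it is background: with probability `nonspecific_rate`
(default 2/20,000, the empirically observed level on nonfunctional control
surfaces) it mimics a specific curve, else it is a flat noise cycle. Every
trace carries its ground-truth subunit label.

**Analysis chain.** Raw channels convert as force = k_c·invols·V_defl and
extension = sens·V_piezo − invols·V_defl (cantilever-bending correction).
The force zero is the median of the terminal detached baseline (last 10%
of samples; a trace whose terminal window is not a plausible baseline is
excluded). Denoising is a boxcar of 5 samples. The contour-length
transform inverts the WLC per point for L_c (points below 10 pN are
masked — the inversion is ill-conditioned there). Events are force peaks
above 30 pN followed by a ≥ 25% relative drop; the contour length of each
flanking stretch is the histogram mode (0.5 nm bins, refined by the median
of the modal ±1 bin), computed only over the upper-force half of the
stretch, where the inversion is well conditioned, and starting each
post-event stretch at the actual force drop so that peak-index jitter
cannot leak old-state samples into the new state. Non-terminal events
whose increment is below 8 nm (far below the 15/16 nm fingerprint steps)
are treated as noise blips and merged away. The fingerprint is certified
when the increments contain, in order, one match per expected ΔL_c within
±2 nm, all before the final rupture. The rupture force is the force at the
last peak; the loading rate is the least-squares slope over the contiguous
run of samples scanned back from the peak while the force stays at or
above 75% of the peak — scanning back (rather than cutting per sample on
force) matters, because a per-sample cut preferentially admits
upward-noise samples at the window edge and biases the slope down by
~20%.

The same window definition is used for the generator's ground-truth
loading rate on the noiseless trace: "the loading rate" of a rupture under
WLC-nonlinear loading is not a unique instantaneous derivative but the
slope of a linear fit immediately before rupture, so the estimand is
defined once and used on both sides. On the strong pulling geometry
(440 pN ruptures, long final flanks) the estimator recovers the truth with
a median error of ~3%; on weak geometries (~100 pN ruptures) the final
flank is short and the same fit has an honest 15–20% scatter.

## Toy trajectories

**Correlated fluctuations.** Node displacements are zero-mean Gaussian
with the programmed correlation matrix (eigendecomposition square root;
the same scalar correlation applies independently per Cartesian axis, so
the 3-D dot-product and per-axis Pearson conventions coincide in
expectation). Default node geometry is a 4 Å-spaced line; tests use a ring
with a high-correlation route to pose a designed force-propagation
problem.

**Pulled chain.** An overdamped-Langevin harmonic chain (16 nodes, 3.5 Å
bonds, k = 10 kcal/(mol·Å²), friction 5 kcal·ns/(mol·Å²), 300 K) is pulled
along z at 0.5 Å/ns through a 1.0 kcal/(mol·Å²) spring — the standard
constant-velocity steered-MD restraint, equal to 0.69 N/m. The anchor node
is held by a stiff (50 kcal/(mol·Å²)) position restraint rather than
frozen, so its fluctuations — and hence its correlations — stay defined.
One adjacent node pair is held by a separate restraint whose rest length
jumps by 8 Å the first time the pulling force exceeds 400 pN (the
lid-opening event); the spring detaches at 800 pN (rupture). With the
0.04 ns frame interval and 2000-frame default this places the opening
after the first 10-ns window and the rupture with ≥ 10 ns to spare, so
the unloaded/loaded window comparison is always well posed. The force
series ramps at ≈ 27 pN/ns — the chain is friction-dominated and barely
relaxes on the run timescale, which is qualitatively what a
microsecond-scale pull looks like from the spring's point of view.

What these toys do **not** emulate: real secondary structure, anisotropic
or solvent-mediated correlations, force-field physics, or the absolute
force scale of any specific complex. Passing tests demonstrate that the
analysis stages recover programmed ground truth from data with the right
statistical shape — not that they would produce identical numbers on real
trajectories.

## Force-propagation networks

Nodes default to one per residue (all heavy atoms of the residue define
its contact monomer) plus optional single-atom ligand nodes. Contact
requires a heavy-atom pair within 4.5 Å in at least 75% of the analyzed
frames (strict: 74/100 frames is not a contact). Correlation is the 3-D
normalized covariance of node-position fluctuations about the window mean
(a per-axis Pearson variant is available behind a flag). Edge weights are
−log|C| (natural log, so |C| = 0.5 ↦ 0.69); contacts with |C| = 0 would
have infinite weight and are dropped with a warning; weights are clipped
at 0 from below, which also guarantees the Floyd–Warshall validity
asserted on every build. Suboptimal paths are all simple source→sink paths
within the tolerance (default 0.69) of the optimum, enumerated by
depth-first search pruned with the all-pairs distance-to-sink lower bound
and capped at 10,000 paths with an explicit truncation flag. Sequence-
adjacent residue pairs are kept as edges by default (a flag removes them).
Windowed analysis cuts the trajectory into consecutive 10-ns windows
resampled every 400 ps (25 frames per window) and pools per-edge usage
counts across windows and replicas.

## Numerical choices

- All WLC inversions are vectorized bisections on the fractional extension
  s ∈ [0, 1) (64 iterations, machine precision for double inputs); the
  force-balance solve bisects directly on s when all segments share one
  persistence length (the default), falling back to a nested
  force-bisection otherwise. Parametrizing by s or by L_c is equivalent —
  the Marko–Siggia form is monotone in both.
- Tie-break at equal force-series maxima: first occurrence (earliest
  rupture-consistent event).
- Residue selection syntax is `chain/resid/name` with 1-based PDB residue
  numbering, so Gly48's Cα is `A/48/CA`.
- Trace text files are written at %.17g so read-back is bitwise; trajectory
  XYZ round-trips at the written precision (~10⁻⁴ Å).
- Degenerate inputs are first-class: all-contact traces raise a baseline
  error, zero-variance samples return a degenerate fit, disconnected
  source/sink returns an empty flagged ensemble, a replica without a force
  series is skipped with a warning.

## Problem sizes

The test suite and the acceptance script run the statistical checks at the
sizes the method needs for its stated tolerances: 2,000 draws per
Kolmogorov–Smirnov comparison, 3,000 forces for the three-component
mixture, 10 rate bins × 200 events for the spectrum, 500 labeled traces
for the classifier, 200 random graphs for the enumeration cross-check, and
10,000 frames for correlation recovery.

## Known limitations

- The loading-rate estimate on short final flanks (weak geometries)
  scatters at the 15–20% level; averaging over events, as the dynamic
  force spectrum does, is the intended use.
- The EM mixture fit assumes a common loading rate per sample (events are
  collapsed to the bin/spot median); strongly heterogeneous per-event
  rates belong in the spectrum fit instead.
- Suboptimal-path enumeration is exponential in the worst case; the
  10,000-path cap makes pathological windows truncate loudly rather than
  hang.
- The contour-length transform assumes a single persistence length for the
  whole tether; with mixed-L_p constructs the recovered L_c is an
  effective value and increments remain comparable but slightly biased.
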