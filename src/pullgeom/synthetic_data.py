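"""Synthetic force-spectroscopy and trajectory data with known ground truth.

Two families of generators:

* SMFS retraction curves — a cantilever (harmonic spring) in series with a
  worm-like-chain tether (PEG linker + protein construct). The ddFLN4
  fingerprint domain contributes two stochastic unfolding substeps (contour
  length increments), and the terminal receptor-ligand bond ruptures with
  Bell kinetics integrated on the sampling grid. Streptavidin-valence
  datasets mix traces over the accessible subunits (A-D), each with its own
  rupture kinetics, plus background cycles.

* Toy molecular trajectories — (i) multivariate-Gaussian node fluctuations
  with a programmed inter-node correlation matrix, for validating the
  correlation-network analysis, and (ii) an overdamped-Langevin harmonic
  chain pulled at constant velocity with a load-triggered loop-opening
  event and a terminal detachment, emulating the statistical structure of
  constant-velocity steered-MD output.

Every generator is reproducible bitwise from its seed and attaches a
ground-truth event log to the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .rupture_stats import BellEvansParams
from .trace_analysis import ForceExtensionTrace
from .trajectory_metrics import Trajectory
from .units import KBT_300K_KCAL_MOL, KBT_300K_PN_NM, KCAL_PER_MOL_A_PN
from .wlc import wlc_force, wlc_fractional_extension  # re-exported: generative primitives

__all__ = [
    "WLCSegment",
    "TetherModel",
    "AcquisitionProtocol",
    "VariantConfig",
    "CorrelationSpec",
    "ToyPullModel",
    "wlc_force",
    "sample_rupture_forces_constant_rate",
    "simulate_trace",
    "generate_variant_dataset",
    "generate_correlated_trajectory",
    "generate_smd_pull_trajectory",
    "default_tether",
]

_F_MAX_PN = 1e5  # bracket ceiling for the force-balance solve
_BISECT_ITERS = 64


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WLCSegment:
    """One serial WLC segment: contour length Lc and persistence length Lp (nm)."""

    Lc: float
    Lp: float

    def __post_init__(self) -> None:
        if self.Lc <= 0 or self.Lp <= 0:
            raise ValueError("segment lengths must be strictly positive")


@dataclass(frozen=True)
class UnfoldingStep:
    """A stochastic tether-lengthening substep: contour-length increment
    delta_Lc (nm) released at Bell-rate k0·exp(F·x_dagger/kBT)."""

    delta_Lc: float
    k0: float
    x_dagger: float

    def __post_init__(self) -> None:
        if self.delta_Lc <= 0 or self.k0 <= 0 or self.x_dagger <= 0:
            raise ValueError("unfolding-step parameters must be strictly positive")


@dataclass(frozen=True)
class TetherModel:
    """Cantilever + serial-WLC tether with fingerprint substeps.

    The two unfolding steps default to the characteristic two-step pattern
    of the ddFLN4 fingerprint domain (configurable increments; 15 and 16 nm
    by default). `unfolded_Lp` is the persistence length assigned to
    contour length released by unfolding.
    """

    cantilever_stiffness: float = 0.15  # N/m
    segments: tuple[WLCSegment, ...] = (WLCSegment(Lc=30.0, Lp=0.38),)
    unfolding_steps: tuple[UnfoldingStep, ...] = (
        UnfoldingStep(delta_Lc=15.0, k0=1.5e-4, x_dagger=1.5),
        UnfoldingStep(delta_Lc=16.0, k0=1.5e-4, x_dagger=1.5),
    )
    terminal_bond: BellEvansParams | None = None
    unfolded_Lp: float = 0.38  # nm
    temperature_kBT: float = KBT_300K_PN_NM  # pN·nm

    def __post_init__(self) -> None:
        if self.cantilever_stiffness <= 0:
            raise ValueError("cantilever stiffness must be strictly positive")
        if not self.segments:
            raise ValueError("tether needs at least one WLC segment")
        if self.unfolded_Lp <= 0 or self.temperature_kBT <= 0:
            raise ValueError("unfolded_Lp and temperature_kBT must be strictly positive")


@dataclass(frozen=True)
class AcquisitionProtocol:
    """AFM retraction protocol: constant-velocity retraction with Gaussian
    force noise on a fixed sampling grid."""

    retract_velocity: float = 800.0  # nm/s
    sampling_rate: float = 12_000.0  # Hz
    retract_distance: float = 350.0  # nm
    force_noise_sd: float = 6.0  # pN
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.retract_velocity, self.sampling_rate, self.retract_distance) <= 0:
            raise ValueError("velocity, rate and distance must be strictly positive")
        if self.force_noise_sd < 0:
            raise ValueError("force noise sd must be nonnegative")

    @property
    def n_samples(self) -> int:
        return int(self.retract_distance / self.retract_velocity * self.sampling_rate)


_ACCESSIBLE = {
    "0SA": (),
    "1SA": ("D",),
    "3SA": ("A", "B", "C"),
    "4SA": ("A", "B", "C", "D"),
}

#: Loading rate (pN/s) at which the default subunit kinetics place their
#: modal rupture forces; the effective rate of the emulated AFM protocol.
REFERENCE_LOADING_RATE = 5e4


def _default_subunit_params() -> dict[str, BellEvansParams]:
    """Per-subunit terminal-bond kinetics.

    Chosen so that the most probable rupture forces at the emulated
    experimental loading rate sit near 100 pN (subunits A and C, weakest
    geometries), 210 pN (B) and 440 pN (D, the anchored subunit probed
    along the strongest axis). The (k0, x_dagger) pairs are configuration,
    not constants of the method.
    """
    r = REFERENCE_LOADING_RATE
    return {
        "A": BellEvansParams.from_modal_force(100.0, 0.50, r),
        "B": BellEvansParams.from_modal_force(210.0, 0.35, r),
        "C": BellEvansParams.from_modal_force(100.0, 0.45, r),
        "D": BellEvansParams.from_modal_force(440.0, 0.19, r),
    }


@dataclass(frozen=True)
class VariantConfig:
    """One streptavidin valence variant (surface spot).

    `nonspecific_rate` is the probability that a cycle without a specific
    tether nonetheless produces a fingerprint-mimicking background event
    (observed at the 1e-4 level in nonfunctional-control experiments);
    `fingerprint_attach_rate` is the probability that a binding attempt
    forms a full specific tether.
    """

    variant_label: str
    subunit_params: dict
    subunit_weights: dict
    nonspecific_rate: float = 2.0 / 20_000.0
    fingerprint_attach_rate: float = 0.025

    def __post_init__(self) -> None:
        if self.variant_label not in _ACCESSIBLE:
            raise ValueError(f"variant_label must be one of {sorted(_ACCESSIBLE)}")
        acc = _ACCESSIBLE[self.variant_label]
        extra = set(self.subunit_weights) - set(acc)
        if extra:
            raise ValueError(f"{self.variant_label} exposes {acc}; weights given for {sorted(extra)}")
        if acc:
            total = sum(self.subunit_weights.get(s, 0.0) for s in acc)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"subunit weights must sum to 1, got {total}")
            missing = [s for s in acc if s not in self.subunit_params]
            if missing:
                raise ValueError(f"missing kinetics for accessible subunits {missing}")
        if not (0 <= self.nonspecific_rate <= 1 and 0 <= self.fingerprint_attach_rate <= 1):
            raise ValueError("rates must be probabilities")

    @property
    def accessible_subunits(self) -> tuple[str, ...]:
        return _ACCESSIBLE[self.variant_label]

    @classmethod
    def default(cls, variant_label: str, **overrides) -> "VariantConfig":
        params = _default_subunit_params()
        acc = _ACCESSIBLE[variant_label]
        weights = {s: 1.0 / len(acc) for s in acc} if acc else {}
        kw = dict(
            variant_label=variant_label,
            subunit_params={s: params[s] for s in acc},
            subunit_weights=weights,
        )
        kw.update(overrides)
        return cls(**kw)


# ---------------------------------------------------------------------------
# Bell-Evans rupture-force sampling (kinetic inverse transform)
# ---------------------------------------------------------------------------


def sample_rupture_forces_constant_rate(
    params: BellEvansParams,
    loading_rate: float,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw n i.i.d. rupture forces of a Bell bond under a constant force ramp.

    Inverse transform of the Bell-Evans survival function:
    F = (kBT/x_dagger) * ln(1 - (x_dagger*r/(k0*kBT)) * ln u), u ~ U(0,1).
    """
    if loading_rate <= 0:
        raise ValueError("loading rate must be strictly positive")
    if n < 1:
        raise ValueError("n must be at least 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    u = rng.random(n)
    u = np.clip(u, np.finfo(float).tiny, 1.0)
    a = params.x_dagger * loading_rate / (params.k0 * params.kBT)
    return (params.kBT / params.x_dagger) * np.log1p(-a * np.log(u))


# ---------------------------------------------------------------------------
# Trace simulation
# ---------------------------------------------------------------------------


def _serial_extension(force: np.ndarray, segments: Sequence[WLCSegment], kBT: float) -> np.ndarray:
    """Total tether extension at common tension, grouping segments by Lp."""
    by_Lp: dict[float, float] = {}
    for seg in segments:
        by_Lp[seg.Lp] = by_Lp.get(seg.Lp, 0.0) + seg.Lc
    ext = np.zeros_like(force)
    for Lp, Lc_total in by_Lp.items():
        ext += Lc_total * wlc_fractional_extension(force, Lp, kBT)
    return ext


def _solve_force_balance(
    z: np.ndarray, segments: Sequence[WLCSegment], k_c_pN_nm: float, kBT: float
) -> np.ndarray:
    """Tension F(z) balancing the cantilever spring against the serial WLC:
    tether_extension(F) + F/k_c = z. Monotone in F; vectorized bisection.

    When all segments share one persistence length the balance is solved in
    a single bisection on the fractional extension s (F is closed-form in
    s); otherwise an outer force bisection wraps the per-segment inversion.
    """
    Lps = {seg.Lp for seg in segments}
    if len(Lps) == 1:
        Lp = Lps.pop()
        Lc_tot = sum(seg.Lc for seg in segments)
        lo = np.zeros_like(z)
        hi = np.full_like(z, 1.0 - 1e-12)
        pref = kBT / Lp
        for _ in range(_BISECT_ITERS):
            s = 0.5 * (lo + hi)
            F = pref * (0.25 / (1.0 - s) ** 2 - 0.25 + s)
            g = Lc_tot * s + F / k_c_pN_nm - z
            hi = np.where(g > 0, s, hi)
            lo = np.where(g > 0, lo, s)
        s = 0.5 * (lo + hi)
        return pref * (0.25 / (1.0 - s) ** 2 - 0.25 + s)
    lo = np.zeros_like(z)
    hi = np.full_like(z, _F_MAX_PN)
    for _ in range(_BISECT_ITERS):
        mid = 0.5 * (lo + hi)
        g = _serial_extension(mid, segments, kBT) + mid / k_c_pN_nm - z
        hi = np.where(g > 0, mid, hi)
        lo = np.where(g > 0, lo, mid)
    return 0.5 * (lo + hi)


def _loading_rate_at(F: np.ndarray, j: int, dt: float, top_fraction: float = 0.25) -> float:
    """Ground-truth loading rate of a noiseless force stretch at event index j.

    The loading rate is *defined* as the linear-fit slope of force vs time
    immediately before the event; here the fit window is the trailing run
    of samples with force at or above (1 - top_fraction) of the event force,
    matching the estimand of the analysis stage.
    """
    if j < 1:
        return float("nan")
    thresh = (1.0 - top_fraction) * F[j]
    i0 = j
    while i0 > 0 and F[i0 - 1] >= thresh:
        i0 -= 1
    if j - i0 < 2:
        i0 = max(j - 2, 0)
    t = np.arange(i0, j + 1) * dt
    return float(np.polyfit(t, F[i0 : j + 1], 1)[0])


def simulate_trace(
    tether: TetherModel,
    bond: BellEvansParams | None = None,
    protocol: AcquisitionProtocol = AcquisitionProtocol(),
) -> ForceExtensionTrace:
    """Simulate one retraction trace of a cantilever-tether-bond system.

    Per sample, the tip-surface separation ramps at the retraction velocity
    and the tension solves the force balance between the cantilever spring
    and the serial WLC tether. Rupture hazards of the next pending
    unfolding substep and of the terminal bond are integrated on the
    sampling grid via per-step probabilities 1 - exp(-k(F)·dt) (supports
    the non-constant loading imposed by WLC nonlinearity). An unfolding
    event adds its contour-length increment to the tether; terminal-bond
    rupture drops the force to the baseline for the rest of the retraction.
    Gaussian noise is added to the force channel last. The noiseless
    ground-truth event log is attached to the metadata.
    """
    bond = bond if bond is not None else tether.terminal_bond
    if bond is None:
        raise ValueError("no terminal bond: pass `bond` or set tether.terminal_bond")
    rng = np.random.default_rng(protocol.seed)
    n = protocol.n_samples
    dt = 1.0 / protocol.sampling_rate
    time = np.arange(n) * dt
    z = protocol.retract_velocity * time
    k_c = tether.cantilever_stiffness * 1000.0  # N/m -> pN/nm
    kBT = tether.temperature_kBT

    force = np.zeros(n)
    extension = z.copy()
    segments = list(tether.segments)
    pending = list(tether.unfolding_steps)
    events: list[dict] = []
    i0 = 0
    while i0 < n:
        F = _solve_force_balance(z[i0:], segments, k_c, kBT)
        k_term = bond.off_rate(F)
        p_term = -np.expm1(-k_term * dt)
        if pending:
            step = pending[0]
            k_unf = step.k0 * np.exp(np.clip(F * step.x_dagger / kBT, None, 700))
            p_unf = -np.expm1(-k_unf * dt)
        else:
            p_unf = np.zeros_like(F)
        draws = rng.random((F.size, 2))
        fire_unf = draws[:, 0] < p_unf
        fire_term = draws[:, 1] < p_term
        fire_any = fire_unf | fire_term
        j = int(np.argmax(fire_any)) if fire_any.any() else F.size
        force[i0 : i0 + min(j + 1, F.size)] = F[: min(j + 1, F.size)]
        extension[i0 : i0 + min(j + 1, F.size)] = (
            z[i0 : i0 + min(j + 1, F.size)] - F[: min(j + 1, F.size)] / k_c
        )
        if j == F.size:
            break  # survived the whole retraction
        idx = i0 + j
        rate = _loading_rate_at(F, j, dt)
        if fire_term[j]:
            events.append(
                {
                    "type": "rupture",
                    "index": idx,
                    "time_s": float(time[idx]),
                    "force_pN": float(F[j]),
                    "loading_rate_pN_s": rate,
                }
            )
            # detached: free cantilever baseline for the rest of the trace
            force[idx + 1 :] = 0.0
            extension[idx + 1 :] = z[idx + 1 :]
            break
        # unfolding: release the increment into the tether
        events.append(
            {
                "type": "unfold",
                "index": idx,
                "time_s": float(time[idx]),
                "force_pN": float(F[j]),
                "delta_Lc_nm": step.delta_Lc,
                "loading_rate_pN_s": rate,
            }
        )
        segments.append(WLCSegment(Lc=step.delta_Lc, Lp=tether.unfolded_Lp))
        pending.pop(0)
        i0 = idx + 1

    if protocol.force_noise_sd > 0:
        force = force + rng.normal(0.0, protocol.force_noise_sd, n)

    ruptures = [e for e in events if e["type"] == "rupture"]
    meta = {
        "protocol": {
            "retract_velocity_nm_s": protocol.retract_velocity,
            "sampling_rate_Hz": protocol.sampling_rate,
            "retract_distance_nm": protocol.retract_distance,
            "force_noise_sd_pN": protocol.force_noise_sd,
            "seed": protocol.seed,
        },
        "events": events,
        "ruptured": bool(ruptures),
        "true_rupture_force_pN": ruptures[0]["force_pN"] if ruptures else None,
        "true_loading_rate_pN_s": ruptures[0]["loading_rate_pN_s"] if ruptures else None,
        "n_unfolding_events": sum(1 for e in events if e["type"] == "unfold"),
    }
    return ForceExtensionTrace(time=time, extension=extension, force=force, metadata=meta)


def default_tether(**overrides) -> TetherModel:
    """The default PEG + ddFLN4 tether used by the variant generator."""
    return TetherModel(**overrides)


def _background_trace(protocol: AcquisitionProtocol) -> ForceExtensionTrace:
    rng = np.random.default_rng(protocol.seed)
    n = protocol.n_samples
    dt = 1.0 / protocol.sampling_rate
    time = np.arange(n) * dt
    z = protocol.retract_velocity * time
    force = rng.normal(0.0, protocol.force_noise_sd, n) if protocol.force_noise_sd > 0 else np.zeros(n)
    meta = {"events": [], "ruptured": False, "n_unfolding_events": 0}
    return ForceExtensionTrace(time=time, extension=z, force=force, metadata=meta)


#: Kinetics of the rare fingerprint-mimicking background events.
_MIMIC_BOND = BellEvansParams.from_modal_force(150.0, 0.40, REFERENCE_LOADING_RATE)


def generate_variant_dataset(
    config: VariantConfig,
    n_traces: int,
    protocol: AcquisitionProtocol = AcquisitionProtocol(),
    tether: TetherModel | None = None,
) -> list[ForceExtensionTrace]:
    """Generate a labeled trace set for one surface spot (valence variant).

    Each cycle forms a specific tether with probability
    `fingerprint_attach_rate` (subunit drawn per `subunit_weights`);
    otherwise it is background, which with probability `nonspecific_rate`
    mimics a specific curve. Every trace carries its ground-truth subunit
    label (or "background") and the spot label in metadata.
    """
    if n_traces < 1:
        raise ValueError("n_traces must be at least 1")
    tether = tether if tether is not None else default_tether()
    master = np.random.default_rng(protocol.seed)
    acc = config.accessible_subunits
    weights = np.array([config.subunit_weights[s] for s in acc]) if acc else None

    traces: list[ForceExtensionTrace] = []
    for i in range(n_traces):
        sub_seed = int(master.integers(2**31))
        proto_i = AcquisitionProtocol(
            retract_velocity=protocol.retract_velocity,
            sampling_rate=protocol.sampling_rate,
            retract_distance=protocol.retract_distance,
            force_noise_sd=protocol.force_noise_sd,
            seed=sub_seed,
        )
        u_attach = master.random()
        u_mimic = master.random()
        if acc and u_attach < config.fingerprint_attach_rate:
            subunit = str(master.choice(list(acc), p=weights))
            trace = simulate_trace(tether, config.subunit_params[subunit], proto_i)
            label = subunit
            specific = True
        elif u_mimic < config.nonspecific_rate:
            trace = simulate_trace(tether, _MIMIC_BOND, proto_i)
            label = "background"
            specific = False
        else:
            trace = _background_trace(proto_i)
            label = "background"
            specific = False
        trace.metadata.update(
            {
                "trace_id": f"{config.variant_label}_{i:05d}",
                "spot_label": config.variant_label,
                "subunit": label,
                "specific": specific,
            }
        )
        traces.append(trace)
    return traces


# ---------------------------------------------------------------------------
# Toy trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationSpec:
    """Programmed inter-node correlation structure for a fluctuation trajectory."""

    n_nodes: int
    target_correlation: np.ndarray
    mean_positions: np.ndarray | None = None  # (n_nodes, 3) Å; default: 5 Å-spaced line
    fluctuation_sd: float = 1.0  # Å

    def __post_init__(self) -> None:
        C = np.asarray(self.target_correlation, dtype=float)
        if C.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("target_correlation must be n_nodes x n_nodes")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("target correlation must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-10):
            raise ValueError("target correlation must have unit diagonal")
        if np.any(np.abs(C) > 1 + 1e-10):
            raise ValueError("correlations must lie in [-1, 1]")
        if np.linalg.eigvalsh(C).min() < -1e-8:
            raise ValueError("target correlation must be positive semidefinite")
        if self.fluctuation_sd <= 0:
            raise ValueError("fluctuation_sd must be strictly positive")
        object.__setattr__(self, "target_correlation", C)
        if self.mean_positions is not None:
            mp = np.asarray(self.mean_positions, dtype=float)
            if mp.shape != (self.n_nodes, 3):
                raise ValueError("mean_positions must be n_nodes x 3")
            object.__setattr__(self, "mean_positions", mp)


def _chain_metadata(n: int) -> dict:
    return {
        "names": np.array(["CA"] * n),
        "elements": np.array(["C"] * n),
        "resnames": np.array(["GLY"] * n),
        "resids": np.arange(1, n + 1),
        "chains": np.array(["A"] * n),
    }


def generate_correlated_trajectory(
    spec: CorrelationSpec,
    n_frames: int,
    seed: int | None = None,
    frame_interval_ns: float = 0.4,
) -> Trajectory:
    """Zero-mean Gaussian node fluctuations with the programmed correlation.

    The same scalar correlation applies independently to each Cartesian
    axis, so both the per-axis Pearson and the 3-D dot-product correlation
    conventions converge to the target as n_frames grows.
    """
    if n_frames < 2:
        raise ValueError("correlation is undefined for fewer than 2 frames")
    n = spec.n_nodes
    C = spec.target_correlation
    w, V = np.linalg.eigh(C)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    zmat = rng.standard_normal((n_frames, 3, n))
    disp = spec.fluctuation_sd * (zmat @ L.T)  # (frames, 3, nodes)
    mean = (
        spec.mean_positions
        if spec.mean_positions is not None
        else np.column_stack([np.zeros(n), np.zeros(n), 4.0 * np.arange(n)])
    )
    coords = mean[None, :, :] + np.transpose(disp, (0, 2, 1))
    return Trajectory(
        coordinates=coords,
        frame_interval_ns=frame_interval_ns,
        metadata={"generator": "correlated_fluctuations", "seed": seed},
        **_chain_metadata(n),
    )


@dataclass(frozen=True)
class ToyPullModel:
    """Overdamped harmonic chain pulled at constant velocity.

    A minimal stand-in for constant-velocity steered-MD output: node 0 is
    anchored, the last node is attached to a harmonic spring whose anchor
    moves along +z at `pull_velocity`. The `loop_nodes` pair is held by a
    restraint whose rest length jumps by `loop_open_offset` the first time
    the pulling force exceeds `loop_open_force` (the lid-opening event);
    the spring detaches when the force exceeds `detach_force` (rupture).
    Internal units: Å, ns, kcal/(mol·Å) for forces (reported in pN).
    """

    n_nodes: int = 16
    bond_length: float = 3.5  # Å
    bond_k: float = 10.0  # kcal/(mol·Å²)
    loop_nodes: tuple[int, int] = (7, 8)
    loop_rest_length: float = 4.0  # Å
    loop_open_offset: float = 8.0  # Å
    loop_k: float = 40.0  # kcal/(mol·Å²)
    loop_open_force: float = 400.0  # pN
    detach_force: float = 800.0  # pN
    anchor_node: int = 0
    pull_node: int = -1
    pull_velocity: float = 0.5  # Å/ns
    spring_constant: float = 1.0  # kcal/(mol·Å²)
    anchor_k: float = 50.0  # kcal/(mol·Å²), position restraint on the anchor
    friction: float = 5.0  # kcal·ns/(mol·Å²)
    kBT: float = KBT_300K_KCAL_MOL  # kcal/mol
    frame_interval_ns: float = 0.04

    def __post_init__(self) -> None:
        if self.n_nodes < 3:
            raise ValueError("need at least 3 nodes")
        i, j = self.loop_nodes
        if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes and i != j):
            raise ValueError("loop_nodes must be two distinct valid indices")
        pull = self.pull_node % self.n_nodes
        if self.anchor_node % self.n_nodes == pull:
            raise ValueError("anchor and pull nodes must differ")
        if self.loop_open_force <= 0:
            raise ValueError("loop_open_force must be strictly positive")
        for name in ("bond_length", "bond_k", "loop_k", "spring_constant", "friction", "frame_interval_ns"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def generate_smd_pull_trajectory(
    model: ToyPullModel,
    n_frames: int = 2000,
    seed: int | None = None,
) -> tuple[Trajectory, np.ndarray]:
    """Integrate the toy pull model; returns (trajectory, force series in pN).

    The force series is the spring extension times the spring constant,
    sampled once per frame. Ground truth (loop-open frame, rupture frame,
    rupture force) is stored in the trajectory metadata; either is None if
    the corresponding threshold was never crossed.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    n = model.n_nodes
    pull = model.pull_node % n
    anchor = model.anchor_node % n
    li, lj = model.loop_nodes
    loop_pair = {li, lj} if abs(li - lj) == 1 else set()

    # initial chain along z; gap at the loop pair uses the loop rest length
    gaps = np.full(n - 1, model.bond_length)
    for k in range(n - 1):
        if {k, k + 1} == loop_pair:
            gaps[k] = model.loop_rest_length
    zpos = np.concatenate([[0.0], np.cumsum(gaps)])
    x = np.column_stack([np.zeros(n), np.zeros(n), zpos])

    rng = np.random.default_rng(seed)
    dt = model.frame_interval_ns
    noise_sd = np.sqrt(2.0 * model.kBT * dt / model.friction)
    pull_anchor_z0 = x[pull, 2]

    bonds = [(k, k + 1) for k in range(n - 1) if {k, k + 1} != loop_pair]
    loop_rest = model.loop_rest_length
    attached = True
    loop_open_frame: int | None = None
    rupture_frame: int | None = None
    rupture_force: float | None = None

    coords = np.empty((n_frames, n, 3))
    force_series = np.empty(n_frames)

    for frame in range(n_frames):
        t = frame * dt
        spring_ext = (pull_anchor_z0 + model.pull_velocity * t) - x[pull, 2]
        f_pull_kcal = model.spring_constant * spring_ext if attached else 0.0
        f_pull_pN = f_pull_kcal * KCAL_PER_MOL_A_PN

        if attached and loop_open_frame is None and f_pull_pN > model.loop_open_force:
            loop_open_frame = frame
            loop_rest = model.loop_rest_length + model.loop_open_offset
        if attached and f_pull_pN > model.detach_force:
            rupture_frame = frame
            rupture_force = f_pull_pN
            attached = False

        coords[frame] = x
        force_series[frame] = f_pull_pN if attached or frame == rupture_frame else 0.0

        # forces (kcal/(mol·Å))
        f = np.zeros((n, 3))
        for a, b in bonds:
            d = x[b] - x[a]
            r = np.linalg.norm(d)
            if r > 0:
                fb = model.bond_k * (r - model.bond_length) * d / r
                f[a] += fb
                f[b] -= fb
        d = x[lj] - x[li]
        r = np.linalg.norm(d)
        if r > 0:
            fl = model.loop_k * (r - loop_rest) * d / r
            f[li] += fl
            f[lj] -= fl
        if attached:
            f[pull, 2] += model.spring_constant * spring_ext
        # stiff position restraint in place of a frozen anchor: the node
        # keeps small fluctuations so correlation-based analyses stay defined
        f[anchor] -= model.anchor_k * (x[anchor] - coords[0][anchor])

        x = x + (dt / model.friction) * f + noise_sd * rng.standard_normal((n, 3))

    traj = Trajectory(
        coordinates=coords,
        frame_interval_ns=dt,
        applied_force=force_series.copy(),
        metadata={
            "generator": "toy_smd_pull",
            "seed": seed,
            "loop_open_frame": loop_open_frame,
            "rupture_frame": rupture_frame,
            "rupture_force_pN": rupture_force,
            "loop_nodes": [li, lj],
            "loop_open_offset_A": model.loop_open_offset,
        },
        **_chain_metadata(n),
    )
    return traj, force_series
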