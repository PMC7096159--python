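"""Bell-Evans rupture-force statistics.

A bond loaded at constant rate ``r`` (pN/s) with force-dependent off-rate
``k(F) = k0 * exp(F * x_dagger / kBT)`` ruptures at a force distributed as

    p(F) = (k0/r) * exp(b*F) * exp[(k0/(b*r)) * (1 - exp(b*F))],   b = x_dagger/kBT

(the Evans-Ritchie constant-loading-rate form). The most probable rupture
force is ``F* = (kBT/x_dagger) * ln(x_dagger*r/(k0*kBT))``, linear in the
log loading rate — the basis of the dynamic force spectrum.

This module provides the density, the modal force, maximum-likelihood
mixture fits of 1-3 Bell-Evans components to rupture-force samples
(expectation-maximization with a profiled exact M-step), a comparison of a
free mixture against a fixed combination of previously fitted components,
and the straight-line dynamic-force-spectrum fit that recovers
``x_dagger`` and ``k0`` from modal forces across loading-rate bins.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .units import KBT_300K_PN_NM

__all__ = [
    "BellEvansParams",
    "MixtureFit",
    "ForceSpectrumFit",
    "bell_evans_logpdf",
    "bell_evans_pdf",
    "modal_force",
    "fit_mixture",
    "select_mixture_order",
    "compare_mixture_vs_fixed_combination",
    "dynamic_force_spectrum",
]

_MIN_FORCES = 50  # minimum sample size for a meaningful mixture fit
_X_DAGGER_BOUNDS_NM = (1e-3, 3.0)  # search range for distance to transition state
_EXP_CLIP = 700.0  # exp() overflow guard


@dataclass(frozen=True)
class BellEvansParams:
    """Single-barrier rupture kinetics: intrinsic off-rate k0 (1/s), distance
    to the transition state x_dagger (nm), thermal energy kBT (pN·nm)."""

    k0: float
    x_dagger: float
    kBT: float = KBT_300K_PN_NM

    def __post_init__(self) -> None:
        for name in ("k0", "x_dagger", "kBT"):
            if not getattr(self, name) > 0:
                raise ValueError(f"BellEvansParams.{name} must be strictly positive")

    @classmethod
    def from_modal_force(
        cls,
        modal_force_pN: float,
        x_dagger: float,
        loading_rate: float,
        kBT: float = KBT_300K_PN_NM,
    ) -> "BellEvansParams":
        """Parameters whose most probable rupture force at `loading_rate`
        equals `modal_force_pN`, given the distance to the transition state."""
        if modal_force_pN <= 0 or loading_rate <= 0:
            raise ValueError("modal force and loading rate must be positive")
        k0 = (x_dagger * loading_rate / kBT) * np.exp(-modal_force_pN * x_dagger / kBT)
        return cls(k0=float(k0), x_dagger=float(x_dagger), kBT=float(kBT))

    def off_rate(self, force):
        """Force-dependent off-rate k(F) = k0 exp(F x_dagger / kBT), 1/s."""
        return self.k0 * np.exp(np.clip(np.asarray(force, float) * self.x_dagger / self.kBT, None, _EXP_CLIP))


def bell_evans_logpdf(F, params: BellEvansParams, loading_rate: float):
    """Log of the Bell-Evans rupture-force density at constant loading rate."""
    if loading_rate <= 0:
        raise ValueError("loading rate must be strictly positive")
    F = np.asarray(F, dtype=float)
    b = params.x_dagger / params.kBT
    z = np.clip(b * F, None, _EXP_CLIP)
    logp = np.where(
        F < 0,
        -np.inf,
        np.log(params.k0 / loading_rate) + z - (params.k0 / (b * loading_rate)) * np.expm1(z),
    )
    return logp if logp.ndim else float(logp)


def bell_evans_pdf(F, params: BellEvansParams, loading_rate: float):
    """Bell-Evans rupture-force density (1/pN); zero for F < 0."""
    return np.exp(bell_evans_logpdf(F, params, loading_rate))


def modal_force(params: BellEvansParams, loading_rate: float) -> float:
    """Most probable rupture force F* = (kBT/x‡)·ln(x‡·r/(k0·kBT)) in pN.

    Returns 0.0 when x‡·r <= k0·kBT, where the density is monotone
    decreasing and the mode sits at zero force.
    """
    if loading_rate <= 0:
        raise ValueError("loading rate must be strictly positive")
    arg = params.x_dagger * loading_rate / (params.k0 * params.kBT)
    if arg <= 1.0:
        return 0.0
    return (params.kBT / params.x_dagger) * float(np.log(arg))


# ---------------------------------------------------------------------------
# Mixture fitting (EM)
# ---------------------------------------------------------------------------


@dataclass
class MixtureFit:
    """Maximum-likelihood Bell-Evans mixture: components sorted by modal force."""

    components: list[tuple[BellEvansParams, float]]
    loading_rate_used: float
    log_likelihood: float
    converged: bool
    degenerate: bool = False
    n_iter: int = 0

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.components])

    @property
    def modal_forces(self) -> np.ndarray:
        """Per-component most probable rupture forces, increasing order."""
        return np.array([modal_force(p, self.loading_rate_used) for p, _ in self.components])

    def bic(self, n_obs: int) -> float:
        n_par = 3 * self.n_components - 1
        return -2.0 * self.log_likelihood + n_par * np.log(n_obs)

    def logpdf(self, F) -> np.ndarray:
        F = np.atleast_1d(np.asarray(F, float))
        comp = np.stack(
            [np.log(w) + bell_evans_logpdf(F, p, self.loading_rate_used) for p, w in self.components]
        )
        return logsumexp(comp, axis=0)

    def pdf(self, F) -> np.ndarray:
        return np.exp(self.logpdf(F))


def _profiled_mstep(F: np.ndarray, gamma: np.ndarray, r: float, kBT: float) -> BellEvansParams:
    """Exact weighted-likelihood maximizer for one component.

    For fixed b = x‡/kBT the optimal k0 is closed-form,
    k0 = b·r·Σγ / Σγ(exp(bF)−1), leaving a 1-D profile likelihood in b.
    """
    A = gamma.sum()
    SF = float(gamma @ F)

    def negQ(log_x: float) -> float:
        x = np.exp(log_x)
        b = x / kBT
        e = np.expm1(np.clip(b * F, None, _EXP_CLIP))
        B = float(gamma @ e)
        if not np.isfinite(B) or B <= 0:
            return np.inf
        k0 = b * r * A / B
        Q = A * np.log(k0 / r) + b * SF - A
        return -Q

    lo, hi = np.log(_X_DAGGER_BOUNDS_NM)
    res = minimize_scalar(negQ, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10})
    x = float(np.exp(res.x))
    b = x / kBT
    B = float(gamma @ np.expm1(np.clip(b * F, None, _EXP_CLIP)))
    k0 = float(b * r * A / B)
    return BellEvansParams(k0=max(k0, 1e-300), x_dagger=x, kBT=kBT)


def _em_run(
    F: np.ndarray,
    r: float,
    kBT: float,
    groups: list[np.ndarray],
    max_iter: int,
    tol: float,
) -> MixtureFit:
    n = F.size
    k = len(groups)
    params: list[BellEvansParams] = []
    weights = np.empty(k)
    for j, idx in enumerate(groups):
        gamma = np.zeros(n)
        gamma[idx] = 1.0
        params.append(_profiled_mstep(F, gamma, r, kBT))
        weights[j] = idx.size / n

    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_comp = np.stack(
            [np.log(w) + bell_evans_logpdf(F, p, r) for p, w in zip(params, weights)]
        )
        log_norm = logsumexp(log_comp, axis=0)
        ll = float(log_norm.sum())
        gamma = np.exp(log_comp - log_norm)  # responsibilities, k x n
        weights = gamma.sum(axis=1) / n
        weights = np.clip(weights, 1e-12, None)
        weights /= weights.sum()
        params = [_profiled_mstep(F, gamma[j], r, kBT) for j in range(k)]
        if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            converged = True
            break
        prev_ll = ll

    log_comp = np.stack([np.log(w) + bell_evans_logpdf(F, p, r) for p, w in zip(params, weights)])
    ll = float(logsumexp(log_comp, axis=0).sum())
    comps = sorted(
        zip(params, weights.tolist()), key=lambda pw: modal_force(pw[0], r)
    )
    return MixtureFit(
        components=[(p, float(w)) for p, w in comps],
        loading_rate_used=r,
        log_likelihood=ll,
        converged=converged,
        n_iter=it,
    )


def fit_mixture(
    forces: Sequence[float],
    loading_rate: float,
    n_components: int,
    init: str = "quantile",
    seed: int | None = 0,
    n_starts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-9,
    kBT: float = KBT_300K_PN_NM,
) -> MixtureFit:
    """Fit a 1-3 component Bell-Evans mixture by maximum likelihood.

    EM with a profiled exact M-step per component; initialized from a
    quantile split of the sorted forces into contiguous groups, with
    `n_starts - 1` additional seeded random-boundary restarts; the best
    log-likelihood wins. Deterministic under a fixed seed.
    """
    F = np.asarray(forces, dtype=float)
    if F.ndim != 1 or F.size == 0:
        raise ValueError("forces must be a nonempty 1-D sequence")
    if F.size < _MIN_FORCES:
        raise ValueError(f"need at least {_MIN_FORCES} forces, got {F.size}")
    if not (1 <= n_components <= 3):
        raise ValueError("n_components must be 1, 2 or 3")
    if loading_rate <= 0:
        raise ValueError("loading rate must be strictly positive")
    if np.any(F < 0):
        raise ValueError("rupture forces must be nonnegative")
    if np.ptp(F) == 0:
        # zero-variance sample: no spread to fit, report degenerate
        p = BellEvansParams(k0=1.0, x_dagger=1.0, kBT=kBT)
        return MixtureFit(
            components=[(p, 1.0)],
            loading_rate_used=loading_rate,
            log_likelihood=-np.inf,
            converged=False,
            degenerate=True,
        )
    if init != "quantile":
        raise ValueError(f"unknown init strategy {init!r}")

    order = np.argsort(F)
    rng = np.random.default_rng(seed)
    n = F.size
    k = n_components

    def split(boundaries: np.ndarray) -> list[np.ndarray]:
        return [g for g in np.split(order, boundaries) if g.size > 0]

    starts: list[list[np.ndarray]] = []
    even = np.array([n * j // k for j in range(1, k)], dtype=int)
    starts.append(split(even))
    while len(starts) < n_starts:
        if k == 1:
            break
        b = np.sort(rng.integers(max(1, n // 20), n - max(1, n // 20), size=k - 1))
        if len(set(b.tolist())) == k - 1:
            starts.append(split(b))

    best: MixtureFit | None = None
    for groups in starts:
        if len(groups) != k:
            continue
        fit = _em_run(F, loading_rate, kBT, groups, max_iter, tol)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    return best


def select_mixture_order(
    forces: Sequence[float],
    loading_rate: float,
    max_components: int = 3,
    seed: int | None = 0,
    **kwargs,
) -> MixtureFit:
    """Fit 1..max_components mixtures and return the best by BIC."""
    F = np.asarray(forces, float)
    fits = [fit_mixture(F, loading_rate, k, seed=seed, **kwargs) for k in range(1, max_components + 1)]
    return min(fits, key=lambda f: f.bic(F.size))


def compare_mixture_vs_fixed_combination(
    forces: Sequence[float],
    fit_a: MixtureFit,
    fit_b: MixtureFit,
    loading_rate: float | None = None,
    seed: int | None = 0,
) -> tuple[MixtureFit, float]:
    """Likelihood of a sample under a free mixture vs. fixed prior components.

    Refits only the weights over the pooled components of `fit_a` and
    `fit_b` (kinetic parameters frozen), and fits a free mixture of the
    same total order; returns ``(free_fit, combined_log_likelihood)``.
    Used to ask whether a tetravalent sample is explained by the union of
    the monovalent and trivalent populations.
    """
    F = np.asarray(forces, dtype=float)
    if F.size == 0:
        raise ValueError("empty force sample")
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("prior fits must have converged")
    r = loading_rate if loading_rate is not None else fit_a.loading_rate_used

    fixed = [p for p, _ in fit_a.components] + [p for p, _ in fit_b.components]
    k = len(fixed)
    logp = np.stack([bell_evans_logpdf(F, p, r) for p in fixed])  # k x n
    w = np.full(k, 1.0 / k)
    ll = -np.inf
    for _ in range(1000):
        log_comp = np.log(w)[:, None] + logp
        log_norm = logsumexp(log_comp, axis=0)
        new_ll = float(log_norm.sum())
        gamma = np.exp(log_comp - log_norm)
        w = np.clip(gamma.sum(axis=1) / F.size, 1e-12, None)
        w /= w.sum()
        if abs(new_ll - ll) < 1e-10 * max(1.0, abs(new_ll)):
            ll = new_ll
            break
        ll = new_ll

    free = fit_mixture(F, r, n_components=min(k, 3), seed=seed)
    return free, ll


# ---------------------------------------------------------------------------
# Dynamic force spectrum
# ---------------------------------------------------------------------------


@dataclass
class ForceSpectrumFit:
    """Straight-line fit of modal force vs ln(loading rate).

    slope = kBT/x‡ gives the distance to the transition state; the
    intercept at r0 = 1 pN/s gives the intrinsic off-rate.
    """

    points: list[tuple[float, float]]  # (loading_rate pN/s, modal force pN)
    slope: float
    intercept: float
    derived_x_dagger: float
    derived_k0: float
    kBT: float
    valid: bool = True
    reason: str = ""


def _as_force_rate_arrays(events) -> tuple[np.ndarray, np.ndarray]:
    if len(events) and hasattr(events[0], "rupture_force"):
        f = np.array([e.rupture_force for e in events], float)
        r = np.array([e.loading_rate for e in events], float)
    else:
        f, r = (np.asarray(a, float) for a in events)
    return f, r


def dynamic_force_spectrum(
    events,
    n_rate_bins: int = 10,
    min_events_per_bin: int = _MIN_FORCES,
    kBT: float = KBT_300K_PN_NM,
    seed: int | None = 0,
) -> ForceSpectrumFit:
    """Bin rupture events by log loading rate and fit the Bell-Evans line.

    Per bin, the modal force comes from a single-component maximum-
    likelihood fit at the bin's median rate. Requires at least three
    populated bins spanning the rate axis; otherwise the fit is flagged
    invalid.
    """
    forces, rates = _as_force_rate_arrays(events)
    ok = (rates > 0) & (forces > 0)
    forces, rates = forces[ok], rates[ok]
    if forces.size == 0:
        return ForceSpectrumFit([], np.nan, np.nan, np.nan, np.nan, kBT, False, "no events")
    log_r = np.log(rates)
    edges = np.linspace(log_r.min(), log_r.max() * (1 + 1e-12), n_rate_bins + 1)
    points: list[tuple[float, float]] = []
    for i in range(n_rate_bins):
        in_bin = (log_r >= edges[i]) & (log_r < edges[i + 1] if i < n_rate_bins - 1 else log_r <= edges[i + 1])
        if in_bin.sum() < min_events_per_bin:
            continue
        r_bin = float(np.median(rates[in_bin]))
        fit = fit_mixture(forces[in_bin], r_bin, n_components=1, seed=seed)
        points.append((r_bin, float(fit.modal_forces[0])))
    if len(points) < 3:
        return ForceSpectrumFit(points, np.nan, np.nan, np.nan, np.nan, kBT, False,
                                "fewer than 3 populated loading-rate bins")
    x = np.log([p[0] for p in points])
    y = np.array([p[1] for p in points])
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        return ForceSpectrumFit(points, float(slope), float(intercept), np.nan, np.nan, kBT,
                                False, "nonpositive slope")
    x_dagger = kBT / slope
    r0 = 1.0  # pN/s reference
    k0 = (x_dagger * r0 / kBT) * np.exp(-intercept * x_dagger / kBT)
    return ForceSpectrumFit(points, float(slope), float(intercept), float(x_dagger), float(k0), kBT)
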