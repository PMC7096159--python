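"""Worm-like-chain (WLC) polymer elasticity.

Marko–Siggia interpolation: with fractional extension ``s = x/Lc``,

    F(s) = (kBT/Lp) * [ 1/(4(1-s)^2) - 1/4 + s ]

which is exact at both the entropic (s -> 0) and the strongly stretched
(s -> 1) limits and within ~10% in between — the community-standard model
for PEG/protein tethers at single-molecule forces.

All inversions (extension given force; contour length given extension and
force) reduce to the scalar root of the monotone function ``F(s)`` on
``s in [0, 1)``, solved here by vectorized bisection.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wlc_force",
    "wlc_fractional_extension",
    "wlc_extension",
    "wlc_contour_length",
]

_S_MAX = 1.0 - 1e-12
_BISECT_ITERS = 64


def _validate_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.all(np.asarray(value) > 0):
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


def wlc_force(extension, Lc: float, Lp: float, kBT: float):
    """Force (pN) of a WLC at the given extension (nm).

    Parameters
    ----------
    extension : float or array
        End-to-end extension, 0 <= extension < Lc.
    Lc, Lp : float
        Contour and persistence lengths in nm.
    kBT : float
        Thermal energy in pN·nm.

    Raises
    ------
    ValueError
        If any length/energy is nonpositive or extension >= Lc (the force
        diverges at full extension).
    """
    _validate_positive(Lc=Lc, Lp=Lp, kBT=kBT)
    s = np.asarray(extension, dtype=float) / Lc
    if np.any(s < 0):
        raise ValueError("extension must be nonnegative")
    if np.any(s >= 1.0):
        raise ValueError("extension must be strictly below the contour length")
    f = (kBT / Lp) * (0.25 / (1.0 - s) ** 2 - 0.25 + s)
    return f if f.ndim else float(f)


def wlc_fractional_extension(force, Lp: float, kBT: float):
    """Fractional extension s solving the Marko–Siggia relation at `force` (pN)."""
    _validate_positive(Lp=Lp, kBT=kBT)
    phi = np.asarray(force, dtype=float) * Lp / kBT
    if np.any(phi < 0):
        raise ValueError("force must be nonnegative")
    lo = np.zeros_like(phi)
    hi = np.full_like(phi, _S_MAX)
    for _ in range(_BISECT_ITERS):
        mid = 0.5 * (lo + hi)
        g = 0.25 / (1.0 - mid) ** 2 - 0.25 + mid - phi
        hi = np.where(g > 0, mid, hi)
        lo = np.where(g > 0, lo, mid)
    s = 0.5 * (lo + hi)
    return s if s.ndim else float(s)


def wlc_extension(force, Lc: float, Lp: float, kBT: float):
    """Extension (nm) of a WLC of contour length `Lc` at `force` (pN)."""
    _validate_positive(Lc=Lc)
    s = wlc_fractional_extension(force, Lp, kBT)
    return Lc * s


def wlc_contour_length(extension, force, Lp: float, kBT: float):
    """Contour length (nm) such that the WLC reaches `extension` at `force`.

    The unique root with Lc > extension; undefined (returns inf) at zero
    force, where any contour length is compatible with zero extension.
    """
    s = wlc_fractional_extension(force, Lp, kBT)
    ext = np.asarray(extension, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        Lc = np.where(np.asarray(s) > 0, ext / np.asarray(s), np.inf)
    return Lc if Lc.ndim else float(Lc)
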