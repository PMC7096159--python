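"""Per-trajectory steered-MD observables.

Rupture force/frame and loading rate from a pulling-force series, binding-
pocket lid-opening metrics (a two-atom distance or a three-atom angle per
frame), histograms of a metric in an early unloaded window versus a window
just before rupture, and summary tables over replica ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "LoopMetricSeries",
    "parse_selection",
    "smd_rupture",
    "pair_distance_series",
    "angle_series",
    "window_histograms",
    "replica_ensemble_summary",
    "smd_replica_plan",
]


@dataclass
class Trajectory:
    """In-memory molecular trajectory: frames x atoms x 3 coordinates in Å
    plus per-atom metadata and an optional per-frame applied pulling force.
    """

    coordinates: np.ndarray  # (n_frames, n_atoms, 3), Å
    names: np.ndarray  # atom names, e.g. "CA"
    elements: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray  # 1-based residue numbers, PDB convention
    chains: np.ndarray
    frame_interval_ns: float
    applied_force: np.ndarray | None = None  # pN per frame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        n_atoms = self.coordinates.shape[1]
        for attr in ("names", "elements", "resnames", "resids", "chains"):
            arr = np.asarray(getattr(self, attr))
            if arr.shape != (n_atoms,):
                raise ValueError(f"{attr} must have length n_atoms={n_atoms}")
            setattr(self, attr, arr)
        if not self.frame_interval_ns > 0:
            raise ValueError("frame_interval_ns must be positive")
        if self.applied_force is not None:
            self.applied_force = np.asarray(self.applied_force, dtype=float)
            if self.applied_force.shape != (self.n_frames,):
                raise ValueError("applied_force must have one value per frame")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.char.upper(self.elements.astype(str)) != "H"

    def select_atoms(self, name=None, resid=None, chain=None, resname=None) -> np.ndarray:
        """Indices of atoms matching all given fields."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if name is not None:
            mask &= self.names.astype(str) == str(name)
        if resid is not None:
            mask &= self.resids.astype(int) == int(resid)
        if chain is not None:
            mask &= self.chains.astype(str) == str(chain)
        if resname is not None:
            mask &= self.resnames.astype(str) == str(resname)
        return np.flatnonzero(mask)

    def single_atom(self, selection) -> int:
        """Resolve a selection to exactly one atom index.

        Raises ValueError listing the matches when the selection is empty
        or ambiguous.
        """
        idx = self.select_atoms(**parse_selection(selection))
        if idx.size != 1:
            matches = [
                f"{self.chains[i]}/{self.resnames[i]}{self.resids[i]}/{self.names[i]}"
                for i in idx
            ]
            raise ValueError(
                f"selection {selection!r} matched {idx.size} atoms "
                f"(need exactly 1): {matches}"
            )
        return int(idx[0])


def parse_selection(selection) -> dict:
    """Normalize an atom selection.

    Accepts a dict of fields for :meth:`Trajectory.select_atoms`, an int
    (atom index is not supported here — use dicts/strings), or a compact
    string ``"chain/resid/name"`` such as ``"A/48/CA"`` (the lid-distance
    endpoints Gly48-CA and Leu124-CA would be ``"A/48/CA"``, ``"A/124/CA"``).
    """
    if isinstance(selection, dict):
        return selection
    if isinstance(selection, str):
        parts = selection.split("/")
        if len(parts) != 3:
            raise ValueError(f"selection string must be 'chain/resid/name', got {selection!r}")
        return {"chain": parts[0], "resid": int(parts[1]), "name": parts[2]}
    raise TypeError(f"unsupported selection {selection!r}")


@dataclass
class LoopMetricSeries:
    """Per-frame scalar geometric metric (distance in nm or angle in degrees)."""

    values: np.ndarray
    metric_kind: str  # "distance" | "angle"
    atoms_used: tuple
    frame_interval_ns: float
    rupture_frame: int | None = None


# ---------------------------------------------------------------------------
# Rupture from the force series
# ---------------------------------------------------------------------------


def smd_rupture(
    force_series: Sequence[float],
    frame_interval_ns: float,
    fit_window_ns: float = 10.0,
) -> tuple[float, int, float]:
    """Rupture force, rupture frame and loading rate from a pulling-force trace.

    The rupture force is the global maximum of the series (first occurrence
    on ties); the loading rate is the least-squares slope of force vs time
    over the `fit_window_ns` immediately preceding (and including) that
    maximum. The rate is NaN when fewer than two frames precede the maximum
    or the series is shorter than the fit window.
    """
    f = np.asarray(force_series, dtype=float)
    if f.size == 0:
        raise ValueError("empty force series")
    i_max = int(np.argmax(f))
    rupture_force = float(f[i_max])
    w = int(round(fit_window_ns / frame_interval_ns))
    if i_max + 1 < max(w, 2) or w < 2:
        return rupture_force, i_max, float("nan")
    t = np.arange(i_max + 1 - w, i_max + 1) * frame_interval_ns * 1e-9  # s
    slope = np.polyfit(t, f[i_max + 1 - w : i_max + 1], 1)[0]
    return rupture_force, i_max, float(slope)


# ---------------------------------------------------------------------------
# Geometric metrics
# ---------------------------------------------------------------------------


def pair_distance_series(traj: Trajectory, sel_i, sel_j) -> LoopMetricSeries:
    """Per-frame distance between two atoms, reported in nm.

    The canonical lid-opening metric is the Cα(Gly48)-Cα(Leu124) distance:
    the flexible L3/4 loop closes over the bound biotin, and its forced
    opening shows up as a step increase of this distance under load.
    """
    i = traj.single_atom(sel_i)
    j = traj.single_atom(sel_j)
    d_A = np.linalg.norm(traj.coordinates[:, i, :] - traj.coordinates[:, j, :], axis=1)
    return LoopMetricSeries(
        values=d_A / 10.0,
        metric_kind="distance",
        atoms_used=(i, j),
        frame_interval_ns=traj.frame_interval_ns,
    )


def angle_series(traj: Trajectory, sel_a, sel_b, sel_c) -> LoopMetricSeries:
    """Per-frame angle (degrees, [0, 180]) at vertex b of three atoms.

    Frames with a zero-length arm are flagged NaN.
    """
    a, b, c = (traj.single_atom(s) for s in (sel_a, sel_b, sel_c))
    if len({a, b, c}) != 3:
        raise ValueError("the three selections must resolve to distinct atoms")
    v1 = traj.coordinates[:, a, :] - traj.coordinates[:, b, :]
    v2 = traj.coordinates[:, c, :] - traj.coordinates[:, b, :]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    ok = (n1 > 0) & (n2 > 0)
    cosang = np.full(traj.n_frames, np.nan)
    cosang[ok] = np.einsum("ij,ij->i", v1[ok], v2[ok]) / (n1[ok] * n2[ok])
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return LoopMetricSeries(
        values=ang,
        metric_kind="angle",
        atoms_used=(a, b, c),
        frame_interval_ns=traj.frame_interval_ns,
    )


def window_histograms(
    series: LoopMetricSeries,
    rupture_frame: int,
    window_ns: float = 10.0,
    bins: int = 30,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray], float]:
    """Histogram a metric in the unloaded start window vs the pre-rupture window.

    Returns ``((counts_unloaded, edges), (counts_loaded, edges), shift)``
    with shared bin edges; shift is the difference of window means (loaded
    minus unloaded), i.e. the lid-opening amplitude for the distance metric.
    """
    w = int(round(window_ns / series.frame_interval_ns))
    if w < 1:
        raise ValueError("window shorter than one frame")
    if rupture_frame <= w:
        raise ValueError(f"rupture frame {rupture_frame} must exceed the window ({w} frames)")
    if rupture_frame - w < w:
        raise ValueError("unloaded and loaded windows overlap")
    v = np.asarray(series.values, dtype=float)
    if v.size < rupture_frame:
        raise ValueError("series shorter than rupture frame")
    unloaded = v[:w]
    loaded = v[rupture_frame - w : rupture_frame]
    both = np.concatenate([unloaded, loaded])
    edges = np.histogram_bin_edges(both[np.isfinite(both)], bins=bins)
    h_un = np.histogram(unloaded, bins=edges)[0]
    h_lo = np.histogram(loaded, bins=edges)[0]
    shift = float(np.nanmean(loaded) - np.nanmean(unloaded))
    return (h_un, edges), (h_lo, edges), shift


def replica_ensemble_summary(
    replicas: Sequence[dict],
    sel_i,
    sel_j,
    window_ns: float = 10.0,
    fit_window_ns: float = 10.0,
) -> tuple[pd.DataFrame, dict]:
    """Summarize an ensemble of SMD replicas.

    Each replica is a dict with keys ``traj`` (Trajectory), ``force_series``
    (pN per frame) and optional ``label`` (pulling-geometry tag). Returns a
    per-replica table (rupture force/frame, loading rate, lid shift) and a
    dict of pooled unloaded/loaded metric values grouped by label.
    """
    if len(replicas) == 0:
        raise ValueError("need at least one replica")
    rows = []
    pooled: dict[str, dict[str, list]] = {}
    for idx, rep in enumerate(replicas):
        traj: Trajectory = rep["traj"]
        force = np.asarray(rep["force_series"], dtype=float)
        label = str(rep.get("label", "all"))
        f_rup, i_rup, rate = smd_rupture(force, traj.frame_interval_ns, fit_window_ns)
        series = pair_distance_series(traj, sel_i, sel_j)
        w = int(round(window_ns / traj.frame_interval_ns))
        shift = np.nan
        unloaded = loaded = None
        if i_rup > 2 * w:
            _, _, shift = window_histograms(series, i_rup, window_ns)
            unloaded = series.values[:w]
            loaded = series.values[i_rup - w : i_rup]
        rows.append(
            {
                "replica": idx,
                "label": label,
                "rupture_force_pN": f_rup,
                "rupture_frame": i_rup,
                "loading_rate_pN_s": rate,
                "loop_shift_nm": shift,
            }
        )
        grp = pooled.setdefault(label, {"unloaded": [], "loaded": []})
        if unloaded is not None:
            grp["unloaded"].append(unloaded)
            grp["loaded"].append(loaded)
    table = pd.DataFrame(rows)
    pooled_arrays = {
        label: {k: (np.concatenate(v) if v else np.array([])) for k, v in d.items()}
        for label, d in pooled.items()
    }
    return table, pooled_arrays


def smd_replica_plan(
    n_geometries: int = 4,
    replicas_per_geometry: int = 100,
    replica_length_ns: float = 80.0,
) -> dict:
    """Bookkeeping of a wide-sampling SMD campaign.

    The default plan — one replica set per pulling geometry (anchoring at
    each of the four subunit C-termini), 100 replicas of 80 ns each —
    totals 4 x 100 x 80 ns = 32 μs of production pulling.
    """
    total_ns = n_geometries * replicas_per_geometry * replica_length_ns
    return {
        "n_geometries": n_geometries,
        "replicas_per_geometry": replicas_per_geometry,
        "replica_length_ns": replica_length_ns,
        "n_replicas_total": n_geometries * replicas_per_geometry,
        "total_simulation_ns": total_ns,
        "total_simulation_us": total_ns / 1000.0,
    }
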