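"""Cross-correlation dynamical network analysis of force propagation.

Nodes (residue Cα's plus designated ligand atoms) are connected when their
monomers satisfy a proximity criterion — any pair of heavy atoms within a
cutoff (default 4.5 Å) in at least a fraction (default 75%) of the frames.
Edges are weighted w_ij = -log(|C_ij|), the negative log of the motional
cross-correlation, so that low weight means efficient mechanical coupling.
Optimal and suboptimal source-to-sink paths (all simple paths within a
weight tolerance of the optimum, default -log(0.5) = 0.69) trace how force
propagates through the complex; per-edge usage counts over the suboptimal
ensemble quantify how likely each contact is to carry force.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import floyd_warshall

from .trajectory_metrics import Trajectory

__all__ = [
    "ContactNetwork",
    "PathEnsemble",
    "default_nodes",
    "contact_map",
    "correlation_matrix",
    "build_network",
    "suboptimal_paths",
    "windowed_network_analysis",
    "PATH_TOLERANCE",
]

logger = logging.getLogger(__name__)

#: Default suboptimal-path inclusion tolerance, -log(0.5).
PATH_TOLERANCE: float = float(-np.log(0.5))


@dataclass
class ContactNetwork:
    """Correlation-weighted contact graph on trajectory nodes."""

    node_labels: list[str]
    adjacency: np.ndarray  # (n, n) bool
    correlation: np.ndarray  # (n, n)
    weights: np.ndarray  # (n, n), -log|C| on edges, +inf elsewhere

    def __post_init__(self) -> None:
        n = len(self.node_labels)
        assert self.adjacency.shape == self.correlation.shape == self.weights.shape == (n, n)
        finite = self.weights[np.isfinite(self.weights)]
        # nonnegative weights guarantee Floyd-Warshall validity (no negative cycles)
        assert np.all(finite >= 0), "edge weights must be nonnegative"

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        ii, jj = np.nonzero(np.triu(np.isfinite(self.weights), k=1))
        g.add_weighted_edges_from(
            (int(i), int(j), float(self.weights[i, j])) for i, j in zip(ii, jj)
        )
        return g


@dataclass
class PathEnsemble:
    """Optimal and suboptimal source->sink paths with per-edge usage counts."""

    source: int
    sink: int
    optimal_path: list[int]
    optimal_weight: float
    suboptimal_paths: list[tuple[list[int], float]]  # includes the optimal path
    edge_usage: dict[tuple[int, int], int]
    tolerance: float
    truncated: bool = False
    connected: bool = True


def default_nodes(
    traj: Trajectory, extra_atom_nodes: Sequence = ()
) -> list[tuple[str, np.ndarray]]:
    """One node per residue (monomer = all heavy atoms of the residue), plus
    one node per explicitly listed extra atom (e.g. ligand atoms).

    Extra atoms are given as selections understood by
    :func:`pullgeom.trajectory_metrics.parse_selection`.
    """
    heavy = traj.heavy_mask
    nodes: list[tuple[str, np.ndarray]] = []
    seen: list[tuple] = []
    for chain, resid in zip(traj.chains, traj.resids):
        key = (str(chain), int(resid))
        if key in seen:
            continue
        seen.append(key)
        idx = traj.select_atoms(chain=key[0], resid=key[1])
        idx = idx[heavy[idx]]
        if idx.size:
            nodes.append((f"{key[0]}/{key[1]}", idx))
    for sel in extra_atom_nodes:
        i = traj.single_atom(sel)
        nodes.append((f"atom:{i}", np.array([i])))
    return nodes


def contact_map(
    traj: Trajectory,
    node_selection: Sequence[tuple[str, np.ndarray]],
    cutoff: float = 4.5,
    min_fraction: float = 0.75,
    frames: np.ndarray | None = None,
    exclude_sequence_adjacent: bool = False,
) -> np.ndarray:
    """Boolean contact matrix between monomers.

    Monomers i and j are in contact iff the minimum heavy-atom distance
    between them is <= `cutoff` (Å) in at least `min_fraction` of the
    analyzed frames (strictly fewer frames -> no contact).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be strictly positive")
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must lie in (0, 1]")
    if len(node_selection) == 0:
        raise ValueError("empty node selection")
    coords = traj.coordinates if frames is None else traj.coordinates[frames]
    n_frames = coords.shape[0]
    n = len(node_selection)
    groups = [np.asarray(idx, dtype=int) for _, idx in node_selection]
    counts = np.zeros((n, n), dtype=int)
    cut2 = cutoff * cutoff
    for fr in range(n_frames):
        xyz = coords[fr]
        for i in range(n):
            gi = xyz[groups[i]]
            for j in range(i + 1, n):
                gj = xyz[groups[j]]
                d2 = ((gi[:, None, :] - gj[None, :, :]) ** 2).sum(axis=2)
                if d2.min() <= cut2:
                    counts[i, j] += 1
    # strict threshold: >= min_fraction of frames
    adjacency = counts + counts.T >= min_fraction * n_frames - 1e-9
    np.fill_diagonal(adjacency, False)
    if exclude_sequence_adjacent:
        labels = [lbl for lbl, _ in node_selection]
        for i in range(n - 1):
            a, b = labels[i].split("/"), labels[i + 1].split("/")
            if len(a) == 2 and len(b) == 2 and a[0] == b[0] and abs(int(a[1]) - int(b[1])) == 1:
                adjacency[i, i + 1] = adjacency[i + 1, i] = False
    return adjacency


def correlation_matrix(
    traj: Trajectory,
    node_selection: Sequence[tuple[str, np.ndarray]],
    frames: np.ndarray | None = None,
    per_axis: bool = False,
) -> np.ndarray:
    """Pearson cross-correlation of node displacement fluctuations.

    Default convention (the one standard in dynamical network analysis):
    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>) with dr the 3-D
    deviation of the node position (mean of its atoms) from its window
    mean. `per_axis=True` instead averages the three per-axis Pearson
    coefficients. Zero-variance nodes yield NaN rows/columns (flagged).
    """
    coords = traj.coordinates if frames is None else traj.coordinates[frames]
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 frames for a correlation estimate")
    pos = np.stack(
        [coords[:, np.asarray(idx, int), :].mean(axis=1) for _, idx in node_selection],
        axis=1,
    )  # (frames, nodes, 3)
    dr = pos - pos.mean(axis=0, keepdims=True)
    if per_axis:
        corr_axes = []
        for ax in range(3):
            x = dr[:, :, ax]
            sd = x.std(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                c = (x.T @ x) / coords.shape[0] / np.outer(sd, sd)
            corr_axes.append(c)
        C = np.nanmean(corr_axes, axis=0)
    else:
        inner = np.einsum("fia,fja->ij", dr, dr) / coords.shape[0]
        var = np.diag(inner).copy()
        with np.errstate(invalid="ignore", divide="ignore"):
            C = inner / np.sqrt(np.outer(var, var))
        zero = var <= 0
        if zero.any():
            logger.warning("zero-variance nodes flagged NaN: %s", np.flatnonzero(zero))
            C[zero, :] = np.nan
            C[:, zero] = np.nan
    C = np.clip(C, -1.0, 1.0)
    if not per_axis:
        np.fill_diagonal(C, 1.0)
    return C


def build_network(
    adjacency: np.ndarray,
    C: np.ndarray,
    node_labels: Sequence[str] | None = None,
) -> ContactNetwork:
    """Contact network with edge weights w_ij = -log(|C_ij|).

    Perfectly correlated contacts cost nothing (w = 0); uncorrelated
    contacts (|C| = 0, infinite weight) are dropped with a warning.
    """
    adjacency = np.asarray(adjacency, dtype=bool)
    C = np.asarray(C, dtype=float)
    if adjacency.shape != C.shape or adjacency.shape[0] != adjacency.shape[1]:
        raise ValueError("adjacency and correlation shapes must match and be square")
    n = adjacency.shape[0]
    labels = list(node_labels) if node_labels is not None else [str(i) for i in range(n)]
    absC = np.abs(C)
    weights = np.full((n, n), np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = -np.log(absC)
    on_edge = adjacency & np.isfinite(w) & (absC > 0)
    dropped = adjacency & ~on_edge
    if dropped.any():
        logger.warning(
            "dropping %d contact edges with |C|=0 or undefined correlation (infinite weight)",
            int(dropped.sum()) // 2,
        )
    weights[on_edge] = np.clip(w[on_edge], 0.0, None)
    np.fill_diagonal(weights, np.inf)
    return ContactNetwork(
        node_labels=labels,
        adjacency=on_edge,
        correlation=C,
        weights=weights,
    )


def suboptimal_paths(
    net: ContactNetwork,
    source: int,
    sink: int,
    tolerance: float = PATH_TOLERANCE,
    max_paths: int = 10_000,
) -> PathEnsemble:
    """All simple source->sink paths within `tolerance` of the optimal weight.

    All-pairs shortest distances come from the Floyd-Warshall algorithm;
    the suboptimal ensemble is enumerated by depth-first search pruned with
    the Floyd-Warshall distance-to-sink lower bound (a partial path is
    abandoned as soon as its weight plus the remaining shortest distance
    exceeds optimal + tolerance). Enumeration truncates with a warning at
    `max_paths` paths.
    """
    n = net.n_nodes
    if not (0 <= source < n and 0 <= sink < n):
        raise ValueError("source and sink must be valid node indices")
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    W = net.weights
    # masked dense input keeps genuine zero-weight edges (|C|=1 contacts)
    dist = floyd_warshall(np.ma.masked_invalid(W), directed=False)
    opt = dist[source, sink]
    if not np.isfinite(opt):
        logger.warning("source %d and sink %d are disconnected", source, sink)
        return PathEnsemble(source, sink, [], np.inf, [], {}, tolerance, connected=False)

    budget = opt + tolerance + 1e-12
    neighbors = [np.flatnonzero(np.isfinite(W[i])) for i in range(n)]
    paths: list[tuple[list[int], float]] = []
    truncated = False

    # iterative DFS over simple paths with optimistic pruning
    path: list[int] = []
    on_path = np.zeros(n, dtype=bool)
    frames: list[list[tuple[int, float]]] = [[(source, 0.0)]]
    while frames:
        frame = frames[-1]
        if not frame:
            frames.pop()
            if path:
                on_path[path.pop()] = False
            continue
        node, w_acc = frame.pop()
        if w_acc + dist[node, sink] > budget:
            continue
        path.append(node)
        on_path[node] = True
        if node == sink:
            paths.append((list(path), w_acc))
            on_path[path.pop()] = False
            if len(paths) >= max_paths:
                truncated = True
                break
            continue
        nxt = [
            (int(m), w_acc + W[node, m])
            for m in neighbors[node]
            if not on_path[m] and w_acc + W[node, m] + dist[m, sink] <= budget
        ]
        frames.append(nxt)
    if truncated:
        logger.warning("suboptimal path enumeration truncated at %d paths", max_paths)

    paths.sort(key=lambda pw: (pw[1], pw[0]))
    usage: dict[tuple[int, int], int] = {}
    for p, _ in paths:
        for a, b in zip(p[:-1], p[1:]):
            e = (min(a, b), max(a, b))
            usage[e] = usage.get(e, 0) + 1
    optimal_path, optimal_weight = (paths[0] if paths else ([], np.inf))
    return PathEnsemble(
        source=source,
        sink=sink,
        optimal_path=optimal_path,
        optimal_weight=float(optimal_weight),
        suboptimal_paths=paths,
        edge_usage=usage,
        tolerance=tolerance,
        truncated=truncated,
    )


def windowed_network_analysis(
    traj: Trajectory,
    node_selection: Sequence[tuple[str, np.ndarray]],
    source: int,
    sink: int,
    window_ns: float = 10.0,
    stride_ns: float = 0.4,
    tolerance: float = PATH_TOLERANCE,
    cutoff: float = 4.5,
    min_fraction: float = 0.75,
    max_paths: int = 10_000,
) -> tuple[list[PathEnsemble], dict[tuple[int, int], int]]:
    """Per-window network + suboptimal-path analysis with pooled edge usage.

    The trajectory is cut into consecutive non-overlapping windows of
    `window_ns`; within each window frames are resampled every `stride_ns`
    (10-ns windows at 400-ps stride give 25 frames per window). Contacts,
    correlations and suboptimal paths are computed per window and edge
    usage is pooled across windows.
    """
    if stride_ns > window_ns:
        raise ValueError("stride must not exceed the window length")
    frames_per_window = int(round(window_ns / traj.frame_interval_ns))
    stride_frames = max(int(round(stride_ns / traj.frame_interval_ns)), 1)
    if frames_per_window < 1 or traj.n_frames < frames_per_window:
        raise ValueError("trajectory shorter than one analysis window")
    ensembles: list[PathEnsemble] = []
    pooled: dict[tuple[int, int], int] = {}
    n_windows = traj.n_frames // frames_per_window
    for w in range(n_windows):
        frames = np.arange(w * frames_per_window, (w + 1) * frames_per_window, stride_frames)
        adjacency = contact_map(traj, node_selection, cutoff, min_fraction, frames=frames)
        C = correlation_matrix(traj, node_selection, frames=frames)
        net = build_network(adjacency, C, [lbl for lbl, _ in node_selection])
        ens = suboptimal_paths(net, source, sink, tolerance, max_paths)
        ensembles.append(ens)
        for e, c in ens.edge_usage.items():
            pooled[e] = pooled.get(e, 0) + c
    return ensembles, pooled
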