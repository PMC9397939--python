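"""Structural connectivity: loading, normalization, delays and graph metrics.

A connectome here is a symmetric, non-negative, zero-diagonal weight matrix
``W`` between brain areas (network nodes) together with a matched matrix of
white-matter tract lengths in millimetres.  Tract lengths divided by a
conduction speed (in mm per model time unit) give the pairwise interaction
delays used by the network model.  A subset of nodes is marked as
epileptogenic zones (EZ): candidate seizure-onset areas.

Weight matrices estimated from tractography carry heavy-tailed streamline
counts with occasional large artifacts; they are therefore truncated at the
95th percentile of all entries and rescaled by that threshold so that
``0 <= W_ij <= 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Connectome",
    "load_connectome",
    "write_matrix",
    "normalize_weights",
    "compute_delays",
    "graph_metrics",
]

#: default conduction speed, mm per model time unit
DEFAULT_SPEED = 60.0
#: default wall-clock duration of one model time unit, seconds
DEFAULT_TIME_UNIT_SECONDS = 0.02

_SYMMETRY_ATOL = 1e-12


@dataclass(frozen=True)
class Connectome:
    """A weighted structural brain network with interaction delays.

    Parameters
    ----------
    weights
        ``(n, n)`` symmetric non-negative coupling matrix, zero diagonal.
    tract_lengths
        ``(n, n)`` symmetric non-negative tract-length matrix, mm.
    ez_nodes
        Indices of epileptogenic-zone nodes (0-based, distinct).
    labels
        Optional node names.
    speed
        Conduction speed in mm per model time unit.
    time_unit_seconds
        Seconds per model time unit (used only for unit conversion).
    """

    weights: np.ndarray
    tract_lengths: np.ndarray
    ez_nodes: tuple[int, ...]
    labels: tuple[str, ...] | None = None
    speed: float = DEFAULT_SPEED
    time_unit_seconds: float = DEFAULT_TIME_UNIT_SECONDS
    delays: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        w = np.ascontiguousarray(np.asarray(self.weights, dtype=float))
        lengths = np.ascontiguousarray(np.asarray(self.tract_lengths, dtype=float))
        _check_square(w, "weights")
        _check_square(lengths, "tract_lengths")
        if w.shape != lengths.shape:
            raise ValueError(
                f"weights {w.shape} and tract_lengths {lengths.shape} differ in size"
            )
        for name, m in (("weights", w), ("tract_lengths", lengths)):
            if not np.isfinite(m).all():
                raise ValueError(f"{name} contains non-finite entries")
            if (m < 0).any():
                raise ValueError(f"{name} contains negative entries")
            if not np.allclose(m, m.T, atol=_SYMMETRY_ATOL, rtol=0.0):
                raise ValueError(f"{name} is not symmetric within {_SYMMETRY_ATOL}")
        if np.any(np.diag(w) != 0.0):
            raise ValueError("weights diagonal must be exactly zero")
        n = w.shape[0]
        ez = tuple(int(i) for i in self.ez_nodes)
        if len(set(ez)) != len(ez):
            raise ValueError(f"ez_nodes are not distinct: {ez}")
        for i in ez:
            if not 0 <= i < n:
                raise IndexError(f"EZ node {i} out of range for n_nodes={n}")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels length does not match matrix size")
        if self.speed <= 0:
            raise ValueError(f"speed must be positive, got {self.speed}")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "tract_lengths", lengths)
        object.__setattr__(self, "ez_nodes", ez)
        object.__setattr__(
            self, "delays", compute_delays(lengths, self.speed)
        )

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def normalized(self, percentile: float = 95.0) -> "Connectome":
        """Return a copy with :func:`normalize_weights` applied."""
        return replace(self, weights=normalize_weights(self.weights, percentile))

    def delay_seconds(self) -> np.ndarray:
        """Pairwise delays in seconds."""
        return self.delays * self.time_unit_seconds


def _check_square(m: np.ndarray, name: str) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {m.shape}")


def _read_matrix(path) -> np.ndarray:
    """Read a whitespace- or comma-delimited numeric matrix from text."""
    try:
        m = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError:
        m = np.loadtxt(path, ndmin=2)
    return m


def write_matrix(path, matrix: np.ndarray) -> None:
    """Write a matrix in the same plain-text dialect :func:`load_connectome` reads.

    Uses full repr precision so that a write/read round trip is bit-exact.
    """
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt="%.17g")


def load_connectome(
    weights_path,
    lengths_path,
    ez_nodes,
    *,
    labels=None,
    speed: float = DEFAULT_SPEED,
    time_unit_seconds: float = DEFAULT_TIME_UNIT_SECONDS,
    symmetrize: bool = False,
) -> Connectome:
    """Load raw (pre-normalization) weight and tract-length matrices.

    The weight diagonal is forced to zero on load: the diffusive coupling
    ``W_ij [x1_j - x1_i]`` makes self-terms vanish identically, and the
    stability analysis' row sums must not include a self-weight.

    Parameters
    ----------
    symmetrize
        If true, mildly asymmetric inputs are replaced by ``(M + M.T) / 2``
        instead of being rejected.
    """
    w = _read_matrix(weights_path)
    lengths = _read_matrix(lengths_path)
    _check_square(w, "weights")
    _check_square(lengths, "tract_lengths")
    if w.shape != lengths.shape:
        raise ValueError(
            f"weights {w.shape} and tract_lengths {lengths.shape} differ in size"
        )
    if symmetrize:
        w = 0.5 * (w + w.T)
        lengths = 0.5 * (lengths + lengths.T)
    np.fill_diagonal(w, 0.0)
    return Connectome(
        weights=w,
        tract_lengths=lengths,
        ez_nodes=tuple(ez_nodes),
        labels=tuple(labels) if labels is not None else None,
        speed=speed,
        time_unit_seconds=time_unit_seconds,
    )


def normalize_weights(weights: np.ndarray, percentile: float = 95.0) -> np.ndarray:
    """Truncate at the given percentile of all entries and rescale to [0, 1].

    The percentile is taken over all ``n**2`` entries (zero diagonal
    included) with linear interpolation; entries above the threshold are
    clipped to it, and everything is divided by the threshold so the
    maximum output is exactly 1.

    Raises
    ------
    ValueError
        If the threshold is zero (e.g. an all-zero matrix).
    """
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    t = float(np.percentile(w, percentile))
    if t <= 0.0:
        raise ValueError(
            f"percentile threshold is {t}; matrix too sparse or all-zero "
            f"for {percentile}th-percentile normalization"
        )
    return np.minimum(w, t) / t


def compute_delays(tract_lengths: np.ndarray, speed: float = DEFAULT_SPEED) -> np.ndarray:
    """Convert tract lengths (mm) into delays in model time units."""
    if speed <= 0:
        raise ValueError(f"speed must be positive, got {speed}")
    lengths = np.asarray(tract_lengths, dtype=float)
    if (lengths < 0).any():
        raise ValueError("tract lengths must be non-negative")
    return lengths / speed


def _distance_graph(conn: Connectome, cost: str) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(conn.n_nodes))
    rows, cols = np.nonzero(np.triu(conn.weights, k=1))
    for i, j in zip(rows.tolist(), cols.tolist()):
        wij = conn.weights[i, j]
        if cost == "inverse":
            dist = 1.0 / wij
        elif cost == "neglog":
            # weights in (0, 1] -> non-negative distances
            dist = -np.log(wij) if wij < 1.0 else 1e-12
        elif cost == "hops":
            dist = 1.0
        else:
            raise ValueError(f"unknown edge cost {cost!r}")
        g.add_edge(i, j, weight=wij, distance=dist)
    return g


def graph_metrics(conn: Connectome, ez: int, *, cost: str = "inverse") -> pd.DataFrame:
    """Per-node graph metrics relative to an active EZ node.

    Shortest paths run on edge costs derived from the coupling weights:
    ``"inverse"`` (default, cost 1/W so stronger links are shorter),
    ``"neglog"`` (cost -log W) or ``"hops"`` (unit cost).  Betweenness is
    unnormalized and uses the same costs; clustering is the weighted
    (Onnela) coefficient; eigenvector centrality is weight-based.
    Disconnected nodes get infinite path length.
    """
    if not 0 <= ez < conn.n_nodes:
        raise IndexError(f"EZ node {ez} out of range for n_nodes={conn.n_nodes}")
    g = _distance_graph(conn, cost)
    spl = nx.single_source_dijkstra_path_length(g, ez, weight="distance")
    path = np.full(conn.n_nodes, np.inf)
    for node, d in spl.items():
        path[node] = d
    btw = nx.betweenness_centrality(g, weight="distance", normalized=False)
    clu = nx.clustering(g, weight="weight")
    try:
        evc = nx.eigenvector_centrality_numpy(g, weight="weight")
    except (nx.NetworkXException, TypeError):
        evc = {i: np.nan for i in g.nodes}
    return pd.DataFrame(
        {
            "shortest_path_length_to_ez": path,
            "betweenness_centrality": [btw[i] for i in range(conn.n_nodes)],
            "clustering_coefficient": [clu[i] for i in range(conn.n_nodes)],
            "eigenvector_centrality": [evc[i] for i in range(conn.n_nodes)],
        },
        index=pd.RangeIndex(conn.n_nodes, name="node"),
    )
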