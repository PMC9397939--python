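"""Synthetic connectome generation.

Patient DTI connectomes are heavy-tailed weighted graphs: a few strong
white-matter bundles and many weak connections, with tract lengths set by
brain geometry (up to about 200 mm).  The generator emulates this by
placing nodes uniformly in a 3D box (~150 mm side), drawing log-normal
weights on a random subset of node pairs, and passing the result through
the same 95th-percentile truncation/normalization applied to real
matrices.  Tract lengths are Euclidean inter-node distances (capped at
200 mm) so that the delay structure correlates with topology, as in real
tractography.

Small deterministic fixtures (two-node, chain, star hub) expose specific
topologies for targeted tests of spread and rank prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectome import Connectome, normalize_weights

__all__ = ["SynthSpec", "synth_connectome", "synth_fixtures"]

#: cap on synthetic tract lengths, mm (longest fibers in patient data)
LENGTH_CAP_MM = 200.0
#: side of the 3D placement box, mm (roughly brain-sized)
BOX_SIDE_MM = 150.0


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a random synthetic connectome.

    ``density`` is the fraction of off-diagonal node pairs with a nonzero
    weight; weights are log-normal (heavy-tailed, emulating streamline
    counts) with the given log-mean and log-sd before normalization.
    """

    n_nodes: int
    density: float = 0.3
    log_mean: float = -1.0
    log_sd: float = 1.0
    ez_nodes: tuple[int, ...] = (0,)
    seed: int = 0
    box_side: float = BOX_SIDE_MM
    length_cap: float = LENGTH_CAP_MM

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if not 0.0 < self.density <= 1.0:
            raise ValueError(f"density must be in (0, 1], got {self.density}")


def synth_connectome(spec: SynthSpec) -> Connectome:
    """Generate a random connectome; reproducible from ``spec.seed``.

    Warns (without failing) if the requested density leaves the graph
    disconnected — disconnected fixtures are themselves useful.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes

    pos = rng.uniform(0.0, spec.box_side, size=(n, 3))
    diff = pos[:, None, :] - pos[None, :, :]
    lengths = np.minimum(np.sqrt((diff**2).sum(axis=-1)), spec.length_cap)
    np.fill_diagonal(lengths, 0.0)
    lengths = 0.5 * (lengths + lengths.T)  # guard against fp asymmetry

    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(len(iu)) < spec.density
    raw = np.zeros((n, n))
    vals = rng.lognormal(spec.log_mean, spec.log_sd, size=int(present.sum()))
    raw[iu[present], ju[present]] = vals
    raw = raw + raw.T
    try:
        weights = normalize_weights(raw)
    except ValueError:
        # matrices sparser than 5% make the all-entry percentile zero;
        # guard by taking the percentile over nonzero entries instead
        t = np.percentile(raw[raw > 0], 95)
        weights = np.minimum(raw, t) / t

    g = nx.from_numpy_array(weights)
    if not nx.is_connected(g):
        n_comp = nx.number_connected_components(g)
        warnings.warn(
            f"synthetic connectome is disconnected ({n_comp} components "
            f"at density {spec.density})",
            stacklevel=2,
        )
    return Connectome(
        weights=weights,
        tract_lengths=lengths,
        ez_nodes=spec.ez_nodes,
    )


def _geometric_lengths(n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, BOX_SIDE_MM, size=(n, 3))
    diff = pos[:, None, :] - pos[None, :, :]
    lengths = np.minimum(np.sqrt((diff**2).sum(axis=-1)), LENGTH_CAP_MM)
    np.fill_diagonal(lengths, 0.0)
    return 0.5 * (lengths + lengths.T)


def synth_fixtures(kind: str, n: int = 2, seed: int = 0) -> Connectome:
    """Deterministic test topologies with the EZ at node 0.

    * ``two_node``: a single symmetric link of weight 1.
    * ``chain``: nearest-neighbour links of weight 1, EZ at one end.
    * ``star_hub``: the EZ is the hub; leaves attach with strictly
      decreasing weights (geometric taper), so that predicted recruitment
      ranks have a known ordering to compare against simulation.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    w = np.zeros((n, n))
    if kind == "two_node":
        n = 2
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = 1.0
    elif kind == "chain":
        for i in range(n - 1):
            w[i, i + 1] = w[i + 1, i] = 1.0
    elif kind == "star_hub":
        taper = 0.8 ** np.arange(n - 1)
        for k, i in enumerate(range(1, n)):
            w[0, i] = w[i, 0] = taper[k]
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    lengths = _geometric_lengths(n, seed)
    lengths = np.where(w > 0, lengths, lengths)  # geometry regardless of edges
    return Connectome(weights=w, tract_lengths=lengths, ez_nodes=(0,))
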