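"""Deterministic drift of the Epileptor network model.

Each node of the network is a 6-variable fast--slow system
``(x1, y1, z, x2, y2, g)``: the (x1, y1) pair generates the slow ictal
oscillation, (x2, y2) the fast one, z is the slow "permittivity" variable
(ionic/metabolic drive) that switches seizures on and off, and g is a
low-pass filtered copy of x1 (integrated as ``g' = x1 - gamma*g``) used as
a smooth seizure-detection observable.

Nodes interact diffusively through z: node i's z-equation contains
``- w * sum_j W_ij [x1_j(t - tau_ij) - x1_i(t)] / tau0``, which vanishes
for identical states and can act either excitatorily or as a restraint.

A 2-variable reduction per node ``(x, z)`` with the same z-coupling is also
provided; it preserves the seizure-onset bifurcation structure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "EpileptorParams",
    "f1",
    "f2",
    "drift_full",
    "drift_reduced",
    "single_node_drift",
    "observe",
    "X0_EZ",
    "X0_SURROUND_RANGE",
]

#: excitability assigned to an active epileptogenic-zone node
X0_EZ = -1.6
#: default non-epileptic excitability range for surround nodes
X0_SURROUND_RANGE = (-2.3, -2.09)
#: reference critical excitability of an isolated node (see stability module)
X0_CRITICAL_SINGLE = -2.061

N_VARS_FULL = 6
N_VARS_REDUCED = 2

# state-variable indices in the full model
IX1, IY1, IZ, IX2, IY2, IG = range(6)


@dataclass(frozen=True)
class EpileptorParams:
    """Model constants plus the study's control parameters.

    ``tau0 >> tau2 >> tau1`` encodes the time-scale separation between the
    permittivity variable, the fast oscillation and the slow oscillation.
    ``w`` is the global connectivity strength scaling all couplings and
    ``sigma`` the standard deviation of the additive noise injected into
    the x2 and y2 equations by the simulator.
    """

    I1: float = 3.1
    I2: float = 0.45
    gamma: float = 0.01
    tau0: float = 6667.0
    tau1: float = 1.0
    tau2: float = 10.0
    w: float = 0.0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tau0 > self.tau2 > self.tau1 > 0):
            raise ValueError(
                "time scales must satisfy tau0 > tau2 > tau1 > 0, got "
                f"tau0={self.tau0}, tau2={self.tau2}, tau1={self.tau1}"
            )
        if self.w < 0:
            raise ValueError(f"coupling strength w must be >= 0, got {self.w}")
        if self.sigma < 0:
            raise ValueError(f"noise SD sigma must be >= 0, got {self.sigma}")

    def with_(self, **kwargs) -> "EpileptorParams":
        return replace(self, **kwargs)


def f1(x1, x2, z):
    """Fast-subsystem nonlinearity of the x1 equation.

    Piecewise: ``x1**3 - 3*x1**2`` for x1 < 0 and
    ``(x2 - 0.6*(z - 4)**2) * x1`` for x1 >= 0 (z enters only on the
    x1 >= 0 branch).  Continuous at x1 = 0.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    z = np.asarray(z, dtype=float)
    neg = x1 * x1 * (x1 - 3.0)
    pos = (x2 - 0.6 * (z - 4.0) ** 2) * x1
    return np.where(x1 < 0.0, neg, pos)


def f2(x2):
    """Nonlinearity of the y2 equation: 0 for x2 < -0.25, else 6*(x2 + 0.25)."""
    x2 = np.asarray(x2, dtype=float)
    return np.where(x2 < -0.25, 0.0, 6.0 * (x2 + 0.25))


def _check_state(state: np.ndarray, n_vars: int) -> np.ndarray:
    s = np.asarray(state, dtype=float)
    if s.ndim != 2 or s.shape[1] != n_vars:
        raise ValueError(f"state must have shape (n_nodes, {n_vars}), got {s.shape}")
    if not np.isfinite(s).all():
        raise FloatingPointError("state contains non-finite entries")
    return s


def _coupling(x1: np.ndarray, weights: np.ndarray, w: float, delayed_x1=None):
    """Diffusive coupling term ``sum_j W_ij [x1_j(t - tau_ij) - x1_i]``.

    ``delayed_x1`` is an (n, n) matrix with entry (i, j) holding
    ``x1_j(t - tau_ij)``; when None the current x1 is used (zero delays).
    """
    if delayed_x1 is None:
        return w * (weights @ x1 - weights.sum(axis=1) * x1)
    delayed_x1 = np.asarray(delayed_x1, dtype=float)
    return w * ((weights * delayed_x1).sum(axis=1) - weights.sum(axis=1) * x1)


def drift_full(
    state: np.ndarray,
    params: EpileptorParams,
    weights: np.ndarray,
    x0: np.ndarray,
    delayed_x1: np.ndarray | None = None,
) -> np.ndarray:
    """Deterministic time-derivative of the full 6D-per-node network.

    Parameters
    ----------
    state
        ``(n, 6)`` array of per-node states ``(x1, y1, z, x2, y2, g)``.
    weights
        ``(n, n)`` symmetric coupling matrix (normalized).
    x0
        Per-node excitability vector.
    delayed_x1
        Optional ``(n, n)`` matrix of delayed neighbours
        ``x1_j(t - tau_ij)``; current values are used when omitted.
    """
    s = _check_state(state, N_VARS_FULL)
    x0 = np.asarray(x0, dtype=float)
    x1, y1, z, x2, y2, g = (s[:, k] for k in range(6))
    p = params
    coup = _coupling(x1, np.asarray(weights, dtype=float), p.w, delayed_x1)
    out = np.empty_like(s)
    out[:, IX1] = y1 - f1(x1, x2, z) - z + p.I1
    out[:, IY1] = (1.0 - 5.0 * x1 * x1 - y1) / p.tau1
    out[:, IZ] = (4.0 * (x1 - x0) - z - coup) / p.tau0
    out[:, IX2] = -y2 + x2 - x2**3 + p.I2 + 0.002 * g - 0.3 * (z - 3.5)
    out[:, IY2] = (-y2 + f2(x2)) / p.tau2
    out[:, IG] = x1 - p.gamma * g
    return out


def drift_reduced(
    state: np.ndarray,
    params: EpileptorParams,
    weights: np.ndarray,
    x0: np.ndarray,
    delayed_x: np.ndarray | None = None,
) -> np.ndarray:
    """Deterministic drift of the 2D-per-node reduced network ``(x, z)``."""
    s = _check_state(state, N_VARS_REDUCED)
    x0 = np.asarray(x0, dtype=float)
    x, z = s[:, 0], s[:, 1]
    p = params
    coup = _coupling(x, np.asarray(weights, dtype=float), p.w, delayed_x)
    out = np.empty_like(s)
    out[:, 0] = -(x**3) - 2.0 * x * x + 1.0 - z + p.I1
    out[:, 1] = (4.0 * (x - x0) - z - coup) / p.tau0
    return out


def single_node_drift(state, params: EpileptorParams, x0: float, model: str = "full"):
    """Drift of one isolated node (w = 0); state is a flat vector."""
    n_vars = N_VARS_FULL if model == "full" else N_VARS_REDUCED
    s = np.asarray(state, dtype=float).reshape(1, n_vars)
    zero_w = np.zeros((1, 1))
    fn = drift_full if model == "full" else drift_reduced
    return fn(s, params.with_(w=0.0), zero_w, np.array([x0])).ravel()


def observe(state: np.ndarray) -> np.ndarray:
    """Observable ``x2 - x1`` per node (full model only).

    Accepts a single ``(n, 6)`` state or a stacked ``(steps, n, 6)``
    trajectory, returning ``(n,)`` or ``(steps, n)`` respectively.
    """
    s = np.asarray(state, dtype=float)
    if s.shape[-1] == N_VARS_REDUCED:
        raise ValueError("observable x2 - x1 is undefined for the reduced model")
    if s.shape[-1] != N_VARS_FULL:
        raise ValueError(f"expected trailing state dimension 6, got {s.shape}")
    return s[..., IX2] - s[..., IX1]
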