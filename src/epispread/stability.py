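"""Linear stability analysis of Epileptor networks.

Phase prediction uses two Jacobians evaluated at fixed points of the
deterministic network (delays set to zero, which is justified because
nodes interact through the slow permittivity variable z):

* the *with-EZ* Jacobian of the full network with the active EZ node at
  epileptic excitability ``x0 = -1.6`` — its leading eigenvalue real part
  ``lambda_R`` decides whether a seizure can start at all;
* the *EZ-removed* Jacobian of the surround-only network in which the EZ
  node is replaced by a constant drive ``x1_bar`` (the average of the EZ's
  x1 during an isolated seizure), entering each neighbour's z-equation
  through the usual diffusive coupling with ``x1_EZ`` frozen — its leading
  eigenvalue ``lambda_tilde_R`` decides whether the surround, driven by a
  seizing EZ, is itself unstable (i.e. whether the seizure spreads).

Joint sign rule: ``lambda_R < 0`` -> no seizure; ``lambda_R > 0`` and
``lambda_tilde_R < 0`` -> seizure without spread; both positive -> spread.
When spread is predicted, the z-components of the with-EZ leading
eigenvector, ``|v_z,i|``, rank the surround nodes: larger magnitude means
earlier recruitment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .connectome import Connectome
from .model_core import (
    IZ,
    N_VARS_FULL,
    N_VARS_REDUCED,
    X0_EZ,
    EpileptorParams,
    drift_full,
    drift_reduced,
    f2,
    single_node_drift,
)

__all__ = [
    "StabilityReport",
    "find_fixed_points_single",
    "single_node_stable_fixed_point",
    "critical_excitability_single",
    "ez_mean_drive",
    "find_network_fixed_point",
    "build_jacobian",
    "network_jacobian",
    "phase_from_eigenvalues",
    "classify_phase",
    "recruitment_ranks",
]

RESIDUAL_TOL = 1e-9
DEDUP_TOL = 1e-6
#: eigenvalues here scale with 1/tau0 (~1.5e-4), so the sign threshold is tight
EIG_ZERO_TOL = 1e-9

PHASE_NO_SEIZURE = "no_seizure"
PHASE_NO_SPREAD = "no_spread"
PHASE_SPREAD = "spread"


@dataclass(frozen=True)
class StabilityReport:
    """Outcome of the two-Jacobian analysis for one parameter point."""

    fixed_point: np.ndarray            # (n, 6) or (n, 2) with-EZ network fixed point
    lambda_R: float                    # leading eigenvalue real part, with-EZ Jacobian
    lambda_tilde_R: float              # same, EZ-removed Jacobian
    x1_ez_mean: float                  # constant drive replacing the EZ
    v_z: np.ndarray                    # |v_z,i| per surround node (EZ excluded)
    surround_nodes: np.ndarray         # node indices matching v_z
    predicted_phase: str
    active_ez: int
    x0_surround: float
    w: float
    model: str

    @property
    def predicted_ranks(self) -> np.ndarray:
        """Rank per surround node (1 = recruited first), ties by node index."""
        order = np.lexsort((self.surround_nodes, -self.v_z))
        ranks = np.empty(len(self.v_z), dtype=int)
        ranks[order] = np.arange(1, len(self.v_z) + 1)
        return ranks


# ---------------------------------------------------------------------------
# single-node fixed points

def _n_vars(model: str) -> int:
    if model == "full":
        return N_VARS_FULL
    if model == "reduced":
        return N_VARS_REDUCED
    raise ValueError(f"model must be 'full' or 'reduced', got {model!r}")


#: default x1 seeds: the hyperpolarized resting branch, where the search
#: protocol for this model starts (a wider grid may be passed explicitly)
DEFAULT_X1_STARTS = (-2.5, -2.0, -1.5, -1.0, -0.6, -0.3, -0.1)


def _single_starts(
    params: EpileptorParams, x0: float, model: str, x1_starts=DEFAULT_X1_STARTS
) -> list[np.ndarray]:
    """Structured multi-start grid: nullcline-consistent seeds over (x1, x2)."""
    starts = []
    x1_grid = np.asarray(x1_starts, dtype=float)
    if model == "reduced":
        for x in x1_grid:
            starts.append(np.array([x, 4.0 * (x - x0)]))
        return starts
    x2_grid = np.array([-2.0, -1.25, -0.6, -0.3, 0.0, 0.6, 1.25])
    for x in x1_grid:
        z = 4.0 * (x - x0)
        y1 = 1.0 - 5.0 * x * x
        g = x / params.gamma
        for x2 in x2_grid:
            starts.append(np.array([x, y1, z, x2, float(f2(x2)), g]))
    return starts


def find_fixed_points_single(
    params: EpileptorParams,
    x0: float,
    model: str = "full",
    x1_starts=DEFAULT_X1_STARTS,
) -> list[tuple[np.ndarray, str]]:
    """Fixed points of one isolated node, each tagged stable/unstable.

    Multi-start root search on the deterministic single-node drift;
    distinct roots are deduplicated at ``1e-6`` relative tolerance and kept
    only if the drift residual is below ``1e-9`` in max-norm.  Stability is
    the sign of the largest real part of the node Jacobian's eigenvalues.
    The default seeds cover the hyperpolarized resting branch (where the
    model's three physiological fixed points live); supply a wider
    ``x1_starts`` grid to explore the depolarized branch as well.
    """
    fun = lambda s: single_node_drift(s, params, x0, model)  # noqa: E731
    roots: list[np.ndarray] = []
    tried = 0
    for start in _single_starts(params, x0, model, x1_starts):
        tried += 1
        sol = scipy.optimize.root(fun, start, method="hybr", tol=1e-13)
        if not sol.success:
            continue
        root = sol.x
        if np.abs(fun(root)).max() > RESIDUAL_TOL:
            continue
        if any(
            np.allclose(root, r, rtol=DEDUP_TOL, atol=DEDUP_TOL) for r in roots
        ):
            continue
        roots.append(root)
    if not roots:
        raise RuntimeError(
            f"no fixed point found for x0={x0}, model={model} "
            f"after {tried} starts"
        )
    out = []
    for root in sorted(roots, key=lambda r: r[0]):
        jac = _single_node_jacobian(root, params, model)
        lam = np.linalg.eigvals(jac).real.max()
        out.append((root, "stable" if lam < 0 else "unstable"))
    return out


def _single_node_jacobian(state, params: EpileptorParams, model: str) -> np.ndarray:
    """Analytic Jacobian of one isolated node (w = 0)."""
    zero_w = np.zeros((1, 1))
    s = np.asarray(state, dtype=float).reshape(1, -1)
    return build_jacobian(s, zero_w, np.zeros(1), params.with_(w=0.0), model=model)


def single_node_stable_fixed_point(
    params: EpileptorParams, x0: float, model: str = "full"
) -> np.ndarray:
    """The unique stable fixed point of an isolated node at excitability x0."""
    stable = [r for r, c in find_fixed_points_single(params, x0, model) if c == "stable"]
    if not stable:
        raise RuntimeError(f"no stable fixed point at x0={x0} (epileptogenic regime?)")
    if len(stable) > 1:
        raise RuntimeError(f"multiple stable fixed points at x0={x0}")
    return stable[0]


def _resting_fixed_point(params: EpileptorParams, x0: float, model: str) -> np.ndarray:
    """Resting-branch fixed point (most hyperpolarized x1), any stability."""
    fps = find_fixed_points_single(params, x0, model)
    return min(fps, key=lambda rc: rc[0][0])[0]


def critical_excitability_single(
    params: EpileptorParams,
    model: str = "full",
    bracket: tuple[float, float] = (-2.3, -1.6),
    tol: float = 1e-4,
) -> float:
    """Critical excitability of an isolated node, by bisection on x0.

    Below the critical value a stable (non-epileptic) fixed point exists;
    above it the node has no stable fixed point and seizes spontaneously.
    """
    lo, hi = bracket

    def has_stable(x0: float) -> bool:
        return any(c == "stable" for _, c in find_fixed_points_single(params, x0, model))

    stable_lo, stable_hi = has_stable(lo), has_stable(hi)
    if stable_lo == stable_hi:
        raise ValueError(
            f"bracket {bracket} does not straddle the stability change "
            f"(stable at both ends: {stable_lo})"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if has_stable(mid) == stable_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# constant EZ drive

_EZ_DRIVE_CACHE: dict[tuple, float] = {}


def ez_mean_drive(params: EpileptorParams, x0_surround: float = -2.2) -> float:
    """Average of the EZ node's x1 over one isolated, noise-free seizure.

    Simulates a single uncoupled node started at the stable fixed point of
    a non-epileptic excitability, switched to ``x0 = -1.6``; x1 is averaged
    between the detected seizure onset and offset.  Deterministic, cached.
    """
    key = (params.I1, params.I2, params.gamma, params.tau0, params.tau1,
           params.tau2, float(x0_surround))
    if key not in _EZ_DRIVE_CACHE:
        from .simulator import reference_isolated_seizure

        ref = reference_isolated_seizure(params, x0_surround=x0_surround)
        _EZ_DRIVE_CACHE[key] = float(ref.x1_mean)
    return _EZ_DRIVE_CACHE[key]


# ---------------------------------------------------------------------------
# network fixed points

def _network_drift(conn, params, x0_vec, model):
    weights = conn.weights
    fn = drift_full if model == "full" else drift_reduced
    nv = _n_vars(model)
    n = conn.n_nodes

    def fun(flat):
        return fn(flat.reshape(n, nv), params, weights, x0_vec).ravel()

    return fun


#: per-equation scaling (by each equation's time constant) used during root
#: finding only; roots are unchanged but the Jacobian is far better
#: conditioned than with raw rates spanning 1 to 1/tau0
def _equation_scale(params: EpileptorParams, model: str) -> np.ndarray:
    if model == "reduced":
        return np.array([1.0, params.tau0])
    return np.array([1.0, params.tau1, params.tau0, 1.0, params.tau2, 1.0])


def _solve_x1_balance(
    x0_vec: np.ndarray,
    params: EpileptorParams,
    weights: np.ndarray,
    drive_weights: np.ndarray | None = None,
    x1_bar: float = 0.0,
) -> np.ndarray:
    """Resting-branch x1 at equilibrium.

    On the hyperpolarized branch (x1 < 0) the x1/z equilibrium conditions
    close on themselves: eliminating z gives
    ``4(x1_i - x0_i) + x1_i^3 + 2 x1_i^2 - 1 - I1 - coupling_i = 0``,
    a diagonally dominant system with a unique solution.  ``drive_weights``
    adds the frozen-EZ diffusive term ``w * W_i,EZ (x1_bar - x1_i)``.
    """
    w = params.w
    rs = weights.sum(axis=1)

    def h(x1):
        z = -(x1**3) - 2.0 * x1 * x1 + 1.0 + params.I1
        val = 4.0 * (x1 - x0_vec) - z - w * (weights @ x1 - rs * x1)
        if drive_weights is not None:
            val = val - w * drive_weights * (x1_bar - x1)
        return val

    sol = scipy.optimize.root(h, np.full(len(x0_vec), -1.4), method="hybr", tol=1e-13)
    if not sol.success or np.abs(h(sol.x)).max() > 1e-10:
        raise RuntimeError(
            f"x1 equilibrium balance did not converge "
            f"(residual {np.abs(h(sol.x)).max():.3e})"
        )
    if (sol.x >= 0).any():
        raise RuntimeError(
            "equilibrium x1 crossed into the depolarized branch; "
            "no resting fixed point"
        )
    return sol.x


def _resting_x2(z: float, g: float, params: EpileptorParams) -> tuple[float, float]:
    """Resting-branch (x2, y2) at equilibrium, given the node's z and g.

    The x2 nullcline on the f2 = 0 piece is the cubic
    ``x2 - x2^3 + I2 + 0.002 g - 0.3 (z - 3.5) = 0``; the resting root is
    the most negative real root on the stable branch ``x2 <= -1/sqrt(3)``.
    Raises when that root has vanished through its fold (seizure onset).
    """
    c = params.I2 + 0.002 * g - 0.3 * (z - 3.5)
    roots = np.roots([-1.0, 0.0, 1.0, c])
    rest = [
        r.real
        for r in roots
        if abs(r.imag) < 1e-9 and r.real <= -1.0 / np.sqrt(3.0) + 1e-12
    ]
    if not rest:
        raise RuntimeError(
            "resting x2 branch has vanished (fold crossed); no stable-branch "
            "fixed point to linearize at"
        )
    return float(min(rest)), 0.0


def _make_ez_removed_drift(weights, ez, params, x0_surround, x1_bar, model):
    """Drift of the surround-only network with the EZ frozen at ``x1_bar``.

    The EZ node's contribution to neighbour j's z-equation keeps the
    diffusive form ``w * W_j,EZ [x1_bar - x1_j]`` with x1_EZ constant.
    """
    n = weights.shape[0]
    keep = np.array([i for i in range(n) if i != ez])
    w_sub = weights[np.ix_(keep, keep)]
    w_ez = weights[keep, ez]
    nv = _n_vars(model)
    m = n - 1
    x0_vec = np.full(m, x0_surround)
    fn = drift_full if model == "full" else drift_reduced
    iz = IZ if model == "full" else 1

    def fun(flat):
        s = flat.reshape(m, nv)
        d = fn(s, params, w_sub, x0_vec)
        x1 = s[:, 0]
        # frozen-EZ diffusive term enters z with the same -w/tau0 prefactor
        d[:, iz] -= params.w * w_ez * (x1_bar - x1) / params.tau0
        return d.ravel()

    return fun, keep, w_sub, w_ez


def _assemble_resting_state(
    x1: np.ndarray, params: EpileptorParams, model: str
) -> np.ndarray:
    """Lift an equilibrium x1 vector to the resting-branch network state."""
    z = -(x1**3) - 2.0 * x1 * x1 + 1.0 + params.I1
    if model == "reduced":
        return np.column_stack([x1, z])
    g = x1 / params.gamma
    y1 = 1.0 - 5.0 * x1 * x1
    x2 = np.empty_like(x1)
    y2 = np.empty_like(x1)
    for i in range(len(x1)):
        x2[i], y2[i] = _resting_x2(z[i], g[i], params)
    return np.column_stack([x1, y1, z, x2, y2, g])


def _polish_root(fun, start: np.ndarray, scale: np.ndarray, what: str) -> np.ndarray:
    m, nv = start.shape

    def scaled(flat):
        return (fun(flat).reshape(m, nv) * scale).ravel()

    sol = scipy.optimize.root(scaled, start.ravel(), method="hybr", tol=1e-13)
    res = np.abs(fun(sol.x)).max()
    if res > RESIDUAL_TOL:
        raise RuntimeError(
            f"{what}: fixed-point polish did not converge "
            f"(residual {res:.3e}, nfev={sol.nfev})"
        )
    return sol.x.reshape(m, nv)


def find_network_fixed_point(
    conn: Connectome,
    params: EpileptorParams,
    x0_surround: float,
    active_ez: int,
    variant: str = "with_ez",
    model: str = "full",
    x1_ez_mean: float | None = None,
) -> np.ndarray:
    """Resting-branch fixed point of the deterministic network, delays zero.

    ``variant="with_ez"`` solves the full n-node network with the active EZ
    at ``x0 = -1.6``; ``variant="ez_removed"`` solves the (n-1)-node
    surround network with the EZ replaced by the constant drive
    ``x1_ez_mean``.  The resting branch is tracked explicitly (it continues
    the tiled single-node stable fixed point): the closed x1/z balance is
    solved first, each node's (x2, y2) is taken on the resting piece of its
    nullcline, and the assembled state is polished by a root solve of the
    full drift.  Returns an ``(m, n_vars)`` state with drift residual below
    ``1e-9``; raises when the resting branch no longer exists (the network
    has been pushed past the seizure-onset fold).
    """
    n = conn.n_nodes
    scale = _equation_scale(params, model)
    if variant == "with_ez":
        x0_vec = np.full(n, x0_surround)
        x0_vec[active_ez] = X0_EZ
        x1 = _solve_x1_balance(x0_vec, params, conn.weights)
        start = _assemble_resting_state(x1, params, model)
        fun = _network_drift(conn, params, x0_vec, model)
        return _polish_root(fun, start, scale, "with_ez")
    if variant == "ez_removed":
        if x1_ez_mean is None:
            x1_ez_mean = ez_mean_drive(params, x0_surround=x0_surround)
        keep = np.array([i for i in range(n) if i != active_ez])
        w_sub = conn.weights[np.ix_(keep, keep)]
        w_ez = conn.weights[keep, active_ez]
        x0_vec = np.full(n - 1, x0_surround)
        x1 = _solve_x1_balance(
            x0_vec, params, w_sub, drive_weights=w_ez, x1_bar=x1_ez_mean
        )
        start = _assemble_resting_state(x1, params, model)
        fun, _, _, _ = _make_ez_removed_drift(
            conn.weights, active_ez, params, x0_surround, x1_ez_mean, model
        )
        return _polish_root(fun, start, scale, "ez_removed")
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# Jacobian assembly

def _df1_partials(x1, x2, z):
    """(df1/dx1, df1/dx2, df1/dz); the x1 >= 0 branch carries x2 and z terms."""
    neg = x1 < 0.0
    d_x1 = np.where(neg, 3.0 * x1 * x1 - 6.0 * x1, x2 - 0.6 * (z - 4.0) ** 2)
    d_x2 = np.where(neg, 0.0, x1)
    d_z = np.where(neg, 0.0, -1.2 * (z - 4.0) * x1)
    return d_x1, d_x2, d_z


def build_jacobian(
    fixed_point: np.ndarray,
    weights_offdiag: np.ndarray,
    row_sum_weights: np.ndarray,
    params: EpileptorParams,
    model: str = "full",
) -> np.ndarray:
    """Analytic network Jacobian at a fixed point, delays ignored.

    The matrix is variable-major: block (a, b) is the m-by-m matrix of
    partials of variable-a equations with respect to variable b, in the
    order (x1, y1, z, x2, y2, g) for the full model and (x, z) reduced.

    ``weights_offdiag`` supplies the off-diagonal coupling W_ij of the
    system actually being linearized, while ``row_sum_weights`` holds each
    node's total incident weight (for the EZ-removed variant this still
    includes the weight to the frozen EZ, whose term depends on x1_i).
    The z-row coupling block is
    ``(1/tau0) * (delta_ij * (4 + w * rowsum_i) - (1 - delta_ij) * w * W_ij)``.
    """
    s = np.asarray(fixed_point, dtype=float)
    m = s.shape[0]
    p = params
    eye = np.eye(m)
    w_off = np.asarray(weights_offdiag, dtype=float)
    rows = np.asarray(row_sum_weights, dtype=float)
    j_z_x1 = (np.diag(4.0 + p.w * rows) - p.w * (w_off - np.diag(np.diag(w_off)))) / p.tau0

    if model == "reduced":
        x, _ = s[:, 0], s[:, 1]
        jac = np.zeros((2 * m, 2 * m))
        jac[0:m, 0:m] = np.diag(-3.0 * x * x - 4.0 * x)
        jac[0:m, m:2 * m] = -eye
        jac[m:2 * m, 0:m] = j_z_x1
        jac[m:2 * m, m:2 * m] = -eye / p.tau0
        return jac

    x1, _, z, x2, _, _ = (s[:, k] for k in range(6))
    d1_x1, d1_x2, d1_z = _df1_partials(x1, x2, z)
    df2 = np.where(x2 < -0.25, 0.0, 6.0)

    jac = np.zeros((6 * m, 6 * m))

    def blk(a, b, mat):
        jac[a * m:(a + 1) * m, b * m:(b + 1) * m] = mat

    blk(0, 0, np.diag(-d1_x1))              # x1 row
    blk(0, 1, eye)
    blk(0, 2, np.diag(-d1_z) - eye)
    blk(0, 3, np.diag(-d1_x2))
    blk(1, 0, np.diag(-10.0 * x1 / p.tau1))  # y1 row
    blk(1, 1, -eye / p.tau1)
    blk(2, 0, j_z_x1)                        # z row
    blk(2, 2, -eye / p.tau0)
    blk(3, 2, -0.3 * eye)                    # x2 row
    blk(3, 3, np.diag(1.0 - 3.0 * x2 * x2))
    blk(3, 4, -eye)
    blk(3, 5, 0.002 * eye)
    blk(4, 3, np.diag(df2 / p.tau2))         # y2 row
    blk(4, 4, -eye / p.tau2)
    blk(5, 0, eye)                           # g row
    blk(5, 5, -p.gamma * eye)
    return jac


def network_jacobian(
    conn: Connectome,
    params: EpileptorParams,
    fixed_point: np.ndarray,
    active_ez: int,
    variant: str = "with_ez",
    model: str = "full",
) -> np.ndarray:
    """Jacobian of the chosen network variant at its fixed point."""
    w = conn.weights
    if variant == "with_ez":
        return build_jacobian(fixed_point, w, w.sum(axis=1), params, model)
    if variant == "ez_removed":
        n = conn.n_nodes
        keep = np.array([i for i in range(n) if i != active_ez])
        w_sub = w[np.ix_(keep, keep)]
        rows = w_sub.sum(axis=1) + w[keep, active_ez]
        return build_jacobian(fixed_point, w_sub, rows, params, model)
    raise ValueError(f"unknown variant {variant!r}")


def _leading_eig(jac: np.ndarray) -> tuple[float, np.ndarray]:
    vals, vecs = scipy.linalg.eig(jac)
    k = int(np.argmax(vals.real))
    vec = vecs[:, k]
    vec = vec / np.linalg.norm(vec)
    return float(vals[k].real), vec


# ---------------------------------------------------------------------------
# phase classification and ranks

def phase_from_eigenvalues(lambda_R: float, lambda_tilde_R: float) -> str:
    """Joint-sign phase rule on the two leading eigenvalue real parts.

    A stable with-EZ fixed point (``lambda_R < 0``) means no seizure
    regardless of the surround variant; an unstable one with a stable
    EZ-removed surround means the seizure stays local; both unstable means
    spread.
    """
    if lambda_R < EIG_ZERO_TOL:
        return PHASE_NO_SEIZURE
    if lambda_tilde_R < EIG_ZERO_TOL:
        return PHASE_NO_SPREAD
    return PHASE_SPREAD


def classify_phase(
    conn: Connectome,
    params: EpileptorParams,
    x0_surround: float,
    active_ez: int,
    model: str = "full",
    x1_ez_mean: float | None = None,
) -> StabilityReport:
    """Two-Jacobian phase prediction for one (x0_surround, w) point.

    ``lambda_R < 0`` -> no_seizure (the surround stabilizes even the active
    EZ); ``lambda_R > 0, lambda_tilde_R < 0`` -> no_spread; both positive
    -> spread.  The leading with-EZ eigenvector's z-component moduli give
    the predicted recruitment order of the surround.

    A variant whose fixed point has vanished (the constant drive or the EZ
    pushed the system past its saddle-node, leaving no equilibrium to
    linearize at) is maximally unstable: its eigenvalue is reported as
    ``+inf``.
    """
    if active_ez not in conn.ez_nodes:
        raise ValueError(f"node {active_ez} is not in ez_nodes {conn.ez_nodes}")
    if x1_ez_mean is None:
        x1_ez_mean = ez_mean_drive(params, x0_surround=x0_surround)

    n = conn.n_nodes
    surround = np.array([i for i in range(n) if i != active_ez])
    try:
        fp = find_network_fixed_point(
            conn, params, x0_surround, active_ez, "with_ez", model
        )
        jac = network_jacobian(conn, params, fp, active_ez, "with_ez", model)
        lam, vec = _leading_eig(jac)
        iz = IZ if model == "full" else 1
        v_z = np.abs(vec[iz * n:(iz + 1) * n])[surround]
    except RuntimeError:
        fp = np.full((n, _n_vars(model)), np.nan)
        lam = np.inf
        v_z = np.full(n - 1, np.nan)

    try:
        fp_rm = find_network_fixed_point(
            conn, params, x0_surround, active_ez, "ez_removed", model,
            x1_ez_mean=x1_ez_mean,
        )
        jac_rm = network_jacobian(conn, params, fp_rm, active_ez, "ez_removed", model)
        lam_rm, _ = _leading_eig(jac_rm)
    except RuntimeError:
        lam_rm = np.inf

    phase = phase_from_eigenvalues(lam, lam_rm)

    return StabilityReport(
        fixed_point=fp,
        lambda_R=lam,
        lambda_tilde_R=lam_rm,
        x1_ez_mean=float(x1_ez_mean),
        v_z=v_z,
        surround_nodes=surround,
        predicted_phase=phase,
        active_ez=active_ez,
        x0_surround=float(x0_surround),
        w=params.w,
        model=model,
    )


def recruitment_ranks(report: StabilityReport) -> pd.DataFrame:
    """Predicted recruitment order of surround nodes (rank 1 = earliest).

    Only meaningful when spread is predicted; ties in ``|v_z,i|`` are
    broken by ascending node index.
    """
    if report.predicted_phase != PHASE_SPREAD:
        raise RuntimeError(
            f"recruitment ranks require predicted_phase='spread', "
            f"got {report.predicted_phase!r}"
        )
    return pd.DataFrame(
        {
            "node": report.surround_nodes,
            "v_z": report.v_z,
            "rank": report.predicted_ranks,
        }
    ).set_index("node")
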