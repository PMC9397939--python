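"""Stochastic delayed integration of the Epileptor network and spread extraction.

The seizure protocol is: start every node at the stable resting state of an
isolated non-epileptic node, integrate with noise for a settle period, then
switch the selected active EZ node to epileptic excitability
(``x0 = -1.6``).  A seizure may then start in the EZ and possibly recruit
surround nodes.  When a seizure terminates in any node (its smooth
observable g falls back below the offset threshold), that node enters a
postictal refractory state implemented by uncoupling it from the network
for the rest of the run; if it is the active EZ its excitability also
reverts to the surround value.

Integration uses the stochastic Heun predictor--corrector scheme with the
Wiener increments of the x2 and y2 equations drawn i.i.d. Gaussian with
variance ``sigma**2 * dt`` (the noise is additive, so the scheme is
unbiased for the Ito system).  Delayed neighbour values
``x1_j(t - tau_ij)`` are served from a ring buffer with delays rounded to
the nearest integer step.

Seizure onset/offset per node is detected online from threshold crossings
of g with hysteresis: onset at the first upward crossing of the onset
threshold after EZ activation, offset at the subsequent downward crossing
of the lower offset threshold.  Thresholds are auto-calibrated from a
reference noise-free isolated-EZ run as baseline plus half (onset) or 0.45
(offset) of the baseline-to-ictal-plateau rise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .connectome import Connectome
from .model_core import EpileptorParams, X0_EZ, observe

__all__ = [
    "Protocol",
    "Trajectory",
    "SpreadOutcome",
    "ReferenceSeizure",
    "reference_isolated_seizure",
    "calibrate_threshold",
    "simulate_seizure_protocol",
    "run_protocol",
    "extract_spread",
    "PHASE_NO_SEIZURE",
    "PHASE_NO_SPREAD",
    "PHASE_SPREAD",
]

PHASE_NO_SEIZURE = "no_seizure"
PHASE_NO_SPREAD = "no_spread"
PHASE_SPREAD = "spread"

#: offset threshold sits at this fraction of the onset rise above baseline
HYSTERESIS_FRACTION = 0.9


@dataclass(frozen=True)
class Protocol:
    """Integration and seizure-protocol settings.

    ``max_steps`` caps the run after EZ activation.  With ``early_stop``
    the run ends once the active EZ seizure has terminated, no node is
    ictal and ``cooldown_steps`` have passed without events.
    ``threshold`` overrides the auto-calibrated onset threshold on g.
    """

    active_ez: int = 0
    x0_surround: float = -2.2
    dt: float = 0.05
    settle_steps: int = 20_000
    max_steps: int = 200_000
    rng_seed: int = 0
    threshold: float | None = None
    activate_ez: bool = True
    store_states: bool = True
    record_stride: int = 1
    early_stop: bool = True
    cooldown_steps: int = 20_000
    divergence_bound: float = 1e4

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.settle_steps < 0 or self.max_steps <= 0:
            raise ValueError("settle_steps must be >= 0 and max_steps > 0")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")


@dataclass(frozen=True)
class Trajectory:
    """Stored states of one run plus the online event log.

    ``states`` has shape (recorded_steps, n, 6) (empty when not stored)
    sampled every ``record_stride`` steps; event steps are in un-strided
    integration steps from the start of the run (-1 where absent).
    """

    times: np.ndarray
    states: np.ndarray
    dt: float
    record_stride: int
    settle_steps: int
    active_ez: int
    onset_steps: np.ndarray
    offset_steps: np.ndarray
    uncouple_steps: np.ndarray
    threshold: float
    threshold_off: float
    n_steps: int

    @property
    def observable(self) -> np.ndarray:
        """x2 - x1 per recorded step and node."""
        return observe(self.states)


@dataclass(frozen=True)
class SpreadOutcome:
    """Coarse-grained result of one run: who seized, when, and the phase."""

    recruited: np.ndarray          # (n,) of {0, 1}
    onset_times: np.ndarray        # model time units, NaN if not recruited
    offset_times: np.ndarray
    active_ez: int
    phase: str = field(init=False)

    def __post_init__(self) -> None:
        if self.spread_size == 0:
            phase = PHASE_NO_SEIZURE
        elif self.spread_size == 1 and self.recruited[self.active_ez]:
            phase = PHASE_NO_SPREAD
        else:
            phase = PHASE_SPREAD
        object.__setattr__(self, "phase", phase)

    @property
    def spread_size(self) -> int:
        return int(self.recruited.sum())

    @property
    def spread_fraction(self) -> float:
        return self.spread_size / len(self.recruited)

    def onset_order(self) -> np.ndarray:
        """Recruited node indices sorted by onset time."""
        rec = np.flatnonzero(self.recruited)
        return rec[np.argsort(self.onset_times[rec], kind="stable")]


# ---------------------------------------------------------------------------
# numba kernel

@njit(cache=True)
def _heun_kernel(
    W, dsteps, x0_vec, ez, x0_ez, x0_revert, activate_ez,
    w, sigma, dt, I1, I2, gamma, tau0, tau1, tau2,
    settle_steps, max_steps,
    thr_on, thr_off,
    init_state, seed,
    store, stride,
    early_stop, cooldown, bound,
):  # pragma: no cover - exercised via the wrapper
    n = W.shape[0]
    total = settle_steps + max_steps
    L = int(dsteps.max()) + 2
    hist = np.empty((L, n))
    state = init_state.copy()
    for r in range(L):
        for j in range(n):
            hist[r, j] = state[j, 0]

    n_rec = total // stride + 1 if store else 1
    states = np.empty((n_rec, n, 6))
    for j in range(n):
        for v in range(6):
            states[0, j, v] = state[j, v]

    coupled = np.ones(n)
    in_seizure = np.zeros(n, np.bool_)
    onset = np.full(n, -1, np.int64)
    offset = np.full(n, -1, np.int64)
    uncouple = np.full(n, -1, np.int64)
    x0 = x0_vec.copy()

    np.random.seed(seed)
    sq = sigma * np.sqrt(dt)

    d1 = np.empty((n, 6))
    d2 = np.empty((n, 6))
    pred = np.empty((n, 6))
    xi = np.zeros(n)
    eta = np.zeros(n)

    last_event = settle_steps
    diverged_at = -1
    t_done = total

    for t in range(total):
        if activate_ez and t == settle_steps:
            x0[ez] = x0_ez

        # --- stage 1: drift at current state (delayed values from history)
        for i in range(n):
            x1 = state[i, 0]
            y1 = state[i, 1]
            z = state[i, 2]
            x2 = state[i, 3]
            y2 = state[i, 4]
            g = state[i, 5]
            coup = 0.0
            if w > 0.0 and coupled[i] > 0.0:
                acc = 0.0
                for j in range(n):
                    wij = W[i, j]
                    if wij != 0.0 and coupled[j] > 0.0:
                        ds = dsteps[i, j]
                        xj = hist[(t - ds) % L, j]
                        acc += wij * (xj - x1)
                coup = w * acc
            if x1 < 0.0:
                fone = x1 * x1 * (x1 - 3.0)
            else:
                fone = (x2 - 0.6 * (z - 4.0) ** 2) * x1
            ftwo = 0.0 if x2 < -0.25 else 6.0 * (x2 + 0.25)
            d1[i, 0] = y1 - fone - z + I1
            d1[i, 1] = (1.0 - 5.0 * x1 * x1 - y1) / tau1
            d1[i, 2] = (4.0 * (x1 - x0[i]) - z - coup) / tau0
            d1[i, 3] = -y2 + x2 - x2 ** 3 + I2 + 0.002 * g - 0.3 * (z - 3.5)
            d1[i, 4] = (-y2 + ftwo) / tau2
            d1[i, 5] = x1 - gamma * g

        if sigma > 0.0:
            for i in range(n):
                xi[i] = sq * np.random.standard_normal()
                eta[i] = sq * np.random.standard_normal()

        for i in range(n):
            for v in range(6):
                pred[i, v] = state[i, v] + dt * d1[i, v]
            pred[i, 3] += xi[i]
            pred[i, 4] += eta[i]

        # --- stage 2: drift at predictor (delayed values at t+1)
        for i in range(n):
            x1 = pred[i, 0]
            y1 = pred[i, 1]
            z = pred[i, 2]
            x2 = pred[i, 3]
            y2 = pred[i, 4]
            g = pred[i, 5]
            coup = 0.0
            if w > 0.0 and coupled[i] > 0.0:
                acc = 0.0
                for j in range(n):
                    wij = W[i, j]
                    if wij != 0.0 and coupled[j] > 0.0:
                        ds = dsteps[i, j]
                        if ds == 0:
                            xj = pred[j, 0]
                        else:
                            xj = hist[(t + 1 - ds) % L, j]
                        acc += wij * (xj - x1)
                coup = w * acc
            if x1 < 0.0:
                fone = x1 * x1 * (x1 - 3.0)
            else:
                fone = (x2 - 0.6 * (z - 4.0) ** 2) * x1
            ftwo = 0.0 if x2 < -0.25 else 6.0 * (x2 + 0.25)
            d2[i, 0] = y1 - fone - z + I1
            d2[i, 1] = (1.0 - 5.0 * x1 * x1 - y1) / tau1
            d2[i, 2] = (4.0 * (x1 - x0[i]) - z - coup) / tau0
            d2[i, 3] = -y2 + x2 - x2 ** 3 + I2 + 0.002 * g - 0.3 * (z - 3.5)
            d2[i, 4] = (-y2 + ftwo) / tau2
            d2[i, 5] = x1 - gamma * g

        ok = True
        for i in range(n):
            for v in range(6):
                val = state[i, v] + 0.5 * dt * (d1[i, v] + d2[i, v])
                state[i, v] = val
                if not (-bound < val < bound):
                    ok = False
            state[i, 3] += xi[i]
            state[i, 4] += eta[i]

        tn = t + 1
        for j in range(n):
            hist[tn % L, j] = state[j, 0]
        if store and tn % stride == 0:
            for j in range(n):
                for v in range(6):
                    states[tn // stride, j, v] = state[j, v]
        if not ok:
            diverged_at = tn
            t_done = tn
            break

        # --- online seizure detection with hysteresis + postictal uncoupling
        if tn > settle_steps:
            for i in range(n):
                g = state[i, 5]
                if not in_seizure[i]:
                    if g >= thr_on:
                        in_seizure[i] = True
                        if onset[i] < 0:
                            onset[i] = tn
                        last_event = tn
                else:
                    if g <= thr_off:
                        in_seizure[i] = False
                        if offset[i] < 0:
                            offset[i] = tn
                        if coupled[i] > 0.0:
                            coupled[i] = 0.0
                            uncouple[i] = tn
                        if i == ez:
                            x0[ez] = x0_revert
                        last_event = tn
            if early_stop and offset[ez] >= 0:
                any_ictal = False
                for i in range(n):
                    if in_seizure[i]:
                        any_ictal = True
                        break
                if not any_ictal and tn - last_event > cooldown:
                    t_done = tn
                    break

    return states, onset, offset, uncouple, t_done, diverged_at


# ---------------------------------------------------------------------------
# reference run and threshold calibration

@dataclass(frozen=True)
class ReferenceSeizure:
    """Calibration data from a noise-free isolated-EZ seizure."""

    threshold: float
    threshold_off: float
    x1_mean: float
    onset_step: int
    offset_step: int
    g_rest: float
    g_max: float
    dt: float


_REFERENCE_CACHE: dict[tuple, ReferenceSeizure] = {}


def reference_isolated_seizure(
    params: EpileptorParams,
    x0_surround: float = -2.2,
    dt: float = 0.05,
    max_steps: int = 600_000,
) -> ReferenceSeizure:
    """Simulate one deterministic seizure of an isolated EZ node.

    The node starts at the stable resting state of excitability
    ``x0_surround`` and is switched to ``x0 = -1.6`` at t = 0.  The run
    defines the onset threshold on g (halfway between resting g and the
    ictal plateau), the offset threshold (90% of that rise) and the mean
    of x1 over the first seizure — the constant drive used by the
    EZ-removed stability variant.
    """
    key = (params.I1, params.I2, params.gamma, params.tau0, params.tau1,
           params.tau2, float(x0_surround), float(dt))
    if key in _REFERENCE_CACHE:
        return _REFERENCE_CACHE[key]

    from .stability import single_node_stable_fixed_point

    init = single_node_stable_fixed_point(params, x0_surround, "full")
    states, *_ = _heun_kernel(
        np.zeros((1, 1)), np.zeros((1, 1), np.int64),
        np.array([X0_EZ]), 0, X0_EZ, X0_EZ, True,
        0.0, 0.0, dt,
        params.I1, params.I2, params.gamma, params.tau0, params.tau1, params.tau2,
        0, max_steps,
        np.inf, np.inf,
        init.reshape(1, 6).astype(float), 0,
        True, 1,
        False, 0, 1e4,
    )
    g = states[:, 0, 5]
    x1 = states[:, 0, 0]
    g_rest = float(g[0])
    g_max = float(g.max())
    if g_max - g_rest < 1.0:
        raise RuntimeError(
            f"no seizure detected in reference run (g rise {g_max - g_rest:.3g}); "
            f"increase max_steps"
        )
    thr = g_rest + 0.5 * (g_max - g_rest)
    thr_off = g_rest + 0.5 * HYSTERESIS_FRACTION * (g_max - g_rest)
    above = g >= thr
    onset = int(np.argmax(above))
    if not above[onset]:
        raise RuntimeError("reference run never crossed its own threshold")
    below_after = (g[onset:] <= thr_off)
    if not below_after.any():
        raise RuntimeError("reference seizure did not terminate; increase max_steps")
    offset = onset + int(np.argmax(below_after))
    ref = ReferenceSeizure(
        threshold=float(thr),
        threshold_off=float(thr_off),
        x1_mean=float(x1[onset:offset + 1].mean()),
        onset_step=onset,
        offset_step=offset,
        g_rest=g_rest,
        g_max=g_max,
        dt=dt,
    )
    _REFERENCE_CACHE[key] = ref
    return ref


def calibrate_threshold(
    params: EpileptorParams, x0_surround: float = -2.2, dt: float = 0.05
) -> tuple[float, float]:
    """(onset, offset) thresholds on g from the reference isolated seizure."""
    ref = reference_isolated_seizure(params, x0_surround, dt)
    return ref.threshold, ref.threshold_off


# ---------------------------------------------------------------------------
# protocol runner

def simulate_seizure_protocol(
    conn: Connectome,
    params: EpileptorParams,
    protocol: Protocol,
    initial_state: np.ndarray | None = None,
) -> Trajectory:
    """Run the settle -> activate-EZ -> postictal-uncoupling protocol.

    Identical seeds give bit-identical trajectories.  Raises on numerical
    divergence, naming the step.
    """
    if protocol.activate_ez and protocol.active_ez not in conn.ez_nodes:
        raise ValueError(
            f"active_ez={protocol.active_ez} not in ez_nodes {conn.ez_nodes}"
        )
    n = conn.n_nodes
    dsteps = np.rint(conn.delays / protocol.dt).astype(np.int64)

    if initial_state is None:
        from .stability import single_node_stable_fixed_point

        fp = single_node_stable_fixed_point(params, protocol.x0_surround, "full")
        initial_state = np.tile(fp, (n, 1))
    initial_state = np.ascontiguousarray(initial_state, dtype=float).reshape(n, 6)

    if protocol.threshold is not None:
        thr_on = float(protocol.threshold)
        # offset keeps the hysteresis rule around the run's own baseline g
        baseline = float(initial_state[:, 5].min())
        thr_off = baseline + HYSTERESIS_FRACTION * (thr_on - baseline)
    else:
        thr_on, thr_off = calibrate_threshold(
            params, protocol.x0_surround, protocol.dt
        )

    rest_g = initial_state[:, 5]
    if np.all(rest_g >= thr_on):
        raise ValueError(
            f"onset threshold {thr_on:.3g} is below resting g for every node; "
            "threshold calibration failed"
        )

    x0_vec = np.full(n, protocol.x0_surround)
    states, onset, offset, uncouple, t_done, diverged = _heun_kernel(
        np.ascontiguousarray(conn.weights), dsteps,
        x0_vec, int(protocol.active_ez), X0_EZ, protocol.x0_surround,
        protocol.activate_ez,
        params.w, params.sigma, protocol.dt,
        params.I1, params.I2, params.gamma, params.tau0, params.tau1, params.tau2,
        protocol.settle_steps, protocol.max_steps,
        thr_on, thr_off,
        initial_state, int(protocol.rng_seed),
        protocol.store_states, protocol.record_stride,
        protocol.early_stop, protocol.cooldown_steps, protocol.divergence_bound,
    )
    if diverged >= 0:
        raise FloatingPointError(
            f"integration diverged at step {diverged} "
            f"(|state| > {protocol.divergence_bound:g})"
        )
    if protocol.store_states:
        n_rec = t_done // protocol.record_stride + 1
        states = states[:n_rec]
        times = np.arange(n_rec) * protocol.dt * protocol.record_stride
    else:
        states = np.empty((0, n, 6))
        times = np.empty(0)
    return Trajectory(
        times=times,
        states=states,
        dt=protocol.dt,
        record_stride=protocol.record_stride,
        settle_steps=protocol.settle_steps,
        active_ez=protocol.active_ez,
        onset_steps=onset,
        offset_steps=offset,
        uncouple_steps=uncouple,
        threshold=thr_on,
        threshold_off=thr_off,
        n_steps=t_done,
    )


def _outcome_from_events(traj: Trajectory) -> SpreadOutcome:
    recruited = (traj.onset_steps >= 0).astype(int)
    onset_t = np.where(traj.onset_steps >= 0, traj.onset_steps * traj.dt, np.nan)
    offset_t = np.where(traj.offset_steps >= 0, traj.offset_steps * traj.dt, np.nan)
    return SpreadOutcome(
        recruited=recruited,
        onset_times=onset_t,
        offset_times=offset_t,
        active_ez=traj.active_ez,
    )


def run_protocol(
    conn: Connectome,
    params: EpileptorParams,
    protocol: Protocol,
    initial_state: np.ndarray | None = None,
) -> tuple[Trajectory, SpreadOutcome]:
    """Simulate and coarse-grain in one call (events from online detection)."""
    traj = simulate_seizure_protocol(conn, params, protocol, initial_state)
    return traj, _outcome_from_events(traj)


def extract_spread(
    traj: Trajectory,
    threshold: float | None = None,
    active_ez: int | None = None,
    hysteresis: float = HYSTERESIS_FRACTION,
) -> SpreadOutcome:
    """Recompute the spread outcome from a stored trajectory's g traces.

    Onset is the first upward crossing of the threshold after EZ
    activation; offset the subsequent downward crossing of
    ``baseline + hysteresis * (threshold - baseline)`` where baseline is
    each node's g at the activation step.
    """
    if traj.states.size == 0:
        raise ValueError("trajectory was run with store_states=False")
    thr = traj.threshold if threshold is None else float(threshold)
    ez = traj.active_ez if active_ez is None else int(active_ez)
    g = traj.states[:, :, 5]
    act_rec = traj.settle_steps // traj.record_stride
    n = g.shape[1]
    baseline = g[min(act_rec, g.shape[0] - 1)]
    if np.all(baseline >= thr):
        raise ValueError(
            f"threshold {thr:.3g} below resting g for all nodes at activation"
        )
    thr_off = baseline + hysteresis * (thr - baseline)
    onset_t = np.full(n, np.nan)
    offset_t = np.full(n, np.nan)
    recruited = np.zeros(n, dtype=int)
    step_t = traj.dt * traj.record_stride
    for i in range(n):
        gi = g[act_rec + 1:, i]
        above = gi >= thr
        if not above.any():
            continue
        k_on = int(np.argmax(above))
        recruited[i] = 1
        onset_t[i] = (act_rec + 1 + k_on) * step_t
        below = gi[k_on:] <= thr_off[i]
        if below.any():
            offset_t[i] = (act_rec + 1 + k_on + int(np.argmax(below))) * step_t
    return SpreadOutcome(
        recruited=recruited,
        onset_times=onset_t,
        offset_times=offset_t,
        active_ez=ez,
    )
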