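"""Grid sweeps, phase diagrams, near-criticality statistics and rank scoring.

A phase diagram tabulates, for every point of an (x0_surround, w) grid,
repeated stochastic runs of the seizure protocol and their coarse-grained
spread outcomes.  A cell is labelled no_seizure if no realization seized,
no_spread if the EZ seized but never recruited anyone, and spread
otherwise.  Cells whose spread size varies across realizations form the
fluctuation (near-criticality) mask; pooled spread sizes there are
characteristically bimodal (small/no spread vs full spread).

Rank scoring compares the stability module's predicted recruitment order
(descending ``|v_z,i|``) against the onset order observed in full-spread
realizations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .connectome import Connectome, graph_metrics
from .model_core import EpileptorParams
from .simulator import (
    PHASE_NO_SEIZURE,
    PHASE_NO_SPREAD,
    PHASE_SPREAD,
    Protocol,
    SpreadOutcome,
    run_protocol,
)
from .stability import StabilityReport

__all__ = [
    "PhaseDiagram",
    "RankEvaluation",
    "sweep_phase_diagram",
    "near_criticality_stats",
    "evaluate_rank_prediction",
    "onset_covariates",
]


@dataclass(frozen=True)
class PhaseDiagram:
    """Per-cell outcome statistics of an (x0, w) sweep.

    ``spread_sizes`` has shape (len(x0_grid), len(w_grid), n_realizations);
    a negative entry marks a diverged realization.  ``seeds`` records the
    per-realization RNG seeds so any run can be replayed exactly.
    """

    x0_grid: np.ndarray
    w_grid: np.ndarray
    spread_sizes: np.ndarray
    labels: np.ndarray                 # (nx, nw) of phase strings
    outcomes: dict[tuple[int, int], list[SpreadOutcome]]
    seeds: np.ndarray                  # (nx, nw, n_realizations)
    n_nodes: int
    active_ez: int
    sigma: float

    @property
    def mean_spread(self) -> np.ndarray:
        s = np.where(self.spread_sizes >= 0, self.spread_sizes, np.nan)
        return np.nanmean(s, axis=2)

    @property
    def std_spread(self) -> np.ndarray:
        s = np.where(self.spread_sizes >= 0, self.spread_sizes, np.nan)
        return np.nanstd(s, axis=2)

    def to_frame(self) -> pd.DataFrame:
        """Long-form per-cell summary (x0, w, mean, std, label)."""
        rows = []
        for a, x0 in enumerate(self.x0_grid):
            for b, w in enumerate(self.w_grid):
                rows.append(
                    {
                        "x0": x0,
                        "w": w,
                        "mean_spread": self.mean_spread[a, b],
                        "std_spread": self.std_spread[a, b],
                        "label": self.labels[a, b],
                    }
                )
        return pd.DataFrame(rows)


def _cell_label(outcomes: list[SpreadOutcome]) -> str:
    phases = {o.phase for o in outcomes}
    if phases == {PHASE_NO_SEIZURE}:
        return PHASE_NO_SEIZURE
    if PHASE_SPREAD in phases:
        return PHASE_SPREAD
    return PHASE_NO_SPREAD


def sweep_phase_diagram(
    conn: Connectome,
    params: EpileptorParams,
    active_ez: int,
    x0_grid,
    w_grid,
    sigma: float,
    n_realizations: int = 30,
    base_seed: int = 0,
    protocol: Protocol | None = None,
) -> PhaseDiagram:
    """Run the seizure protocol over an (x0, w) grid with repetitions.

    Seeds are ``base_seed + flat_cell_index * n_realizations + r`` and are
    stored in the result for exact replay.  A diverged realization flags
    its cell (spread size -1) and the sweep continues.
    """
    x0_grid = np.sort(np.asarray(x0_grid, dtype=float))
    w_grid = np.sort(np.asarray(w_grid, dtype=float))
    nx_, nw = len(x0_grid), len(w_grid)
    proto = protocol or Protocol(active_ez=active_ez)
    sizes = np.zeros((nx_, nw, n_realizations), dtype=int)
    seeds = np.zeros((nx_, nw, n_realizations), dtype=np.int64)
    labels = np.empty((nx_, nw), dtype=object)
    outcomes: dict[tuple[int, int], list[SpreadOutcome]] = {}
    for a, x0 in enumerate(x0_grid):
        for b, w in enumerate(w_grid):
            cell_idx = a * nw + b
            p = params.with_(w=float(w), sigma=float(sigma))
            cell: list[SpreadOutcome] = []
            for r in range(n_realizations):
                seed = base_seed + cell_idx * n_realizations + r
                seeds[a, b, r] = seed
                cell_proto = Protocol(
                    active_ez=active_ez,
                    x0_surround=float(x0),
                    dt=proto.dt,
                    settle_steps=proto.settle_steps,
                    max_steps=proto.max_steps,
                    rng_seed=seed,
                    threshold=proto.threshold,
                    store_states=False,
                    early_stop=proto.early_stop,
                    cooldown_steps=proto.cooldown_steps,
                    divergence_bound=proto.divergence_bound,
                )
                try:
                    _, out = run_protocol(conn, p, cell_proto)
                except FloatingPointError as err:
                    warnings.warn(
                        f"cell (x0={x0:.4g}, w={w:.4g}) realization {r}: {err}",
                        stacklevel=2,
                    )
                    sizes[a, b, r] = -1
                    continue
                sizes[a, b, r] = out.spread_size
                cell.append(out)
            outcomes[(a, b)] = cell
            labels[a, b] = _cell_label(cell) if cell else "diverged"
    return PhaseDiagram(
        x0_grid=x0_grid,
        w_grid=w_grid,
        spread_sizes=sizes,
        labels=labels,
        outcomes=outcomes,
        seeds=seeds,
        n_nodes=conn.n_nodes,
        active_ez=active_ez,
        sigma=float(sigma),
    )


def near_criticality_stats(
    diagram: PhaseDiagram, k_small: int | None = None, min_count: int = 1
) -> dict:
    """Fluctuation mask and pooled spread-size distribution near criticality.

    The mask marks cells whose spread size varies across realizations
    (std > 0, i.e. at least ``min_count`` realizations deviate from the
    cell majority).  Pooled sizes over masked cells are summarized by the
    fraction of probability mass in the two extreme bins
    (``size <= k_small`` vs ``size >= n - k_small``); ``k_small`` defaults
    to 10% of the network size, rounded up.
    """
    if diagram.spread_sizes.shape[2] < 2:
        raise ValueError("need >= 2 realizations per cell for fluctuation stats")
    n = diagram.n_nodes
    if k_small is None:
        k_small = int(np.ceil(0.1 * n))
    sizes = diagram.spread_sizes
    valid = sizes >= 0
    mask = np.zeros(sizes.shape[:2], dtype=bool)
    for a in range(sizes.shape[0]):
        for b in range(sizes.shape[1]):
            vals = sizes[a, b][valid[a, b]]
            if len(vals) < 2:
                continue
            counts = np.bincount(vals)
            n_deviant = len(vals) - counts.max()
            mask[a, b] = n_deviant >= min_count
    pooled = sizes[mask][valid[mask]] if mask.any() else np.empty(0, dtype=int)
    hist = np.bincount(pooled, minlength=n + 1) if pooled.size else np.zeros(n + 1, int)
    if pooled.size:
        lo = float((pooled <= k_small).mean())
        hi = float((pooled >= n - k_small).mean())
    else:
        lo = hi = 0.0
    return {
        "mask": mask,
        "pooled_sizes": pooled,
        "histogram": hist,
        "k_small": k_small,
        "frac_small": lo,
        "frac_full": hi,
        "frac_extreme": lo + hi,
    }


@dataclass(frozen=True)
class RankEvaluation:
    """Scores of eigenvector-based rank prediction against simulations."""

    true_ranks: np.ndarray         # (n_real, m) surround ranks by onset time
    predicted_ranks: np.ndarray    # (m,) from |v_z,i|
    abs_errors: np.ndarray         # (n_real, m)
    per_rank_mae: np.ndarray       # (m,) mean abs error at each true rank
    per_rank_band: np.ndarray      # (2, m) empirical 95% band
    mean_corrected_onsets: np.ndarray  # (n_real, m)
    surround_nodes: np.ndarray

    @property
    def mae(self) -> float:
        return float(self.abs_errors.mean())

    def spearman(self) -> float:
        """Mean Spearman correlation between predicted and true ranks."""
        rs = [
            scipy.stats.spearmanr(self.predicted_ranks, tr).statistic
            for tr in self.true_ranks
        ]
        return float(np.mean(rs))


def _onset_ranks(onsets: np.ndarray) -> np.ndarray:
    """Rank 1 = earliest onset; ties broken by node position (stable sort)."""
    order = np.argsort(onsets, kind="stable")
    ranks = np.empty(len(onsets), dtype=int)
    ranks[order] = np.arange(1, len(onsets) + 1)
    return ranks


def evaluate_rank_prediction(
    outcomes: list[SpreadOutcome], report: StabilityReport
) -> RankEvaluation:
    """Compare predicted recruitment ranks with observed onset ranks.

    Only full-spread realizations are scored (others are filtered with a
    warning): partial spreads leave some ranks undefined.
    """
    surround = report.surround_nodes
    full = []
    for o in outcomes:
        if o.recruited.sum() == len(o.recruited):
            full.append(o)
    if len(full) < len(outcomes):
        warnings.warn(
            f"filtered {len(outcomes) - len(full)} partial-spread realizations",
            stacklevel=2,
        )
    if not full:
        raise ValueError("no full-spread realizations to evaluate")
    pred = report.predicted_ranks
    true_ranks = np.array([_onset_ranks(o.onset_times[surround]) for o in full])
    onsets = np.array([o.onset_times[surround] for o in full])
    mco = onsets - onsets.mean(axis=1, keepdims=True)
    errs = np.abs(true_ranks - pred[None, :])
    m = len(surround)
    per_rank_mae = np.zeros(m)
    band = np.zeros((2, m))
    for rank in range(1, m + 1):
        vals = errs[true_ranks == rank]
        per_rank_mae[rank - 1] = vals.mean() if vals.size else np.nan
        if vals.size:
            band[:, rank - 1] = np.percentile(vals, [2.5, 97.5])
    return RankEvaluation(
        true_ranks=true_ranks,
        predicted_ranks=pred,
        abs_errors=errs,
        per_rank_mae=per_rank_mae,
        per_rank_band=band,
        mean_corrected_onsets=mco,
        surround_nodes=surround,
    )


def onset_covariates(
    outcomes: list[SpreadOutcome],
    conn: Connectome,
    active_ez: int,
    report: StabilityReport | None = None,
) -> pd.DataFrame:
    """Associations between onset times, EZ weights, path lengths and |v_z|.

    Onset times are mean-corrected per realization (their per-run mean
    subtracted) before pooling.  Returns Spearman rank correlations and,
    where both covariates are positive, log-log least-squares slopes with
    95% confidence intervals.  Zero-variance covariates yield NaN.
    """
    surround = np.array([i for i in range(conn.n_nodes) if i != active_ez])
    full = [o for o in outcomes if o.recruited.sum() == len(o.recruited)]
    if not full:
        raise ValueError("no full-spread realizations")
    onsets = np.array([o.onset_times[surround] for o in full])
    mco = (onsets - onsets.mean(axis=1, keepdims=True)).ravel()
    w_ez = np.tile(conn.weights[surround, active_ez], len(full))
    metrics = graph_metrics(conn, active_ez)
    spl = np.tile(
        metrics["shortest_path_length_to_ez"].to_numpy()[surround], len(full)
    )
    rows = []

    def add(name, x, y, loglog=False):
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"pair": name, "spearman": np.nan, "slope": np.nan,
                         "slope_lo": np.nan, "slope_hi": np.nan})
            return
        rho = scipy.stats.spearmanr(x, y).statistic
        slope = lo = hi = np.nan
        if loglog and (np.asarray(x) > 0).all() and (np.asarray(y) > 0).all():
            res = scipy.stats.linregress(np.log(x), np.log(y))
            slope = res.slope
            # 95% CI from the slope standard error
            tcrit = scipy.stats.t.ppf(0.975, len(x) - 2)
            lo, hi = slope - tcrit * res.stderr, slope + tcrit * res.stderr
        rows.append({"pair": name, "spearman": float(rho), "slope": slope,
                     "slope_lo": lo, "slope_hi": hi})

    add("onset_vs_w_ez", w_ez, mco)
    add("onset_vs_shortest_path", spl, mco)
    if report is not None:
        vz = np.tile(report.v_z, len(full))
        add("vz_vs_w_ez", w_ez, vz, loglog=True)
        add("onset_vs_vz", vz, mco)
    return pd.DataFrame(rows).set_index("pair")
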