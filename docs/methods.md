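# Methods

## The model

Each brain area (network node) is a six-variable Epileptor
`(x1, y1, z, x2, y2, g)`:

```
x1' = y1 - f1(x1, x2, z) - z + I1
y1' = (1 - 5 x1^2 - y1) / tau1
z'  = (4 (x1 - x0) - z - w * sum_j W_ij [x1_j(t - tau_ij) - x1_i]) / tau0
x2' = -y2 + x2 - x2^3 + I2 + 0.002 g - 0.3 (z - 3.5) + xi(t)
y2' = (-y2 + f2(x2)) / tau2 + eta(t)
g'  = x1 - gamma * g
```

with `f1 = x1^3 - 3 x1^2` for `x1 < 0` and `(x2 - 0.6 (z - 4)^2) x1` for
`x1 >= 0` (the `>=` branch applies at the switch point exactly), and
`f2 = 0` for `x2 < -0.25`, `6 (x2 + 0.25)` otherwise.  Constants:
`I1 = 3.1`, `I2 = 0.45`, `gamma = 0.01`, `tau0 = 6667`, `tau1 = 1`,
`tau2 = 10`.  The time-scale separation `tau0 >> tau2 >> tau1` makes z the
slow permittivity variable that carries nodes in and out of seizure; g is
integrated as an ODE (a leaky integral of x1) and serves as the smooth
observable used for seizure detection.  A two-variable reduction per node,

```
x' = -x^3 - 2 x^2 + 1 - z + I1
z' = (4 (x - x0) - z - w * sum_j W_ij [x_j - x_i]) / tau0
```

keeps the same onset bifurcation and is supported in all stability
operations.

The excitability `x0` controls each node's distance to seizure onset: an
isolated node seizes spontaneously above the critical value
`x0c ~ -2.061` (recomputed by bisection, see below).  The active
epileptogenic zone (EZ) is set to `x0 = -1.6`; surround nodes stay in the
non-epileptic band `[-2.3, -2.09]`.  Nodes interact diffusively through z
with symmetric weights `W_ij` in `[0, 1]`, global gain `w >= 0` and
delays `tau_ij = length_ij / speed` (speed 60 mm per time unit; one unit
is 0.02 s, so 3000 mm/s and at most 0.067 s for 200 mm tracts).

## Connectome handling

Raw tractography-style weight matrices are truncated at the 95th
percentile of all `n^2` entries (zero diagonal included, linear
interpolation) and divided by that threshold.  The transform is
deliberately *not* exactly idempotent: after clipping, the new 95th
percentile interpolates between the largest unclipped entry and 1, so a
second pass rescales by a factor within one inter-entry gap of 1 (exact
idempotence is impossible under interpolated percentiles; the property
tests assert the sharp bound instead).  Asymmetric inputs are rejected
unless explicit transpose-averaging is requested; the diagonal is forced
to zero on load because the diffusive coupling has no self-term and the
stability row sums must not include one.

Shortest paths to the EZ use edge cost `1/W_ij` by default (stronger
links are "closer"); `-log W` and unit hops are selectable since no
canonical weight-to-distance transform exists for these matrices.
Betweenness (unnormalized, same costs), weighted Onnela clustering and
weighted eigenvector centrality complete the per-node metric table.

## Simulation protocol

Integration uses the stochastic Heun predictor–corrector with step
`dt = 0.05` and i.i.d. Gaussian Wiener increments of variance
`sigma^2 * dt` applied to the x2 and y2 equations only; the same
increment is added at the predictor and corrector stage.  Noise is
additive, so no Ito/Stratonovich ambiguity arises.  Delayed neighbour
values `x1_j(t - tau_ij)` come from a ring buffer with delays rounded to
the nearest step; zero-delay pairs read the current (predictor) state.
A run starts with every node at the stable resting state of an isolated
non-epileptic node, settles for 20,000 noisy steps, then switches the
active EZ to `x0 = -1.6`.  After a seizure terminates in any node, that
node is uncoupled from the network for the rest of the run (postictal
refractoriness); the EZ additionally reverts to the surround
excitability.  One seizure per run is analysed, so "uncoupled for the
remainder" implements the unspecified postictal duration.  Runs stop
early once the EZ seizure has ended, no node is ictal and 20,000 steps
pass without events; runs are capped at 200,000 post-activation steps by
default (150,000 in the sweep tests — ample, since onset latencies are a
few thousand time units).  Identical seeds give bit-identical
trajectories.

Seizure onset/offset per node is detected on g with hysteresis.  The
onset threshold is auto-calibrated from one deterministic reference run
of an isolated EZ node: baseline g plus half the baseline-to-ictal-peak
rise; the offset threshold sits at 90% of that rise above baseline, which
suppresses chatter when noisy traces graze the threshold.  The same
reference run supplies `x1_bar`, the mean of x1 over the first seizure,
used as the constant EZ drive in the stability analysis (the isolated-node
convention; an in-network average would differ only through coupling
feedback and is configurable via the `x1_ez_mean` argument).

The integration kernel is JIT-compiled (numba); the drift it implements
is tested for exact agreement against the reference numpy drift
functions, and its noise statistics are verified against the stationary
Lyapunov covariance of the linearized node (with a shortened `tau0` so
the slow mode mixes inside the simulated window, and small sigma so the
linearization holds).

## Stability analysis

All stability computations set `tau_ij = 0`: coupling acts through the
slow variable z, so delays do not move equilibria and have little effect
on their bifurcations (the simulator property tests confirm phase labels
match with and without delays).

Fixed points exploit the structure of the resting branch.  For `x1 < 0`
the x1/z equilibrium conditions close on themselves; eliminating z gives
a diagonally dominant system in x1 with a unique solution, found by a
damped Newton solve.  Each node's `(x2, y2)` is then placed on the
resting piece of its x2 nullcline — the most negative real root with
`x2 <= -1/sqrt(3)` of `x2 - x2^3 + I2 + 0.002 g - 0.3 (z - 3.5) = 0` —
and the assembled state is polished by a root solve of the full drift
(each equation rescaled by its time constant for conditioning; residual
below 1e-9 in the unscaled drift is enforced).  When the resting x2 root
has vanished through its fold, or the x1 balance crosses into the
depolarized branch, no resting equilibrium exists: that variant is
reported as maximally unstable (`lambda = +inf`), which is precisely the
seizure-onset condition.  Tracking the resting branch explicitly matters:
generic root searches happily converge to the coexisting mid-branch
(always-unstable) equilibria and would wrongly label the entire diagram
unstable.

The single-node search seeds a nullcline-consistent grid on the
hyperpolarized branch, where the model's three physiological fixed points
live (one stable, two unstable at non-epileptic x0).  An exhaustive
two-branch grid also finds a fourth, always-unstable equilibrium on the
depolarized branch (`x1 >= 0`); it plays no role in the resting-state
analysis and is excluded from the default seeds, but a wider `x1_starts`
grid reaches it.  The critical excitability is found by bisecting x0 on
`[-2.3, -1.6]` (tolerance 1e-4) for the existence of a stable fixed
point; the full model gives -2.0614, and the reduced model admits a
closed form via the vanishing Jacobian trace that the tests use as an
oracle.

Two Jacobians are assembled analytically in variable-major block form
(each block an m-by-m matrix over nodes) and certified against central
finite differences of the drift to 1e-6:

* **with-EZ**: the full 6n-by-6n linearization at the network fixed
  point with the EZ at `x0 = -1.6`.  Its leading eigenvalue real part
  `lambda_R` decides seizure initiation.
* **EZ-removed**: the 6(n-1)-square linearization of the surround
  network in which the EZ is frozen at the constant `x1_bar`; the frozen
  term still depends on each neighbour's own x1, so the z-row diagonal
  keeps the full row sum including the weight to the EZ.  Its leading
  eigenvalue `lambda_tilde_R` decides spread.

Note that differentiating the y2 equation gives `+f2'(x2)/tau2` for the
`(y2, x2)` block; the finite-difference oracle adjudicates this sign.
Phase rule: `lambda_R < 0` means no seizure (this dominates regardless of
the surround variant); `lambda_R > 0` with `lambda_tilde_R < 0` means a
localized seizure (no spread); both positive means spread.  The numeric
zero threshold is 1e-9 because near the no-seizure boundary the relevant
eigenvalues live on the `1/tau0` scale.  When spread is predicted, the
moduli of the leading with-EZ eigenvector's z-components, `|v_z,i|`
(eigenvector normalized to unit 2-norm), rank the surround nodes: larger
magnitude, earlier recruitment; exact ties break by ascending node index.

## Sweeps and statistics

Phase diagrams run the full protocol over an `(x0_surround, w)` grid
with repeated stochastic realizations (30 by default; seeds
`base_seed + cell_index * reps + r` are stored for exact replay).  A cell
is labelled `no_seizure` if no realization seized, `no_spread` if the EZ
seized but never recruited anyone, `spread` otherwise; mean and standard
deviation of spread size are stored so diagrams can also be rendered by
size.  The fluctuation (near-criticality) mask marks cells whose spread
size varies across realizations; a configurable minimum deviant count is
available.  Pooled spread sizes over masked cells are summarized by the
fraction of mass within `k_small` of the extremes (`k_small` defaults to
10% of n, rounded up).

Rank evaluation scores `|v_z,i|` predictions against onset order in
full-spread realizations only (partial spreads leave ranks undefined and
are filtered with a warning): absolute per-node rank errors, per-true-rank
mean error with empirical 95% bands, and per-realization mean-corrected
onset times (each run's mean onset subtracted, removing the global shift
that varies with `(x0, w)` and noise realization).

## Synthetic connectomes

Patient DTI matrices are not available, so the generator emulates their
statistics: nodes placed uniformly in a 150 mm box, tract lengths equal
to Euclidean distances capped at 200 mm (delay structure therefore
correlates with topology), edges on a random fraction (density, default
0.3) of node pairs, log-normal weights (log-mean -1, log-sd 1, matching
the heavy tail of streamline counts) passed through the same
95th-percentile normalization as real matrices.  Everything is
reproducible from the spec seed.  For matrices sparser than 5% the
all-entry percentile is zero and the generator falls back to the
percentile over nonzero entries.  What the generator does *not* emulate:
community/hemispheric block structure, degree–distance correlations
beyond geometry, and any specific patient's degree sequence — so passing
tests demonstrate the method's internal consistency, not clinical
fidelity.

Deterministic fixtures cover targeted topologies: a two-node pair, a
chain with the EZ at one end, and a "star hub" whose EZ is the hub with
geometrically tapering leaf weights (known ground-truth recruitment
order).  A two-node network cannot express the no-seizure phase inside
the non-epileptic surround band: in the strong-coupling limit the pair
locks at the mean excitability `(-1.6 + x0_s)/2 > x0c`, which is still
epileptogenic; suppressing the EZ needs enough surround nodes to pull the
locked mean below `x0c` (three at `x0_s = -2.3`).  The 10-node test
network shows all three phases.

## Problem sizes and scaled-down checks

The concordance study uses a 10-node synthetic network (density 0.5,
seed 0), a 10x10 grid with `x0` linear in `[-2.3, -2.09]` and `w`
log-spaced in `[0.2, 20]` (chosen to straddle both transition curves
found by the stability scan), 10 realizations per cell at `sigma = 0.05`,
and 150,000 post-activation steps.  Under these conditions the
two-Jacobian prediction matches the empirical cell label on ~98% of
cells outside the fluctuation mask, and all three phases appear.

One scaled-down limitation is documented rather than hidden: on 10 nodes
the near-criticality spread-size distribution is not bimodal in the
strict extreme-bin sense.  This network's EZ has one dominant neighbour,
so spread grows through a stable intermediate cluster (sizes 3–4) before
jumping to full spread — the same strongly-connected-subset phenomenon
that produces split fluctuation regions in larger networks — and the
fluctuating cells concentrate mass at that cluster size rather than at
`<= k_small`.  The two-mode structure with a gap (no mass at sizes 5–8)
is present, but the extreme-bin mass fraction stays near 1/3; recovering
the sharp small-vs-full bimodality appears to require the larger (84- and
162-area) parcellations.

## Known limitations

* Stability analysis linearizes at the pre-ictal equilibrium; it cannot
  see finite-amplitude effects, so it tends to overestimate the spread
  region near the no-spread boundary.
* The g-threshold, hysteresis fraction and postictal rule are explicit
  design choices (no canonical values exist); all are overridable.
* Delay rounding is to the nearest integer step; sub-step delay
  interpolation is not implemented.
* Sweeps are sequential; the per-cell contract (independent seeds,
  deterministic merge order) makes external parallelization safe but
  none is built in.
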