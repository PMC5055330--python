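# Methods

## Model and state

The simulator evolves a complete signed graph on `N ≥ 3` agents together
with an `N × F` opinion matrix, `x_{i,f} ∈ [0, 1]`.  Signs are stored as a
symmetric `±1` int8 matrix with zero diagonal; completeness and symmetry are
enforced at construction and preserved by every flip.  The state caches the
number of unbalanced triads; flipping one pair toggles the balance of
exactly the `N − 2` triads through it, so the cache is maintained in `O(N)`
per flip (the update is `(N−2) − 2u`, `u` the currently unbalanced triads
through the pair).  The full count used at initialization comes from the
closed form `Σ_triads s_ij s_ik s_jk = trace(S³)/6`.

Balance of the whole graph is decided in `O(N²)`: the positive subgraph
must have at most two connected components and signs must equal the
same-component indicator off the diagonal.  Tests verify this against
exhaustive triad enumeration.  Clique extraction returns the positive
components of a balanced graph (the component of agent 0 first).

## Dynamics

One time step revises one triad drawn uniformly from all `N(N−1)(N−2)/6`
triads (balanced triads: no-op).  Unbalanced triads resolve by:

* **preferential** — `(−−−)`: the pair with the smallest opinion distance
  becomes friends; `(−++)`: with probability `p` the negative link turns
  positive, otherwise the positive link with the largest opinion distance
  breaks.  Exact distance ties are broken uniformly at random from the
  run's RNG stream.
* **random** (LTD) — the legal candidate link is uniform.
* **constrained** (CTD) — the LTD candidate is applied only if the global
  unbalanced count does not increase; rejections are logged.  A run is
  declared *jammed* after 50 consecutive rounds without an admissible flip
  while unbalanced triads remain.

Opinion revisions are asynchronous: every `M` triad steps (deterministic
counter) one uniformly chosen agent replaces its opinion, issue by issue,
with the mean over itself and all friends within confidence `ε` under the
configured metric.  `M = max(1, round((N−1)(N−2)/6))`; `(N−1)(N−2)` is
always even, so the rounding never sees an exact half.  An optional
stochastic schedule instead triggers an opinion update after each triad
step with probability `6/((N−1)(N−2))`, scaled by `opinion_rate` for
schedule-robustness experiments (e.g. doubling the update speed).

A *round* is `N·M` steps.  Runs terminate **absorbed** when the network is
balanced and the opinions are at a fixed point; balance alone never ends a
run.  Because balance is absorbing for the network (no unbalanced triad can
ever reappear), the implementation switches after balance to pure opinion
relaxation: rounds of `N` i.i.d. uniform single-agent revisions.  The
fixed point is detected by the *synchronous residual* — the largest change
any single revision would produce, computed without mutating the state —
falling below `tol_fixedpoint = 1e−10`.  The residual is zero exactly at
the fixed points of the asynchronous dynamics, and unlike a "max change
over one sweep" probe it does not perturb the i.i.d. schedule.  The
scheduler choice is not cosmetic: replacing i.i.d. picks by random
permutation sweeps measurably shifts the pure-BC consensus threshold at
`N = 40` (to ≈ 0.35 instead of ≈ 0.5), so the i.i.d. protocol is used
throughout.

After absorption, opinions within `tol_cluster = 1e−6` (single-linkage, run
metric) are snapped to their cluster mean for reporting; asynchronous
averaging only reaches equality asymptotically, and the tolerance fixes the
`N_op` count against that.

## Numerical and engineering choices

* Two engines share one semantics: compiled numba kernels (default) and a
  pure-Python reference used by small-N contract tests.  Each is
  bit-reproducible from `Params.seed` (a SeedSequence derives separate
  streams for initialization/bookkeeping and for the kernels); the engines
  consume randomness differently and therefore agree in law, not bitwise.
* Ensemble seeds derive as `base_seed + cell_index·runs + run_index`
  (mod 2³¹), making every sweep a pure function of its spec.
* `rho0` is a per-link independent probability, not an exact quota.
* Distances for flip decisions are recomputed from current opinions at
  every revision (they are time-dependent); nothing is cached across
  opinion updates.
* `p = 0.5` is rejected only in the p-threshold grid (no guaranteed
  absorbing class); `Params` accepts any `p ∈ (0,1)` exclusive.
* Hyperplane separability of two point sets is decided exactly by linear
  feasibility (`w·a − b ≥ 1` on one set, `≤ −1` on the other) with
  `scipy.optimize.linprog`; a degenerate empty side is separable by
  convention and flagged.  The alignment score is the leading-eigenvalue
  fraction of the population covariance of a cluster's points (1 ⇔
  collinear, 1/F ⇔ isotropic; undefined when all points coincide).
* `D⁺`/`D⁻` average opinion distance over unordered positive/negative
  links; an empty link class yields NaN (undefined), never 0.  For `F > 1`
  the run's configured metric enters the sums.

## Metastability and caps

For `p < 1/2` the coupled dynamics usually reaches the bipolar state in a
few rounds, but two related mechanisms can park a run for times beyond any
practical cap:

1. **Structural metastability.**  Configurations with three or more
   mutually hostile cliques ordered by opinion are quasi-stable: the
   `(−−−)` cross-triads keep befriending their closest pair, and the
   resulting `(−++)` triads keep breaking exactly that new link, so escape
   requires a rare sequence of `p`-branch acceptances.  The frozen-opinion
   case `ε = 0` is the extreme: balance times grow roughly exponentially
   with `N` and a large fraction of `N = 40` runs outlive any desk-scale
   cap.
2. **Numerical opinion collapse.**  Once a forming cluster's opinions
   become bit-identical doubles (sub-ulp differences vanish in the mean),
   all its pairwise distances tie exactly and the preferential rule
   degenerates to a uniform random flip inside the cluster.  A quenched
   random tie-break priority (equivalent to an infinitesimal generic
   perturbation) was evaluated and does **not** change absorption rates —
   the waiting times are dominated by mechanism 1 — so the plain uniform
   tie-break is kept.

Consequently every experiment runs with an explicit `max_rounds` cap, capped
runs are recorded with termination `"max_rounds"`, and all ensemble
statistics (medians of balance times, mean `N_op`, `D⁻`, clique statistics)
are computed over absorbed runs with the absorbed fraction reported
alongside.  Threshold scans for the coupled model qualify a grid cell on
its absorbed runs.

## Problem sizes used by the test suite

The acceptance-style tests run at the sizes the quantities were defined at
where that is desk-scale (`N = 40` for thresholds and separation, `N = 30`
for the p-transition, `N = 20` for the two-issue checks) and scale down
only the clique-size-invariance ensemble (to `N = 60` with 200 runs per
`ρ₀` cell) and the LTD comparison, where the random-flip baseline is capped
at 150 rounds and capped runs are scored at the cap — a lower bound that
can only make the comparison harder for the coupled model.  The pure-BC
consensus threshold test takes the largest of three independent 8-run
scans, since a single "all 8 runs reach consensus" scan is an order
statistic with a long left tail.

## What the generator emulates — and what it does not

Initial conditions are i.i.d.: link signs positive with probability `ρ₀`
(default 1/2) and opinions uniform on `[0,1]^F`.  This matches the study
conditions the dynamics was characterized under, and the built-in
experiments reproduce the expected behavior: consensus thresholds near 0.5
(pure BC) and 0.25 (coupled, per clique), inter-clique separation `D⁻ ≈
1/2` with clique means near 1/4 and 3/4, a bipolar/all-friends transition
at `p ≈ 1/2`, perfect 1-D segregation and 2-D hyperplane separability of
absorbed states, cluster-level opinion alignment, and `ρ₀`-invariant
clique-size differences.  None of this says anything about real social
networks: the graph is complete and unweighted, agents are homogeneous in
`ε` and update rates, opinions live in a bounded box with purely
attractive influence (no repulsion from enemies), and signs carry no
strength.  Results at other `N` follow the trends above but absolute
balance times do not extrapolate (they grow super-polynomially for small
`ε`).

## Known limitations

* Incomplete or weighted networks and opinion repulsion are out of scope.
* Medians/means are undefined (NaN, flagged) when fewer than half of a
  cell's runs absorb.
* `N_op` near cluster-merge boundaries can shift by ±1 with the clustering
  tolerance; the default `1e−6` is applied after fixed-point snapping.
* Per-round `N_op` is not monotone after balance (asynchronous merging
  transiently splits clusters at round boundaries); only the final count
  is guaranteed not to exceed the count at balance.
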