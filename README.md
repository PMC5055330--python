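# bcpf — coupled structural balance and bounded-confidence opinion dynamics

`bcpf` is a seedable discrete-time simulator for the joint evolution of
social ties and opinions on a complete signed network.  It is aimed at
researchers in computational social science and sociophysics who study how
homophily-driven rewiring of friendships/enmities interacts with
confirmation-biased opinion formation — polarization into hostile cliques,
segregation of opinions between them, and fragmentation of opinions within
them.

## The model

`N` agents form a complete graph.  Each link carries a sign
`s_ij ∈ {−1, +1}` (enmity / friendship) and each agent an opinion vector
`x_i ∈ [0, 1]^F` over `F` issues.  A triad `ijk` is *balanced* iff
`s_ij · s_ik · s_jk = +1`; a complete signed graph is balanced iff it is
all-friends or splits into two mutually hostile cliques (the *bipolar*
state).

**Tie dynamics (preferential flip).**  Each time step one uniformly chosen
triad is revised.  Balanced triads are untouched.  An all-enemies `(−−−)`
triad befriends the pair with the *smallest* opinion distance `Δ_ij`.  A
`(−++)` triad (two friends of a common enemy) resolves its negative link to
positive with probability `p`; otherwise (probability `1 − p`) it breaks the
positive link with the *largest* `Δ_ij`.  Setting the flipped link uniformly
at random instead recovers local triad dynamics (LTD); additionally
accepting a flip only when the global unbalanced-triad count does not
increase recovers constrained triad dynamics (CTD).

**Opinion dynamics (bounded confidence, friends only).**  Every
`M = round((N−1)(N−2)/6)` triad steps one uniformly chosen agent `i`
averages, issue by issue, the opinions of its confidence set

    x_i ← (1/η_i) Σ_{j ∈ ν_i} x_j,
    ν_i = {i} ∪ { j : s_ij = +1 and Δ_ij ≤ ε },

so enemies never influence an agent.  For `F > 1` the distance is
`Δ_ij = max_f |x_i,f − x_j,f|` (Chebyshev; Euclidean available).  A *round*
is `N·M` steps: on average every triad and every opinion is revised once per
round.  A run ends when the network is balanced **and** opinions are at a
fixed point (synchronous residual below `1e−10`); balance is absorbing for
the network, so ties freeze first and opinions then relax within the frozen
cliques.

For `p < 1/2` the dynamics settles into two hostile cliques whose opinions
segregate (a "left" and a "right" clique); for `p > 1/2` it reaches the
all-friends state.  The confidence level `ε` controls how many distinct
opinions survive inside each clique.

## Worked example

One realization at `N = 40`, `p = 0.1`, `ε = 0.2`:

```bash
bcpf run --agents 40 --p 0.1 --epsilon 0.2 --seed 7 --max-rounds 300
```

prints (abridged):

```json
{
  "termination": "absorbed",
  "T_balance_steps": 34284,
  "T_balance_rounds": 3.47,
  "T_end_steps": 326040,
  "clique_sizes": [25, 15],
  "N_op": 2,
  "D_plus": 0.0,
  "D_minus": 0.4595
}
```

The network reached social balance after ~3.5 rounds (34 284 triad
revisions), splitting into hostile cliques of 25 and 15 agents.  Opinions
then converged to one value per clique (`N_op = 2`, intra-clique diversity
`D⁺ = 0`), with the two clique opinions separated by `D⁻ ≈ 0.46` — the
polarized outcome typical of `p < 1/2` and `ε ≳ 0.25`-level confidence.
Across many seeds `D⁻` averages ≈ 0.5, with clique means near 0.25 and 0.75.

The same library surface is available in Python:

```python
from bcpf import Params, run

res = run(Params(n_agents=40, p=0.1, epsilon=0.2, seed=7, max_rounds=300))
res.series           # per-round DataFrame: F_unbal, D_plus, D_minus, N_op
res.cliques          # the two friendly cliques
res.clustering       # opinion clusters and centroids
```

Other entry points: `bcpf baseline` (pure bounded confidence on a frozen
all-friends network), `bcpf sweep --grid epsilon=0:1:0.05 --runs 8`
(ensembles with tidy CSV summaries), and `bcpf thresholds --which bc|bcpf|p`
(critical-value estimators).  Initial conditions can be supplied as plain
CSV (`--network` with header `i,j,sign`; `--opinions` with header
`agent,x_1,...,x_F`); all agent indices are 0-based.  A JSON config file
whose keys mirror the `Params` fields (`n_agents`, `n_issues`, `p`,
`epsilon`, `rho0`, `metric`, `flip_rule`, `opinion_update_period`,
`opinion_rate`, `stochastic_schedule`, `max_rounds`, `seed`,
`tol_fixedpoint`, `tol_cluster`) can be passed with `--config`; explicit
flags override it.

Caveat: at small `ε` a fraction of runs parks in metastable multi-clique
configurations whose escape times exceed any practical cap; such runs end
with termination `"max_rounds"` and are reported (and excluded from
absorbed-state aggregates) by the ensemble tools.  See
`docs/methods.md`.

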