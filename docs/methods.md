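# Methods

This note documents the models implemented by `commonpool`, the choices
made where the design was genuinely open, and what the synthetic test
conditions do and do not show.

## The game model

The environment is an iterated trust game over a regenerating common
pool. Static parameters (`GameConfig`): player count `p = 4`, carrying
capacity `R0 = 200` resource units, growth factor `r = 0.4`, and a
termination rule — either a fixed horizon `T = 40` rounds or a
geometric rule (minimum 25 rounds, then a 0.2 per-round ending
probability, giving mean length `25 + 0.8/0.2 = 29`). Each round the
mechanism splits the pool into offers plus a retained amount; players
contribute part of their offer back; contributions grow by `(1 + r)`;
the pool is capped at `R0` and absorbs at zero.

Conventions:

- **Depletion does not truncate an episode by default.** Metrics are
  defined per trial over the full horizon, so a collapsed game plays
  out its remaining rounds with zero offers. A `truncate_on_depletion`
  flag ends the episode once the pool falls below the offer-unit
  threshold instead.
- **Sub-unit offers.** An offer below 1 unit cannot meaningfully be
  reciprocated (the human-facing version of this game increments
  contributions in whole units), so the receiving player keeps it all
  and contributes 0. This rule is enforced in both continuous and
  integer-contribution modes. The same 1-unit threshold defines
  depletion, active players, and exclusions in the analysis module.
- **Geometric termination** counts post-minimum survival draws with
  survival probability `1 − end_prob`; the draw happens once, up
  front, from the episode seed.
- Rounds are 0-indexed internally; logs expose a 1-based `trial` for
  reporting ("trial 40" is the last round of the standard game).
- The pool cap is applied once, after surplus accounting; no
  intermediate rounding is performed.

The sustainability constant: if every player keeps fraction `f` of
every offer, replenishment balances draw-down exactly when
`(1 + r)(1 − f) = 1`, i.e. `f = r/(1+r) = 2/7 ≈ 28.6 %` at `r = 0.4`.
The acceptance script verifies this both analytically and with a
1,000-round simulation.

## Hand-coded mechanisms

The weighted family allocates
`e_i = w·R/p + (1−w)·R·c_{i,prev}/Σ_j c_{j,prev}`, with an equal split
on the opening round. Choices:

- **Zero contributions last round** make the proportional term allocate
  0 to everyone (the group analogue of the poverty trap: a defector is
  excluded, and a fully defecting group excludes itself). The
  unallocated remainder stays in the pool.
- `residual_fraction` (0–0.4 of the pool withheld before applying the
  formula) defaults to 0: full allocation is the high-performing
  regime and the one all evaluation runs use.
- The interpolating mechanism sets `w = (R/R0)^k`. Its calibration grid
  is log-spaced, `k = exp(g)` for `g ∈ {−5, −4.9, …, 5}` (101 points);
  a natural-log grid contains values near the high-exponent regime
  (`e^3.1 ≈ 22`) where the mechanism is near-proportional unless the
  pool is almost full. Calibration ties break toward the larger
  exponent. The calibration routine reports the best exponent exactly
  as found on its grid.
- The random baseline draws five Dirichlet(1) proportions per round:
  four offers plus the retained share.

## Player archetypes and synthetic fixtures

Scripted archetypes express behaviour as a reciprocation *fraction* of
the received offer; Gaussian noise (when enabled) is applied to the
fraction and truncated to [0, 1], so contract bounds hold by
construction.

- *Sustainer*: fraction `1/(1+r)`, optionally noisy, optionally lapsing
  to 0 for single rounds with probability `lapse_prob`.
- *Free rider*: fixed fraction, default 0.
- *Conditional cooperator*: matches the mean observed fraction of the
  other players on the previous round (computed from remembered offers,
  so the policy is stateful); starts at the sustainable target.
- *Grim trigger*: sustainer until any other player's observed fraction
  drops below 0.1, then 0 forever. This archetype exists to give
  imitation learners a genuinely history-dependent behaviour: the
  trigger depends on *past offers* (to turn past contributions into
  fractions) and persists indefinitely, neither of which is visible in
  a single-round observation.

Default fixture conditions used by the tests and the acceptance
script: noisy sustainers use `noise_sd = 0.05`; the memory-necessity
fixture mixes grim players, lapsing sustainers (`lapse_prob = 0.08`,
`noise_sd = 0.05`) and free riders; the mechanism-training population
mixes sustainers, free riders and conditional cooperators with equal
weight. Fixture games sample a mechanism per game (weighted baselines
draw `w ~ Uniform[0,1]`, mirroring a data-collection design that
spreads behaviour from equal to proportional regimes).

What the synthetic populations do **not** emulate: human end-game
effects, learning across games, response noise correlated with pool
size, and idiosyncratic per-participant styles. Passing the clone
fidelity tests therefore shows the imitation pipeline recovers *known*
generative behaviour from logs, not that it reproduces human play;
training on real gameplay logs is supported through the same JSON
Lines reader but is outside the test conditions.

## Behavioural clones

Architecture: observations are ego-centric (focal player rolled to
slot 0) 9-vectors — four current offers, four previous contributions,
pool — divided by the normaliser 200. Two ReLU encoder layers (default
width 64) feed a GRU (width 32), two decoder layers (width 64) and a
linear head over `N` bins partitioning the contribution proportion
space [0, 1]. `N` defaults to 10 and is configurable. A memoryless
ablation replaces the GRU with an equal-width feed-forward layer.

The action head is categorical-uniform: bin probabilities from a
softmax; at inference the modal bin is taken (ties to the lowest index)
and the contribution drawn uniformly inside the bin. A `sample_full`
mode samples the categorical instead, and an `expectation` mode returns
the deterministic mean `e·Σ_b p_b(b+0.5)/N` — the form used inside
differentiable mechanism training. The bin semantics read the bin
interval on the proportion scale (index interval rescaled by `1/N`);
the top bin is closed so `c = e` maps to bin `N−1`.

Training: one sequence per player per game; backpropagation through
time of the cross-entropy between predicted bins and the bins of the
actually chosen contributions; Adam with learning rate starting at
5e-4, multiplied by 0.95 every 1,000 updates, floored at 5e-6; batches
of 256 sequences at full scale. Rounds where the focal offer is below
1 are masked out of the loss: the zero contribution there is forced by
the rules and carries no behavioural signal. Checkpoint selection
scores ensembles by surplus under hand-coded baselines minus λ times
surplus under the random mechanism (λ = 1 by default): competent play
under sensible planners, no degenerate profit under random ones.
Ensembles sample members with replacement per episode slot during
training; a fixed-slot mode pins one member per seat for analysis.

Desk-scale conditions (tests, acceptance script): encoder/decoder
widths 32, GRU 16, batch 64, 600–800 updates, 120–200 fixture games.
These sizes were chosen once as the smallest at which the pipeline's
qualitative properties (cross-entropy well below ln N, modal-bin
recovery, recurrent-beats-memoryless on grim data) are comfortably
expressed.

## The graph-network mechanism

Each round becomes a fully connected directed graph: one vertex per
player with attributes (previous endowment, previous contribution,
pool), empty edge attributes, pool as the global attribute, all
normalised by 200. A graph block updates edges first
(`e'_{sr} = φ_e(e_{sr}, v_s, v_r, u)`), then nodes from summed incoming
updated edges (`v'_r = φ_v(Σ_s e'_{sr}, v_r, u)`), then the global from
summed edges and nodes. Shared update functions plus sum aggregation
give permutation equivariance, and symmetric round-0 inputs force a
uniform opening offer — both property-tested over random parameters.

Block 1 uses single ReLU layers of width 32 for `φ_e`, `φ_v`, `φ_u`.
Block 2 uses a ReLU edge layer (32); the node update is a GRU (hidden
16) whose state persists across rounds of an episode, followed by a
ReLU layer (32) and a linear scalar head; the global update is a ReLU
layer (32) plus a linear scalar head. The four node scalars and the
global scalar are softmax-normalised into five allocation weights
(four offers, one retained share), multiplied by the pool. A
memoryless variant replaces the GRU with a feed-forward layer and
passes the same feasibility/equivariance suite.

Training maximises cumulative surplus `Σ_t Σ_i (e_{i,t} − c_{i,t})` by
reverse-mode differentiation through the rollout: the pool update
(`min` and `max` are differentiated at their active branch), the
offers, and the players. Two gradient modes:

- `expected_action` (default): players act via their expected
  contribution, making the whole rollout deterministic and exactly
  differentiable, hence bitwise reproducible per seed.
- `pathwise_sample`: the categorical-uniform action is sampled and the
  sample carries the expectation's gradient (a straight-through
  estimator). Both modes are approximations to the underlying
  stochastic objective and are declared as such.

The sub-unit-offer rule enters as a constant mask (no gradient through
the discontinuity). Full-scale recipe: Adam, learning rate 1e-3 ×
0.95 every 1,000 updates floored at 1e-5, batches of 256 episodes,
500,000 updates, checkpoints every 50,000. Checkpoint selection takes
the highest mean evaluation surplus over a fixed seed set (32 episodes
at full scale; 8 in desk runs), ties to the later checkpoint.

Desk-scale conditions: width 16, GRU 8, batch 4 episode rollouts per
update, horizon 12 during training (evaluation still plays the full
40-round game), 600 updates. Under these conditions the trained
mechanism roughly doubles the equal baseline's surplus on the mixed
archetype population and learns the expected qualitative policy:
starve free riders, keep sustainers funded.

## Metrics

- **Gini** uses the sorted-vector identity equal to the mean absolute
  pairwise difference over twice the mean; an all-zero vector has
  Gini 0 by definition (total collapse is perfect equality). The
  implementation is checked against the O(n²) pairwise oracle.
- **Exclusions** are runs of consecutive sub-unit offers to a player
  who was included on the previous trial; a run reaching the final
  trial is flagged never-reincluded.
- **Lagged regressions** fit, per trial, OLS of the offer on the focal
  player's contributions at lags −4…+4 (plus an intercept), pooling
  (game, player) rows within a condition; medians across trials are
  reported. Zero-variance regressors get zero weights rather than an
  error — constant-offer mechanisms are legitimate inputs. An optional
  z-scored mode makes weights comparable across trials with different
  pool levels. Whether to pool players within a trial or fit per
  player was an open choice; pooling is used because per-trial,
  per-player fits with nine regressors are underdetermined at four
  players.
- Condition summaries report per-game rows, means, the
  sustained/depleted split, and the surplus–Gini correlation within
  each subset (undefined correlations are reported as absent, not as
  numbers).

## Numerical choices

- Allocation feasibility (`Σ offers + retained = R`) is enforced to
  1e-9 relative tolerance; episode rollouts rescale offers only to
  absorb sub-ulp softmax overshoot.
- Argmax ties in the clone head break to the lowest bin; calibration
  ties break to the larger exponent; checkpoint-score ties break to the
  later checkpoint.
- All randomness flows from integer seeds through
  `numpy.random.default_rng`; per-episode and per-stage streams are
  derived by seed tuples, so every pipeline stage is reproducible
  byte-for-byte given its seed (expectation-mode training included).
- The autodiff engine differentiates `min`/`max` by routing the
  gradient to the first argument on ties, and `where` masks carry no
  gradient. Gradient correctness is tested against central finite
  differences for every operation family used.

## Known limitations

- Pure-numpy training is CPU-bound; the full-scale printed recipes
  (hundreds of thousands of updates, batch 256) are supported by the
  code but impractical without acceleration. All shipped experiments
  use the desk-scale conditions above.
- The straight-through `pathwise_sample` gradient is biased; it is
  provided for completeness, while `expected_action` is the default
  and the tested path.
- Scripted archetypes are stylised; conclusions about human play
  require training clones on real gameplay logs, which the pipeline
  accepts but does not ship.
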