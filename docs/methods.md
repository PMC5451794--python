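# Methods

## Model

`boldfish` simulates a group of `N` agents repeatedly playing an
N-player snowdrift game in extensive form. Agent `i`'s boldness
`s_i ∈ (0, 1)` is both a personality trait and its strategy. Each task:

1. decision times `t_i ~ Exp(rate = s_i)` are drawn independently; the
   agent with the smallest time is the initiator. By the standard
   properties of competing exponentials the winner's index follows
   `P(m) = s_m / Σ_i s_i` and the winning time is `Exp(Σ_i s_i)`, both
   of which the test suite checks by Monte Carlo against the explicit
   race;
2. each non-initiator independently follows with probability `1 − s_i²`
   (the quadratic encodes that bolder agents respond less to someone
   else's initiative), free-riding otherwise. The draws are independent
   across agents and do not depend on how many others already
   cooperate — the role rule is memoryless per agent;
3. the task succeeds (`r = 1`) with probability
   `P(success | obstacle level, n_C)` from the success table; payoffs
   are `p_C = r·b − c` for the initiator and followers, `p_D = r·b` for
   free-riders;
4. only the initiator updates, `s ← r·λ + s·(1 − λ)`. Under a constant
   outcome this recursion has the closed form
   `s(k) = r + (s(0) − r)(1 − λ)^k`, which the suite asserts on a
   forced-outcome environment.

The reference model strips out personality: each agent cooperates
independently with probability `ŝ_i`; there is no initiator and no
decision time, `n_C = 0` is possible and counts as failure with zero
payoffs for everyone (the only reading consistent with the payoff
definition). With evolution enabled, every cooperator applies the same
update rule with the shared outcome.

## Parameters and defaults

| parameter | symbol | default | meaning |
|---|---|---|---|
| `n_agents` | N | 6 | group size |
| `benefit` | b | 2 | benefit to every agent on success (payoff units) |
| `cost` | c | 1 | cost paid by each cooperator (payoff units) |
| `update_rate` | λ | 0.9 | reinforcement rate of the initiator's trait |
| `bold_threshold` | — | 0.7 | agent is "bold" when `s_i > 0.7` (strict) |
| `shy_threshold` | — | 0.3 | agent is "shy" when `s_i < 0.3` (strict) |
| `n_tasks` | — | 200 | tasks per evolution |
| `stats_window` | — | 100 | trailing tasks used for all summary statistics |
| `replicates` | — | 5 | runs per sweep cell |

N=6, b=2, c=1, 200 tasks and the last-100 window are the canonical
experimental settings of the study this model describes; λ is swept over
0.4–0.9 in steps of 0.1 in the full grid, and 0.9 — the value used for
the headline high-update-rate comparisons and for the evolving reference
model — is the single-run default. Initial traits are i.i.d. uniform on
(0, 1) from the seeded stream unless supplied explicitly. Decision times
are dimensionless (rates are boldness values, not physical seconds).

## The success table

The physical environment — robots pushing obstacles of 1.6, 2.0, 2.5 and
2.9 kg within a time limit — is replaced by a single Bernoulli draw per
task with probability `P(success | level, n_C)`. Empirically pinned
cells: `(O1, 1) = 0.17`, `(O1, n_C ≥ 2) = 1`, `(O2..O4, n_C ≤ 2) = 0`,
`(any level, 6) = 1`. The remaining cells use a deterministic threshold
fill — success iff `n_C` reaches 2/3/4/5 for O1..O4 — chosen to be
consistent with the qualitative description of the environment
(the hardest task succeeds "almost surely" with 5–6 cooperators). These
intermediate cells are a declared stand-in, not measured data; the table
is fully overridable from the run configuration as a `level × n_C`
matrix, validated at load time for monotonicity in both axes.

Because the environment is a stand-in, the simulator reproduces the
*qualitative* phenomena (cooperator counts tracking difficulty, bold
counts falling with difficulty, diversity rising with λ and difficulty,
the reference model collapsing on hard tasks) rather than the exact
figures measured on physical hardware. Passing tests demonstrate the
mechanics and the self-organisation phenomena, not hydrodynamic realism:
there is no spatial motion, no pushing-force model, no duration
dependence, and no timeout process (timeouts are folded into the
probabilities).

## Numerical choices

- **Trait clamping.** The exact update maps (0, 1) into itself, but in
  float64 `r·λ + s·(1 − λ)` rounds to exactly 1.0 after ~17 successful
  updates at λ = 0.9. Updates are therefore clamped to
  `[nextafter(0, 1), nextafter(1, 0)]`, the representable interior of
  the unit interval. Closed-form recovery is asserted at 1e-12 absolute
  tolerance — the scale of accumulated float round-off — rather than
  bitwise.
- **Tie-breaking.** Equal decision times (probability zero under
  continuous sampling) resolve to the lowest agent index, so degenerate
  hand-built inputs stay reproducible.
- **Fast mode.** `play_stage_game(..., fast=True)` samples the initiator
  directly from `s_m / Σ s_i` and the winning time from `Exp(Σ s_i)`
  instead of materialising the race; distributionally equivalent (tested
  by chi-square) but the losers' decision times are not generated. The
  explicit race is the default because the decision time is itself a
  reported statistic.
- **Replicate seeding.** Sweep cell (λ, level, replicate) derives its
  seed from `SeedSequence([base_seed, λ·1000, level index, replicate])`,
  reduced mod 2³¹, so any subset of a sweep reruns identically in
  isolation.
- **Serialization.** Floats are written with shortest round-trip `repr`;
  identical seed + configuration produce byte-identical CSVs, and every
  value survives a write/read cycle exactly.

## Design choices where the design was open

- **Statistics window.** Initiator shares `p_i` and the diversity index
  `d_I` use the same trailing window as every other statistic; `d_I` is
  the population (divide-by-N) standard deviation, not the sample form.
- **Per-capita normalisation.** "Average cost" and "average pay-off" are
  reported per agent per task (`c·n_C/N` and `Σπ/N`), which makes values
  comparable across group sizes and yields the per-task identity
  `payoff + cost = r·b`, asserted in the tests.
- **Bold counts per task.** `n_B` is computed from the post-update trait
  snapshot of each task (the state carried into the next task), applied
  uniformly across the simulator and the metrics.
- **Follower independence.** The follower/free-rider draws are
  independent Bernoulli per non-initiator; no conditioning on how many
  others cooperate.
- **Reference-model corner.** `n_C = 0` is allowed and is an automatic
  failure; the reference dynamics are run verbatim with no assumption
  about the direction its converged strategies take.

## Problem sizes

The test suite and the acceptance script use the study-scale settings
throughout: 200-task evolutions, 5 replicates per sweep cell, the 2-rate
× 4-level grid, and 10⁵-draw Monte Carlo checks for the distributional
laws. A full test run completes in well under a minute on one CPU.

## Known limitations

- Intermediate success-table cells are constructed defaults; quantities
  that depend on them (e.g. exact success rates at low λ) are not
  comparable to hardware measurements.
- Single-evolution phenomena (e.g. the exact diversity of one run) are
  seed-dependent; only replicate-averaged trends are stable.
- The model assumes a single initiator per task and no within-task
  dynamics; partial participation, interruption and communication are
  out of scope.
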