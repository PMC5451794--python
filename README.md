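# boldfish

Seeded simulator of an N-player snowdrift foraging game in which
leadership and personality divergence self-organise. A small group of
agents repeatedly faces a collective task — pushing a weighted obstacle
out of the way — and each agent carries a *boldness* trait
`s_i ∈ (0, 1)` that is simultaneously its strategy in the repeated game.
The package is for researchers in collective animal behaviour and
evolutionary game theory who want a fast, fully reproducible in-silico
version of this experiment: every run is determined by a configuration
and a seed.

## The model

One *stage game* (task) unfolds in four steps:

1. **Initiator race.** Each agent draws an exponential decision time
   `t_i ~ Exp(s_i)` (mean `1/s_i`); the agent with the smallest draw
   initiates. The winner is distributed as `P(i) = s_i / Σ_m s_m`, so
   bold agents lead more often.
2. **Role assignment.** Each other agent independently joins as a
   follower with probability `1 − s_i²`, otherwise it free-rides.
   Initiator + followers are the cooperators (C-players).
3. **Outcome and payoffs.** The task succeeds (`r = 1`) with a
   probability `P(success | obstacle, n_C)` given by a success table
   over four difficulty levels O1–O4 (obstacles of 1.6–2.9 kg); with
   `n_C = 6` cooperators every task succeeds, while a single pusher only
   moves the lightest obstacle 17% of the time. Payoffs follow the
   snowdrift structure `p_C = r·b − c`, `p_D = r·b` with `b = 2 > c = 1`.
4. **Reinforcement.** Only the initiator learns:
   `s ← r·λ + s·(1 − λ)` with update rate `λ ∈ (0, 1)` — success makes
   it bolder, failure shyer.

An *evolution* is 200 such tasks with the traits threaded through; all
summary statistics (mean boldness s̄, cooperator count n_C, bold count
n_B with `s_i > 0.7`, initiator shares `p_i`, the diversity index
`d_I = √((1/N) Σ_i (p_i − p̄)²)`, decision time, per-capita cost and
pay-off, success rate) are computed over the last 100 tasks. A
personality-free reference model — each agent simply cooperates with
probability `ŝ_i`, optionally updated by the same rule — is included for
contrast.

## Worked example

```python
import boldfish as bf

params = bf.GameParams()                      # N=6, b=2, c=1, λ=0.9
table = bf.build_default_success_table(params.n_agents)
schedule = bf.make_schedule({"fixed": "O4"})  # hardest task, 200 times
record = bf.run_evolution(params, schedule, table, seed=1)
stats = bf.summarize_evolution(record)        # last-100-task window
print(f"cooperators per task: {stats.mean_n_coop:.2f}")
print(f"bold agents:          {stats.mean_n_bold:.2f}")
print(f"diversity d_I:        {stats.diversity:.3f}")
print(f"success rate:         {stats.success_rate:.2f}")
print(f"decision time:        {stats.mean_decision_time:.3f}")
```

prints

```
cooperators per task: 4.99
bold agents:          2.00
diversity d_I:        0.232
success rate:         0.99
decision time:        0.480
```

On the hardest task the group settles at ~5 cooperators (the minimum
that guarantees success), only two agents stay bold, the initiator role
concentrates on few agents (d_I well above 0), and the group succeeds in
99% of the last 100 tasks while taking ~0.48 time units to produce an
initiator. Rerunning on O1 instead gives ~2 cooperators, ~5 bold agents
and a much shorter decision time: the group adapts its division of
labour to task difficulty without any communication.

The same runs are available from the shell:

```bash
boldfish run --seed 1 --out-dir out/          # single evolution → CSV + JSON
boldfish sweep --seed 1 --out-dir out/sweep   # λ × difficulty grid, 5 replicates
boldfish reference --seed 1 --out-dir out/ref # personality-free contrast
```

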