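# Methods

## Model

`divlearn` simulates a population of `n_agents` agents placed on the nodes
of a simple undirected graph, each holding one candidate solution — an
`n_elements`-bit vector, stored internally as an integer code with element
0 in the least-significant bit.  Solution quality is given by NK payoff
functions: for each element, a contribution value drawn i.i.d. uniform on
[0, 1] for every joint state of the element and its `k_interactions`
partner elements, with partners sampled uniformly without replacement and
fixed at generation (the standard random-neighbourhood NK variant).  The
raw payoff of a solution is the mean contribution over elements.  Raw
payoffs are normalized by the enumerated global maximum and raised to the
power `exponent`, so the transformed payoff lies in (0, 1] and equals 1
exactly at the global optimum.  The transform is strictly monotone, so it
never reorders solutions; its purpose is to concentrate payoff mass on
near-optimal solutions.

Skill diversity is modelled by partitioning the population into
`n_classes` *exactly* equally sized classes.  Each class owns one
independently drawn landscape with identical `(n_elements,
k_interactions, exponent)`; agents are assigned to classes by a uniformly
random balanced permutation and to graph nodes by a random shuffle.
Unequal class sizes are rejected with an error rather than silently
rebalanced, because class size would otherwise confound the diversity
variable.

### Dynamics

Each step is synchronous: all decisions read the time-t snapshot and all
accepted changes apply simultaneously.  Per agent:

1. **Exploitation** — evaluate every neighbour's current solution under
   the *focal agent's own* payoff function; adopt the best one iff it
   strictly exceeds the agent's current payoff.  Ties among equally good
   neighbour solutions are broken uniformly at random.
2. **Exploration** (only when exploitation yields no candidate) — flip
   one uniformly chosen element; keep the result iff it strictly improves
   the agent's own payoff.

Both moves require *strict* improvement.  This makes each agent's payoff
non-decreasing, rules out churn between equal-payoff solutions (payoff
ties across distinct solutions have probability zero within one
landscape), and gives an exact absorption test: a state is absorbed iff no
agent has a strictly better neighbour solution under its own function and
every agent sits at a local optimum of its own landscape.  From such a
state every future step is the identity, which `run()` exploits to stop
early; reaching the horizon without absorption is recorded on the
trajectory, not an error.

Evaluating neighbours' solutions under the focal agent's own function is a
deliberate design choice: the alternative rule — pick the neighbour with
the highest *self-reported* payoff, adopt only if the solution improves
the own payoff — is available via `evaluation="advertised"` for
sensitivity analysis.  Under unconditional adoption of self-reported-best
solutions, diverse populations degenerate (agents perpetually adopt
solutions that are poor under their own function), which is why that
variant is not offered.

### Measurement

Collective performance is ⟨P⟩(t), the population mean of own-function
transformed payoffs; it is non-decreasing under these dynamics.  On smooth
landscapes (`k_interactions = 0`) the interesting quantity is T_O, each
agent's first step holding its own landscape's optimum (own payoff exactly
1; the payoff table pins the raw argmax to exactly 1.0 so this comparison
is free of rounding).  Agents that never reach their optimum within the
horizon are *censored*: excluded from mean-T_O averages, with the censored
fraction reported alongside rather than imputed.  Aggregation over
realizations aligns ⟨P⟩(t) curves by step and pads runs that absorbed
early with their absorbing value; T_O values are pooled across all agents
of all realizations (the mean of per-realization means is reported too,
since the two weightings can differ when censoring is uneven).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_elements` (N_NK) | 15 | solution length in bits; landscapes are built by exhaustive enumeration of all 2^N_NK solutions (guard at 24 bits) |
| `k_interactions` (K_NK) | 0 or 7 | ruggedness; 0 = smooth single peak (simple task), 7 = hundreds of local optima (complex task) |
| `exponent` | 8 | payoff sharpening power |
| `n_agents` (N) | 1000 | population size |
| `n_classes` (C) | 1 | number of skill classes; must divide N |
| `mean_degree` (⟨k⟩) | 4 | link density; Erdős–Rényi edge probability p = ⟨k⟩/(N−1) |
| `max_steps` | 1000 | horizon; runs stop earlier at absorption |
| `n_realizations` | 50 | independent repetitions per condition |

Network families: `er` (Erdős–Rényi, the default density control),
`regular` (random regular), `smallworld` (Watts–Strogatz, with
`rewire_prob`), `complete`.  Isolated nodes in sparse ER graphs are kept:
such agents never exploit and only explore.  No connectivity repair or
giant-component extraction is performed.

## Randomness and reproducibility

Every stochastic component draws from its own named stream spawned from a
master seed (`numpy.random.SeedSequence` with integer tags): per-class
landscapes, class assignment, node shuffle, initial solutions, network,
dynamics.  Consequences: two sweep cells sharing a realization index reuse
identical network and initial-solution draws whenever their configurations
coincide on those components, and changing the class count does not
perturb the network draw.  Within a run, each step consumes exactly two
arrays from the dynamics stream — `rng.random(n_agents)` tie-break
uniforms, then `rng.integers(0, n_elements, n_agents)` flip positions —
for every agent whether used or not.  This fixed consumption pattern is
what makes the vectorized synchronous step bit-identical to a naive
per-agent reference loop, which the test suite verifies on random
micro-instances.

## Numerical choices

- The full transformed payoff table (2^N_NK entries per class) is
  precomputed at landscape generation; normalization already requires the
  enumeration, and the cache makes every payoff evaluation during
  dynamics an O(1) table lookup.
- Ties for the maximum raw payoff (probability zero under continuous
  contributions) break to the smallest solution code, for determinism.
- The payoff table entry at the raw argmax is set to exactly 1.0,
  avoiding `(x/x)**8` rounding in the "reached own optimum" test.
- Exploitation tie-breaks select the ⌊u·m⌋-th tied neighbour in adjacency
  order from a per-agent uniform u, identically in the vectorized and
  reference implementations.
- Landscape serialization stores generation inputs only (partners,
  contribution tables, seed); payoff tables are rebuilt on load.

## What the generator emulates — and what it does not

All inputs are synthetic by construction: NK landscapes stand in for task
structures whose difficulty is tunable through K_NK, and random graphs
stand in for communication structure with density as the single control.
Conclusions from these simulations are about this idealized setting:
payoffs are observed noiselessly, skills map to statistically independent
landscapes with identical parameters, classes are exactly balanced and
randomly placed, and updates are synchronous.  Real collectives violate
all of these in various ways (correlated skills, noisy evaluation,
degree-correlated ability, asynchronous communication), so passing tests
demonstrate properties of the model, not of any empirical system.

## Problem sizes

The test suite and the acceptance script run desk-scale configurations —
N = 200–500 agents, 50–100 realizations per condition, horizons of
750–1000 steps — chosen so the full suite completes in a few minutes
while leaving the qualitative phenomena (simple-task convergence,
diversity slowing simple tasks, density speeding them, complex-task
suboptimality) well resolved.  Paper-scale runs (N = 1000, thousands of
realizations, dense degree grids) use the same code paths via
`ExperimentConfig`.

## Known limitations

- Final-performance differences between homogeneous and diverse
  populations on *dense* networks are small relative to
  realization-to-realization variability — homogeneous runs inherit a
  large variance from the single landscape draw per realization — so
  resolving them needs realization counts in the thousands, beyond the
  desk-scale defaults.
- Landscapes must be exhaustively enumerable (N_NK ≤ 24); there is no
  sampling-based normalization for larger solution spaces.
- No asynchronous updating, no copying strategies other than best-member,
  no noisy payoff observation, no unequal class sizes or class-correlated
  placement.
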