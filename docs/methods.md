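# Methods

This package simulates developmental learning of hierarchical
probabilistic structure by a predictive-coding-inspired variational
recurrent neural network (PV-RNN), and measures how the *meta-prior* —
the per-layer weight on the KL (regularisation) term of the variational
free energy — interacts with environmental signal noise to shape
behavioural and cognitive flexibility and the causal "generative
hierarchy" of the learned latent representation.

## The environment

Observations are 2-D trajectories mimicking reaching movements,
generated by a three-level hidden process:

1. **Transition bias** `b ∈ (0, 1)` — the top-level context: the
   probability that a reach from HOME targets LEFT (else RIGHT).
2. **Target state** — one Bernoulli(b) draw per reach.
3. **Signal noise** `σ` — goal positions are drawn from
   `N(center(target), σ² I)`, and i.i.d. `N(0, σ² I)` observation noise
   perturbs every time step; samples are clipped to `[-1, 1]²`.

State centers default to HOME = (0, −0.6), LEFT = (−0.6, 0.6),
RIGHT = (0.6, 0.6) — a well-separated triangle in the unit box, exposed
in `EnvConfig`. `σ_stable = 0.05` keeps the three states cleanly
separable; `σ_noisy = 0.25` makes LEFT/RIGHT clouds overlap (the
"noisy environment" manipulation).

Each reach is HOME → goal → HOME by linear interpolation
(`steps_per_segment = 6` each way) with `dwell_steps = 2` at the goal
and at HOME, i.e. a 16-step cycle. The cycle length is deliberately a
divisor of the half- and full-sequence lengths (128/256/512): a test
sequence is built by concatenating two independently rendered halves
with biases on opposite sides of 0.5, and an integral number of cycles
per half keeps the reach rhythm *phase-coherent* across the switch.
With a non-divisor cycle the concatenation itself injects a phase jump
in the rigid rhythm, which no amount of posterior inference can absorb
(the clock is identical in every training sequence, so the latents
never learn to control phase); that artefact floors prediction
accuracy after the switch in *every* condition and masks the
meta-prior effect the experiments are designed to measure.

The default training corpus is two sets of nine 512-step sequences,
one per transition bias in
{0.98, 0.87, 0.76, 0.65, 0.54, 0.43, 0.32, 0.21, 0.10}. A scaled-down
preset (used by the condition grid and the test suite) uses one set of
six 256-step sequences with biases {0.98, 0.76, 0.65, 0.43, 0.32,
0.10} — three per side of 0.5, preserving the asymmetric ladder.

**What the generator does not emulate:** real reaching kinematics
(minimum-jerk profiles, variable movement durations), proprioceptive or
3-D channels, non-Gaussian noise, and any sensory consequence of the
agent's own action. Passing tests therefore speak to the model's
ability to extract a three-level stochastic structure from clean
low-dimensional signals, not to robustness on naturalistic sensorimotor
data.

## The agent

Three layers, each with deterministic leaky-integrator units `d` and
Gaussian latents `z`:

| layer | n_d | n_z | τ |
|------:|----:|----:|---:|
| 1 (lower / fast)  | 20 | 2 | 2 |
| 2 (middle)        | 10 | 2 | 8 |
| 3 (higher / slow) | 10 | 2 | 32 |

Per step `t` and layer `l`:

```
prior       p(z_t^l | d_{t-1}^l):  μ^p = tanh(W_μ d_{t-1}^l + b_μ),
                                   σ^p = exp(W_σ d_{t-1}^l + b_σ)
posterior   q(z_t^l | a_t^l):      μ^q = tanh(a^μ_t),  σ^q = exp(a^σ_t)
dynamics    h_t^l = (1 − 1/τ_l) h_{t-1}^l
                    + (1/τ_l) (Σ_m W_{m→l} d_{t-1}^m + W_z z_t^l + b)
            d_t^l = tanh(h_t^l)
output      x̂_t = tanh(W_out d_t^1 + b_out)
```

`m` ranges over layers {l−1, l, l+1} that exist: the hierarchy is
connection-restricted, and `z` never crosses layers. The loss is the
meta-prior-weighted free energy

```
L = Σ_t ½‖x_t − x̂_t‖²  +  Σ_t Σ_l w^l KL[q(z_t^l) ‖ p(z_t^l)]
```

with a fixed-unit-variance Gaussian likelihood (the environment's
output noise level is not revealed to the agent, and no variance head
is learned; any constant likelihood scale is absorbed into the scale
of `w`). The conditions *weak / normal / strong* set the lower layer's
`w` to 0.1 / 1.0 / 10 with 1.0 elsewhere. Initial states are
`h_0 = d_0 = 0`, so the first-step prior is the learned constant
`(tanh b_μ, exp b_σ)`; weights start `N(0, 1/fan-in)` on the allowed
connectivity, biases and adaptive variables at zero.

The posterior is parameterised by the adaptive variables alone
(`μ^q = tanh a^μ`); the conditioning on `d_{t-1}` enters through the KL
against the `d`-dependent prior, which is the standard PV-RNN reading.
A config switch for an additive `d`-dependence in `μ^q` was considered
and rejected: it complicates the error-regression contract (frozen
weights would then shape the posterior directly) without changing any
quantity this package measures.

### Implementation

No autodiff framework is used: the layers are stacked into single
`d` (40,) and `z` (6,) vectors, the connection restriction is a binary
block mask multiplied into weight matrices and their gradients, and
backpropagation through time is implemented analytically. Everything
except the reverse-time carry is vectorised over (sequence, time); the
gradients are validated against central finite differences to 1e-4
relative error in the test suite. The two sequential carry loops are
numba-compiled, with an equivalent pure-NumPy fallback (both agree to
1e-13). Training uses Adam on two parameter groups: synaptic weights
(lr 1e-3 full-scale, 2e-3 scaled preset) and adaptive variables at 10x
that rate — the per-step adaptive variables are sequence memory, not
shared structure, and tolerate a much faster rate. One optimizer step
is taken per *sequence*, in an epoch-wise shuffled order. Both the
split learning rate and the per-sequence stepping were forced by the
loss landscape: full-batch gradients with a single shared rate leave
the runs on a long plateau in which the network predicts the average
reach cycle and `z` carries nothing, and escape from that plateau is
erratically seed-dependent; per-sequence gradient noise breaks it for
every corpus/seed combination probed. A full-batch mode remains
available (`TrainConfig(batch_gradient=True)`). Fresh
reparameterisation noise is drawn each update from the run's seeded
generator, so training is bit-reproducible.

Default epoch budgets — 5×10⁴ (full corpus), 1.5×10³ (scaled preset) —
were chosen by watching the reconstruction plateau on the scaled
corpus, not taken from any reference.

## Test phase: error regression

With weights frozen, the network adapts online to an unseen sequence by
optimising `a` in a sliding window (default length 16, 30 Adam
iterations per step at lr 0.05, warm-starting each new step's `a` from
its predecessor; the grid runs use 15 iterations). The windowed loss is
the free energy restricted to the window, with a test-phase meta-prior
`w_test` that defaults to the network's learning-phase `w`. After
optimising, the network rolls one step past the window with the prior
mean to emit the one-step-ahead prediction. Optimisation and prediction
use distribution means (no sampling), so reported predictions are
deterministic; a sampling mode exists in `generate` for rollouts.

## Measures

- **Behavioural flexibility** — % of steps on which the
  nearest-center state of the one-step-ahead prediction matches that of
  the observation, over the full test sequence. Nearest-center ties
  break toward HOME < LEFT < RIGHT.
- **Cognitive flexibility** — max over the highest layer's two
  posterior-mean traces of |Pearson r| with the piecewise-constant true
  bias signal; exactly constant traces score 0 by convention. The
  posterior mean (μ^q) is correlated, not sampled z or d, and the max
  (not mean) over units is taken because the two top-layer units tend
  to code the two context directions with opposite sign; a mean-|r|
  aggregate is available via an argument.
- **Latent-space traversal / generative hierarchy** — for each latent
  unit, closed-loop generation of 1,024 steps per clamp value on a
  21-point grid spanning [−1, 1] (mean channel: the sampled z entry is
  pinned; variance channel: σ^p is pinned to exp(value), so σ spans
  ≈[0.37, 2.72]). Each generated sequence is summarised by nine
  per-state properties (stay steps, entries, coordinate variance); a
  unit's *efficacy* is the max over properties of |Pearson r(clamp
  value, property)|, and a layer's *generative hierarchy* is its units'
  mean efficacy. Non-clamped latents are sampled from the prior with an
  independent, fixed noise stream per grid point: a unit scores high
  only if its causal effect on behaviour rises above the generation
  noise. (An earlier design shared one noise stream across grid points;
  that makes the correlation ≈1 for *any* infinitesimal monotone
  effect and cannot discriminate layers.)

## Condition grid and statistics

The experiment crosses meta-prior {weak, normal, strong} with
environment {stable, noisy}. Per condition: one corpus (shared across
that environment's conditions, like a fixed stimulus set), `n`
independently seeded networks, one freshly generated test sequence per
network, and the metrics above; results are one tidy row per network.
Analysis per metric and condition applies a 1.5×IQR Tukey fence
(quartiles by linear interpolation, the numpy default) before
between-subject ANOVA. The two-way ANOVA uses Type-III sums of squares
via sum-to-zero effect coding and full-model comparison — cells are
unbalanced after outlier removal, so marginal tests are the defensible
choice. Simple effects of environment within a meta-prior level test
the two-cell contrast against the pooled within-cell error of the full
design. Post-hoc pairwise comparisons use pooled-error t tests with
Shaffer's modified sequentially rejective Bonferroni schedule for three
groups (thresholds α/3, α, α on the ascending p-values, stopping at the
first retention — after one true rejection at most one hypothesis among
three pairwise equalities can remain true). Outlier filtering is per
metric, independently.

## Problem sizes

The test suite and the bundled experiments run the scaled preset: six
256-step training sequences, 1,500 epochs, five networks per condition,
15 error-regression iterations per step, and full-length (1,024-step)
traversals. These sizes were fixed once, by loss-plateau convergence
and by what a laptop-class single core handles comfortably; the
full-scale settings (18×512, 5×10⁴ epochs, 20 networks per condition)
are available through `GridConfig(scaled=False)` and the CLI `--full`
flag.

## What the scaled experiments do and do not reproduce

At the scaled size, the condition grid reproduces the flexibility
ordering (normal and weak out-predict strong on context-switching
sequences) and the layer-resolved representation pattern (the higher
layer's generative hierarchy peaks under the normal meta-prior, while
the weak condition keeps a strong lower layer but a weak higher
layer). It does **not** reproduce the noise-amelioration effect (the
strong condition improving in the noisy environment): that effect
presupposes a severe strong/stable learning deficit, and at this
corpus size the deficit is an optimization-regime phenomenon — it
appears under full-batch training, where environmental noise does
rescue the strong networks, but full-batch training also strands many
normal-condition runs, whereas the reliably converging per-sequence
scheme lets strong/stable networks learn the corpus well enough that
there is little left to ameliorate, and the noisy observations
themselves depress state agreement. Separating the regimes appears to
require the full-scale corpus and training length, which is orders of
magnitude beyond what a test suite can run; the corresponding check is
left in the suite as a known failure rather than weakened.

## Known limitations

- The kinematics are a stand-in (the linear 16-step cycle described
  above); absolute flexibility percentages depend on them, and only
  the *orderings* across conditions should be compared with other
  implementations of the same design.
- The unit-variance output likelihood fixes the recon/KL exchange rate;
  meta-prior values are only comparable within this convention.
- Error regression optimises a non-convex windowed objective with a
  few dozen Adam steps; it exhibits the behaviours of interest here
  (tracking, perseveration under a strong prior) but is not a global
  optimiser, and its window/iteration/learning-rate settings are
  empirical defaults.
- Statistical replication at the scaled size is directional
  (orderings of condition means), not numerical: F and t statistics
  from 20-network full-scale runs are stochastic outcomes and are not
  reproduced.
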