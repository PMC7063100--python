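# Methods

## Model

The simulator implements a two-armed decision problem abstracted from infant
gaze-following experiments: an actor attends to one of two equally salient
objects; the infant either follows the actor's gaze (action B, reward
probability 1 — joint attention always succeeds) or looks at one object at
random (action A, reward probability 0.5). Behavioral values Q(A), Q(B)
start at zero and are updated by a delta rule whose target is the *expected*
reward `R·P(r)` (optionally scaled by the communicative cue). Rewards are
never sampled as Bernoulli outcomes: the update equations place the reward
probability inside the target, so the only stochasticity in the value
process comes from the per-trial cue and state draws. This makes the
baseline variant fully deterministic and gives every variant an exactly
solvable mean learning curve (below).

Actions are selected by a soft-max policy `P(a) ∝ exp(Q(a)/τ)`. Action
choice never feeds back into the values in the default full-information
update mode, in which both action values are updated each trial with the
shared trial context (the infant sees both objects and the actor's target
whether or not it followed). A `selected_only` mode that updates just the
chosen action is retained for sensitivity analysis; the exact mean-curve
analytics deliberately refuse to run in that mode, because there the
context seen by each value depends on the policy and the expectation
recursion is no longer linear.

## Variants and their parameters

All parameters live on `ModelSpec`; defaults are the standard study
conditions used throughout the tests and the acceptance script.

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.005 | learning rate; the cap on what one trial can teach |
| `reward_value` R | 1 | reward magnitude (dimensionless) |
| `pr_follow`, `pr_random` | 1.0, 0.5 | reward probabilities of the two actions |
| `cue_low`, `cue_high` | 0.5, 1.5 | bounds of the uniform communicative-intent draw C |
| `state_mean`, `state_sd` | 0.5, 0.16 | normal parameters of the internal state S / Ds |
| `motivation` M | 0.0 | fixed additive offset to the cue (enhancement only) |
| `tau` | 0.46 | soft-max temperature |
| `n_trials` | 2000 | session length |

The four variants: `baseline` (no context), `cue` (C scales the reward
target), `independent_state` (an attentional state S, independent of C,
scales the learning rate), and `enhancement` (the cue raises the default
state Ds through a decision tree: S = Ds when C+M ≤ 1, else
min(Ds·(C+M), 1)). The cue scales the update target of *both* actions — it
is a property of the trial, not of the action; the reward probability is
the only action-specific factor. This is the only reading under which a
single temperature reproduces both converged choice probabilities (~75% at
a value gap of ~0.52 and ~70% at ~0.41).

Motivation M is restricted to `cue_low + M ≥ 0` so update targets stay
nonnegative, and to the enhancement variant, where it shifts the cue both
in the reward target and in the decision-tree threshold.

### Numerical choices

- **State draws.** The normal state is *clipped* to [0, 1] rather than
  redrawn. Clipping at ±3.1σ is symmetric about the default mean 0.5, so it
  preserves the mean and shrinks the sd by only ~0.1%; it is also cheaper
  and keeps one draw per trial in the stream. The choice is recorded in
  every run summary.
- **Boundary cue.** C + M exactly 1 is a measure-zero event and takes the
  "no enhancement" branch (the strong-cue branch requires C + M > 1
  strictly).
- **Soft-max temperature.** The source experiments report converged choice
  probabilities but no temperature. τ = 0.46 is calibrated once, jointly,
  so that the converged policy reproduces both reported probabilities
  (~75% under standard motivation and ~70% at M = −0.2) with a single
  value; it is an explicit config field echoed in all outputs.
- **RNG.** One independently seeded PCG64 stream per trajectory; the
  within-trial draw order is fixed (cue, state, action, target coin, with
  the coin consumed even on follow trials) so trajectories are bit-stable.

## Fixed points and exact mean curves

In full-information mode the trial context is independent of the current
values, so the cross-seed expectation obeys the linear recursion
`E[Q_{t+1}] = (1 − α·E[S])·E[Q_t] + α·E[S·target]`, giving

- the **weighted fixed point** `Q* = E[S·target]/E[S]`, and
- the exact mean curve `E[Q_t] = Q*·(1 − (1 − α·E[S])^t)`.

The **naive** fixed point `R·P(r)·(E[C]+M)` — the expectation of the update
target — coincides with Q* whenever S is constant or independent of C. The
enhancement decision tree correlates S with C (strong cues get extra
learning weight), tilting the follow-action asymptote to ≈1.036 at M = 0
and ≈0.817 at M = −0.2, slightly above the naive 1.0 and 0.8. Both numbers
are reported; the naive one is the "expected optimal value" of plain
Q-learning, the weighted one is what the literal update equations converge
to. The discrepancy (≤ 0.04 under defaults) is an analytic property of
applying a cue-correlated multiplier to the learning rate.

E[S] and E[S·(C+M)] are computed by Gauss–Legendre quadrature (order 400)
over the uniform cue; the inner expectation over the clipped-normal default
state is evaluated in closed form from truncated-normal partial moments
(via the normal cdf/pdf), including the min(Ds·C′, 1) cap — no inner grid
is needed. An independent Monte-Carlo oracle (`mc_fixed_point_oracle`,
≥10⁶ (C, Ds) samples with a delta-method SE on the ratio estimate)
cross-checks every quadrature value in the tests; the two routes agree
within 3 SE for every variant and motivation level exercised.

Effective learning rates α·E[S] under defaults: cue 0.005, enhancement
≈0.0028, independent_state 0.0025 — the source of the convergence-speed
ordering cue < enhancement < independent_state, and of the same ordering of
mean values at trial 100 (≈0.394 > 0.253 > 0.221).

## Convergence diagnostic

No convergence criterion accompanies the reported trial counts in the
source experiments, so the package defines one: the convergence trial is
the first trial after which `|Q(B) − tail mean|` stays within a band δ
through the end of the run, the tail mean taken over the final 100 trials.
Per-seed trials are summarized by median and IQR over ≥100 shared seeds,
with a paired bootstrap on the median for pairwise speed orderings;
non-converged seeds are censored at `n_trials + 1`.

The band default is **δ = 0.05**. The stationary sd of the value process
under default parameters is 0.0149 (cue), 0.0110 (enhancement), and 0.0100
(independent_state): a band comparable to these (e.g. 0.02) measures each
variant's *noise amplitude* rather than its learning speed — the noisiest
variant (cue) then looks slowest, inverting the true ordering. At δ ≥ 3×
the largest stationary sd, in-band persistence is governed by the mean
curve and the diagnostic measures speed. Absolute convergence-trial numbers
remain δ-dependent and are treated only as an ordering, never as point
targets.

## What the simulations do and do not show

The generator *is* the study design: there are no external data. Ensembles
of independently seeded sessions (200 seeds × 2,000 trials in the tests and
the acceptance script; smaller sizes in unit tests and examples) stand in
for populations of infants, and every quantitative claim checked by the
tests is a property of this synthetic environment — uniform cues, clipped
normal states, stationary reward contingencies, expected-reward targets.
Passing tests show the implementation is faithful to that model; they say
nothing about real infants, whose cue statistics are non-stationary, whose
rewards are sampled outcomes, and whose individual parameters (α, τ, M)
vary. No fitting to empirical infant data is attempted or supported.

Other known limitations: two objects and a perfectly valid actor gaze only
(no saliency, head-pose discrepancy, or multi-object scenes); motivation is
a fixed trait, not time-varying; learning rate is constant; reversal of the
reward contingencies is out of scope.
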