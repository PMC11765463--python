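# Methods

This note documents the modelling assumptions, numerical conventions and
design choices behind `actinf`, and what the shipped simulations do and do
not establish.

## Generative model and conventions

A POMDP generative model consists of the observation model **A**, the
transition model **B**, the preference prior **C**, the state prior **D**
and the habit prior **E** (see the README for shapes). Conventions:

- All user-facing category, state and action indices are 1-based, matching
  the behavioural tables the package reads and writes; numpy internals are
  0-based and the conversion happens at the indexing site.
- **C** is stored as unnormalised log-preferences (0 neutral, positive
  preferred, negative aversive). It is converted to a distribution by a
  softmax only inside pragmatic-value and risk computations, so adding a
  constant to a modality's preferences has no behavioural effect.
- Policies are enumerated exhaustively and lexicographically over (time
  step, factor, action index); with control dimensions (4, 1) and planning
  depth 2 this yields the 4² = 16 policies of the T-maze. Stochastic model
  initialisation is deliberately not offered; reproducibility is through
  explicit seeds only.
- Dirichlet pseudo-counts over A, B and D represent uncertain model
  components; their column-normalised means are used as the expected model
  during inference. When learning is enabled for a component without
  supplied counts, flat counts of 1 are used (an uninformative prior; the
  alternative — scaled copies of the initial component — is available by
  passing the counts explicitly).

## Perception

State inference minimises the time-specific variational free energy under
a mean-field posterior over factors, by fixed-point iteration: each factor
is updated to q*(s^f) = σ(E_{q∖f}[ln p(o|s)] + ln prior_f), sweeping
factors in ascending order. Numerical choices:

- probabilities are floored at 1e-16 before every logarithm; softmaxes use
  max-subtraction;
- the sweep is initialised at the predictive (transition) prior, so a
  single-factor model converges in one sweep and equals exact Bayes;
- iteration stops after 10 sweeps or when |ΔF_t| < 0.001 (both
  configurable); each full sweep cannot increase F_t;
- an observation with zero likelihood under every state combination
  (before flooring) degenerates inference to the prior with a warning.

The free energy is exposed together with its complexity − accuracy split;
F_t ≥ −ln p(o_t) always, with equality at the exact posterior.

## Planning and action

Each policy's expected free energy accumulates over the roll-out:
G = Σ_t (−state info gain − pragmatic value − parameter novelty), with
risk + ambiguity computed alongside (the two decompositions are
algebraically identical and tested to 1e-10). Roll-outs condition on
predicted states only — the agent does not anticipate how its own beliefs
would change after future observations (no "sophisticated" inference), which
is why cue information is valued through the state information gain rather
than through its downstream effect on arm choice.

The parameter-novelty term uses the Dirichlet form
w(o, s) = ½(1/θ(o,s) − 1/Σ_{o'}θ(o',s)), in expectation under the
mean-field predicted q(o)·∏_f q(s^f) and restricted to the modalities being
learned. It is non-negative and vanishes as counts grow; cells with zero
prior counts (structurally impossible observations) are excluded. This is
one of several novelty conventions in use; only its qualitative behaviour
is load-bearing here.

The policy posterior is q(π) = σ(ln E − γ G) with policy precision γ
(γ = 0 recovers the habit prior E exactly). First-step action marginals
per factor are sampled ∝ p(u)^α: α = 1 samples the marginal itself and
α → ∞ is argmax. γ and α default to 16. An alternative reading of "softmax
transforming the action probabilities with α" would apply the softmax to
the probability vector itself (σ(α·p)); the p^α convention is used here
because it makes α = 1 the identity and gives α a clean inverse-temperature
semantics.

## Learning

Dirichlet counts update by θ_{t+1} = ω θ_t + η χ_t with learning rate η and
forgetting rate ω (defaults 1). χ is the outer product of the observation
one-hot with the joint state posterior for A; of consecutive posteriors in
the taken action's slice for B; and the first-step posterior for D. With
ω = 1, η = 1 each A update adds exactly unit mass per learned modality.
When ω < 1 the discount applies to the whole learned component per update
(not only the updated column), the simplest deterministic reading of the
rule. Within a time step the order is: state inference → count updates →
policy inference → action selection; B updates start at the second step and
D updates occur only at the first.

## The T-maze

The environment has four locations (centre 1, right arm 2, left arm 3, cue
4), a fixed-per-episode reward condition (right/left), rewards emitted only
in the arms (the rewarding arm pays reward with probability 0.95, the other
arm mirrors with loss), a cue that reveals the condition only at the cue
location (validity 1.0 by default), and deterministic location control.
The bundled agent model is structurally identical to this process except
that the reward modality is agnostic (0.5/0.5 reward/loss in both arms and
conditions) and carries a weak Dirichlet prior of 2·A with learning
restricted to that modality: the payout contingency must be learned.
Preferences are +3 (reward) and −3 (loss) log-units; D puts the agent at
the centre with an uninformed condition belief; E is uniform over the 16
two-step policies.

Typical behaviour: first move to the cue (the condition information gain
outweighs the one-step pragmatic cost), certainty about the condition,
then repeated visits to the rewarding arm; after 300 steps the learned
reward probability for that arm is ≈ 0.94–0.95 (the generative 0.95 shrunk
slightly by the prior counts). A minority of seeded episodes (~5–10%)
instead hit a genuine failure mode of greedy expected-free-energy agents:
if the first visit to each arm happens to return a loss, both arms look
pragmatically worse than staying at the centre/cue (≈1 nat), the small
novelty bonus (≈0.17 nats) cannot overcome this, and the agent never
samples the arms again — nothing further is learned. The acceptance script
therefore reports the median over seeds, i.e. the typical learned value.

## Dataset simulation and fitting

`simulate_dataset` draws each agent's action precision from a group
Gaussian (negative draws rejected), runs each agent in a fresh T-maze for T
steps, and emits a long-format table (one action column per factor;
uncontrollable factors are constant 1 and ignored by the likelihood). The
generator reproduces the study conditions it is used for — two groups of
five agents, α ~ N(8, 2²) and N(24, 2²), 300 steps — and is exactly
reproducible from its seed.

Fitting is per subject and meta-Bayesian: the replay likelihood presents
the recorded observations to a fresh agent, accumulates the log-probability
of each recorded action under the α-softmax of the agent's action
marginals (floored at 1e-16), and advances the agent with the recorded
action (teacher forcing). Sampling uses an adaptive random-walk Metropolis
sampler (per-parameter proposal scales adapted during warmup toward ~0.4
acceptance; chains initialised from the prior at points of finite
posterior density), since the replay likelihood is not assumed
differentiable. Posterior summaries (mean, std, mcse, ess_bulk, ess_tail,
rhat, quantiles) and PSIS-LOO are delegated to ArviZ. When α is the only
free parameter the action marginals are independent of it, so they are
precomputed once per subject and every posterior evaluation is closed
form; this equals the full replay likelihood to machine precision (tested).

### Identifiability caveat

Under the default T-maze settings (γ = α = 16, preference strength 3) the
simulated agent's action marginals are one-hot to ~1e-7 at almost every
step — once settled, alternatives are ~e^(−γ·ΔG) with ΔG ≈ 2.6 nats — and
the only non-degenerate steps are exact ties between the two (initially
symmetric) arms, which carry no information about α. The replay
log-likelihood is therefore essentially flat in α for α ≳ 2, and per-subject
posteriors reproduce the prior. Group-level recovery of α from this task at
these settings is structurally impossible, not a sampler failure: the
recovery study in the test suite accordingly documents this expectation
(the group-separation assertions fail while all convergence diagnostics
pass). α recovery is meaningful in tasks/settings where agents face
repeated non-trivial choices with moderate marginals (e.g. lower γ, weaker
preferences, or environments with recurring decision points).

## Problem sizes

The shipped simulations use 300-step episodes for learning results, 200
episodes for behaviour frequencies, 500–1000 random models for the
inference and planning identity checks, and a 3+3-agent, 100-step,
2-chain × 1000-draw configuration for the recovery study; these sizes keep
Monte-Carlo error comfortably inside the asserted tolerances.

## Known limitations

- Policy roll-outs are not "sophisticated": information gained at future
  steps does not inform predicted future choices within a roll-out.
- Learning is implemented for A, B and D only; E and γ are fixed.
- A is not action-dependent; state spaces are discrete and flat (no
  hierarchy or temporal depth beyond the policy horizon).
- Per-subject fits are independent; there is no hierarchical pooling.
- The synthetic T-maze data are cleaner than real behaviour (no lapses,
  no drift in hyper-parameters, a perfectly valid cue by default), so
  passing recovery-style checks here does not by itself establish
  identifiability in empirical data.
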