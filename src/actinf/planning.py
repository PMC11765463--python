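"""Policy evaluation by expected free energy and precision-weighted action selection.

Each policy pi (a fixed-length sequence of per-factor actions) is scored by
its expected free energy

    G(pi) = - information gain - pragmatic value - parameter novelty,

summed over the planning roll-out, where the information gain is the mutual
information between hidden states and predicted observations, the pragmatic
value is the expected log-preference E_q(o|pi)[ln p(o|C)], and the optional
parameter-novelty term rewards visiting (o, s) cells whose Dirichlet counts
are still small. An algebraically equivalent decomposition,

    G(pi) = expected ambiguity + risk,

(expected conditional observation entropy plus the KL divergence of
predicted from preferred observations) is computed alongside and reported.

Policies with lower G are preferred: the policy posterior is
q(pi) = softmax(ln E - gamma * G) with policy precision gamma and habit
prior E. Marginalising the first step of q(pi) gives per-factor action
probabilities, from which actions are sampled as p(u)^alpha (softmax of
alpha * ln p) with action precision alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import PROB_FLOOR, DirichletCounts
from .perception import softmax, transition_prior

__all__ = [
    "Hyperparameters",
    "PlanningSettings",
    "EFEResult",
    "expected_states",
    "expected_observations",
    "state_info_gain",
    "pragmatic_value",
    "param_info_gain",
    "expected_free_energy",
    "policy_posterior",
    "marginal_action_probabilities",
    "action_distribution",
    "sample_action",
]


def _flog(x):
    return np.log(np.maximum(x, PROB_FLOOR))


@dataclass
class Hyperparameters:
    """Inference-algorithm hyper-parameters (not part of the generative model).

    gamma : policy precision — inverse temperature of the softmax over
        expected free energies (default 16).
    alpha : action precision — inverse temperature of the softmax over
        marginal action probabilities (default 16); higher values give more
        deterministic action selection.
    eta_A / eta_B / eta_D : Dirichlet learning rates in (0, 1].
    omega : forgetting rate in (0, 1]; 1 means counts are never discounted.
    """

    gamma: float = 16.0
    alpha: float = 16.0
    eta_A: float = 1.0
    eta_B: float = 1.0
    eta_D: float = 1.0
    omega: float = 1.0

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        for name in ("eta_A", "eta_B", "eta_D", "omega"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")


@dataclass
class PlanningSettings:
    """Which expected-free-energy terms to use and what is being learned.

    ``learned_modalities`` / ``learned_factors_B`` / ``learned_factors_D``
    are 1-based indices restricting Dirichlet learning (and parameter
    novelty) to a subset of modalities/factors; empty means all of those
    for which counts exist.
    """

    policy_length: int = 1
    use_state_info_gain: bool = True
    use_param_info_gain: bool = False
    learned_modalities: tuple[int, ...] = ()
    learned_factors_B: tuple[int, ...] = ()
    learned_factors_D: tuple[int, ...] = ()

    def __post_init__(self):
        if self.policy_length < 1:
            raise ValueError("policy_length must be >= 1")


@dataclass
class EFEResult:
    """Expected free energy of one policy and its decompositions."""

    G: float
    info_gain: float
    pragmatic_value: float
    param_info_gain: float
    risk: float
    ambiguity: float
    predicted_states: list  # per roll-out step: per-factor state distributions
    predicted_obs: list  # per roll-out step: per-modality observation distributions


def expected_states(B, current, policy) -> list[list[np.ndarray]]:
    """Roll the beliefs forward under a policy's action sequence."""
    out = []
    q = current
    for step in np.asarray(policy):
        q = transition_prior(B, q, step)
        out.append(q)
    return out


def expected_observations(A, q) -> list[np.ndarray]:
    """Predicted observation distribution per modality, q(o) = E_q(s)[p(o|s)]."""
    out = []
    for A_m in A:
        x = A_m
        for f in range(len(q) - 1, -1, -1):
            x = np.tensordot(x, q[f], axes=([1 + f], [0]))
        s = x.sum()
        out.append(x / s if s > 0 else x)
    return out


def state_info_gain(A, q, q_obs=None) -> float:
    """Mutual information between hidden states and observations, summed
    over modalities: H[q(o)] - E_q(s) H[p(o|s)]. Non-negative; zero when
    observations carry no information about states under q."""
    total = 0.0
    if q_obs is None:
        q_obs = expected_observations(A, q)
    for A_m, qo in zip(A, q_obs):
        H_marginal = -float(qo @ _flog(qo))
        H_cond = -(A_m * _flog(A_m)).sum(axis=0)  # entropy per state combination
        x = H_cond
        for f in range(len(q) - 1, -1, -1):
            x = np.tensordot(x, q[f], axes=([f], [0]))
        total += H_marginal - float(x)
    return total


def pragmatic_value(q_obs, C) -> float:
    """Expected log-preference E_q(o)[ln p(o|C)], summed over modalities.

    C holds unnormalised log-preferences; it is softmax-normalised here.
    """
    total = 0.0
    for qo, C_m in zip(q_obs, C):
        total += float(qo @ _flog(softmax(C_m)))
    return total


def _ambiguity(A, q) -> float:
    """Expected conditional entropy E_q(s) H[p(o|s)], summed over modalities."""
    total = 0.0
    for A_m in A:
        H_cond = -(A_m * _flog(A_m)).sum(axis=0)
        x = H_cond
        for f in range(len(q) - 1, -1, -1):
            x = np.tensordot(x, q[f], axes=([f], [0]))
        total += float(x)
    return total


def _risk(q_obs, C) -> float:
    """KL divergence of predicted from preferred observations."""
    total = 0.0
    for qo, C_m in zip(q_obs, C):
        total += float(qo @ (_flog(qo) - _flog(softmax(C_m))))
    return total


def param_info_gain(counts_A, q, q_obs, learned_modalities) -> float:
    """Dirichlet novelty of the A-counts expected under the predicted
    (observation, state) distribution.

    For each learned modality the cell weight is
    w(o, s) = 1/2 * (1/theta(o, s) - 1/sum_o' theta(o', s)), which is
    non-negative and vanishes as the counts grow (nothing left to learn);
    the expectation is taken under the mean-field product q(o) * prod_f q(s^f).
    """
    if counts_A is None:
        return 0.0
    total = 0.0
    for m in learned_modalities:
        theta = counts_A[m - 1]
        col = theta.sum(axis=0, keepdims=True)
        if np.any(col <= 0):
            raise ValueError(f"degenerate counts in modality {m}: a column sums to zero")
        w = 0.5 * (1.0 / np.maximum(theta, PROB_FLOOR) - 1.0 / col)
        w = w * (theta > 0)  # cells with zero counts carry no mass to visit
        x = w
        for f in range(len(q) - 1, -1, -1):
            x = np.tensordot(x, q[f], axes=([1 + f], [0]))
        total += float(q_obs[m - 1] @ x)
    return total


def expected_free_energy(
    A,
    B,
    C,
    current,
    policy,
    settings: PlanningSettings,
    counts_A=None,
) -> EFEResult:
    """Score one policy: roll out beliefs, accumulate the EFE terms per step."""
    ig = pv = pig = risk = amb = 0.0
    qs_steps = expected_states(B, current, policy)
    qo_steps = []
    for qs in qs_steps:
        qo = expected_observations(A, qs)
        qo_steps.append(qo)
        if settings.use_state_info_gain:
            ig += state_info_gain(A, qs, qo)
        pv += pragmatic_value(qo, C)
        if settings.use_param_info_gain and counts_A is not None:
            pig += param_info_gain(counts_A, qs, qo, settings.learned_modalities)
        risk += _risk(qo, C)
        amb += _ambiguity(A, qs)
    G = -ig - pv - pig
    return EFEResult(
        G=G,
        info_gain=ig,
        pragmatic_value=pv,
        param_info_gain=pig,
        risk=risk,
        ambiguity=amb,
        predicted_states=qs_steps,
        predicted_obs=qo_steps,
    )


def policy_posterior(G, E, gamma: float) -> np.ndarray:
    """q(pi) = softmax(ln E - gamma * G); gamma = 0 recovers the habit prior."""
    G = np.asarray(G, dtype=float)
    E = np.asarray(E, dtype=float)
    if G.shape != E.shape:
        raise ValueError("G and E must have the same length")
    return softmax(_flog(E) - gamma * G)


def marginal_action_probabilities(q_pi, policies, num_controls) -> list[np.ndarray]:
    """Marginalise the policy posterior onto first-step actions, per factor."""
    q_pi = np.asarray(q_pi, dtype=float)
    out = []
    for f, nc in enumerate(num_controls):
        p = np.zeros(nc)
        for qp, pol in zip(q_pi, policies):
            p[int(pol[0][f]) - 1] += qp
        out.append(p / p.sum())
    return out


def action_distribution(action_probs, alpha: float) -> list[np.ndarray]:
    """Per-factor sampling distribution softmax(alpha * ln p), i.e. p^alpha."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    return [softmax(alpha * _flog(p)) for p in action_probs]


def sample_action(action_probs, alpha: float, rng: np.random.Generator) -> tuple[int, ...]:
    """Sample one 1-based action index per factor from p(u)^alpha."""
    dists = action_distribution(action_probs, alpha)
    return tuple(int(rng.choice(len(d), p=d)) + 1 for d in dists)
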