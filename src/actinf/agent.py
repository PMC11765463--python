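"""The action–perception loop: an agent bundling model, beliefs and settings.

An :class:`Agent` holds the generative-model components, optional Dirichlet
counts, the current beliefs and the algorithmic settings, and exposes the
per-step cycle

    infer states  ->  update Dirichlet parameters  ->  infer policies
                  ->  marginalise and sample an action,

recording histories of observations, beliefs, free energies, policy
posteriors and actions as it goes.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import learning
from .model import (
    DirichletCounts,
    ModelShape,
    construct_policies,
    dirichlet_expected,
    normalize_columns,
    validate_model,
)
from .perception import InferenceSettings, infer_states, transition_prior
from .planning import (
    EFEResult,
    Hyperparameters,
    PlanningSettings,
    action_distribution,
    expected_free_energy,
    marginal_action_probabilities,
    policy_posterior,
    sample_action,
)

__all__ = ["Agent", "init_agent"]


class Agent:
    """Discrete-state-space active inference agent.

    ``A`` and ``B`` are mandatory; omitted ``C``/``D``/``E`` default to
    neutral/uniform priors. If Dirichlet counts are supplied for a
    component, the expected (count-normalised) component is used for
    inference and updated online; learning can be restricted to a subset of
    modalities/factors through :class:`~actinf.planning.PlanningSettings`.
    """

    def __init__(
        self,
        A,
        B,
        C=None,
        D=None,
        E=None,
        counts_A=None,
        counts_B=None,
        counts_D=None,
        hyper: Hyperparameters | None = None,
        planning: PlanningSettings | None = None,
        inference: InferenceSettings | None = None,
    ):
        num_obs = tuple(a.shape[0] for a in A)
        num_states = tuple(b.shape[0] for b in B)
        num_controls = tuple(b.shape[2] for b in B)
        self.planning = planning or PlanningSettings()
        self.hyper = hyper or Hyperparameters()
        self.inference = inference or InferenceSettings()
        self.shape = ModelShape(
            num_obs=num_obs,
            num_states=num_states,
            num_controls=num_controls,
            policy_length=self.planning.policy_length,
        )
        if C is None:
            C = [np.zeros(no) for no in num_obs]
        if D is None:
            D = [np.full(ns, 1.0 / ns) for ns in num_states]
        self.policies = construct_policies(num_controls, self.planning.policy_length)
        if E is None:
            E = np.full(len(self.policies), 1.0 / len(self.policies))
        violations = validate_model(A, B, C, D, E, self.shape)
        if violations:
            raise ValueError("invalid model: " + "; ".join(violations))

        self.A = [a.copy() for a in A]
        self.B = [b.copy() for b in B]
        self.C = [c.copy() for c in C]
        self.D = [d.copy() for d in D]
        self.E = np.asarray(E, dtype=float).copy()
        self.counts = DirichletCounts(
            A=None if counts_A is None else [c.copy() for c in counts_A],
            B=None if counts_B is None else [c.copy() for c in counts_B],
            D=None if counts_D is None else [c.copy() for c in counts_D],
        )
        if self.counts.A is not None and not self.planning.learned_modalities:
            self.planning.learned_modalities = tuple(range(1, len(A) + 1))
        if self.counts.B is not None and not self.planning.learned_factors_B:
            self.planning.learned_factors_B = tuple(range(1, len(B) + 1))
        if self.counts.D is not None and not self.planning.learned_factors_D:
            self.planning.learned_factors_D = tuple(range(1, len(D) + 1))
        self._refresh_expected()
        self.reset()

    # ------------------------------------------------------------------ state

    def reset(self) -> None:
        """Clear beliefs and histories; the next step is the first time step."""
        self.qs = None  # current per-factor posterior
        self._q_prev = None
        self.prev_action = None
        self.q_pi = None
        self.t = 0
        self.obs_history: list[tuple[int, ...]] = []
        self.belief_history: list[list[np.ndarray]] = []
        self.action_history: list[tuple[int, ...]] = []
        self.fe_history: list[float] = []
        self.q_pi_history: list[np.ndarray] = []
        self._pending_marginals = None

    def _refresh_expected(self) -> None:
        """Recompute the expected A/B/D from counts where learning is on."""
        if self.counts.A is not None:
            for m in self.planning.learned_modalities:
                self.A[m - 1] = normalize_columns(self.counts.A[m - 1])
        if self.counts.B is not None:
            for f in self.planning.learned_factors_B:
                self.B[f - 1] = normalize_columns(self.counts.B[f - 1])
        if self.counts.D is not None:
            for f in self.planning.learned_factors_D:
                d = self.counts.D[f - 1]
                self.D[f - 1] = d / d.sum()

    # ------------------------------------------------------------ one cycle

    def infer(self, obs) -> list[np.ndarray]:
        """State inference for one observation; returns the posterior."""
        if self.qs is None or self.prev_action is None:
            prior = [d.copy() for d in self.D]
        else:
            prior = transition_prior(self.B, self.qs, self.prev_action)
        q, F = infer_states(self.A, prior, obs, self.inference)
        self._q_prev = self.qs
        self.qs = q
        self.t += 1
        self.obs_history.append(tuple(int(o) for o in obs))
        self.belief_history.append([x.copy() for x in q])
        self.fe_history.append(F)
        return q

    def learn(self, obs) -> None:
        """Dirichlet updates for A (always), B (from the second step) and D
        (first step only), where counts are present."""
        h = self.hyper
        p = self.planning
        if self.counts.A is not None:
            self.counts.A = learning.update_A_counts(
                self.counts.A, obs, self.qs, h.eta_A, h.omega, p.learned_modalities
            )
        if self.counts.B is not None and self._q_prev is not None and self.prev_action is not None:
            self.counts.B = learning.update_B_counts(
                self.counts.B, self.qs, self._q_prev, self.prev_action,
                h.eta_B, h.omega, p.learned_factors_B,
            )
        if self.counts.D is not None and self.t == 1:
            self.counts.D = learning.update_D_counts(
                self.counts.D, self.qs, h.eta_D, h.omega, p.learned_factors_D
            )
        self._refresh_expected()

    def infer_policies(self) -> tuple[np.ndarray, np.ndarray]:
        """Expected free energy for every policy and the policy posterior."""
        G = np.array(
            [
                expected_free_energy(
                    self.A, self.B, self.C, self.qs, pol, self.planning, self.counts.A
                ).G
                for pol in self.policies
            ]
        )
        self.q_pi = policy_posterior(G, self.E, self.hyper.gamma)
        self.G = G
        return G, self.q_pi

    def action_marginals(self, obs) -> list[np.ndarray]:
        """Run inference, learning and policy evaluation for one observation
        and return the per-factor marginal probabilities of the next action
        (before the action-precision softmax)."""
        self.infer(obs)
        self.learn(obs)
        self.infer_policies()
        marginals = marginal_action_probabilities(
            self.q_pi, self.policies, self.shape.num_controls
        )
        self._pending_marginals = marginals
        return marginals

    def commit_action(self, action) -> None:
        """Record ``action`` (1-based per-factor indices) as the action taken."""
        action = tuple(int(u) for u in action)
        for f, (u, nc) in enumerate(zip(action, self.shape.num_controls)):
            if not 1 <= u <= nc:
                raise IndexError(f"action {u} out of range 1..{nc} in factor {f + 1}")
        self.prev_action = action
        self.action_history.append(action)
        self.q_pi_history.append(self.q_pi.copy())
        self._pending_marginals = None

    def step(self, obs, rng: np.random.Generator):
        """Full cycle: perceive, learn, plan, sample and commit an action."""
        marginals = self.action_marginals(obs)
        action = sample_action(marginals, self.hyper.alpha, rng)
        self.commit_action(action)
        return action

    # ------------------------------------------------------------- accessors

    _PARAMS = ("gamma", "alpha", "eta_A", "eta_B", "eta_D", "omega")

    def get_parameter(self, name: str) -> float:
        if name not in self._PARAMS:
            raise KeyError(f"unknown parameter {name!r}; known: {self._PARAMS}")
        return getattr(self.hyper, name)

    def set_parameter(self, name: str, value: float) -> None:
        """Set a hyper-parameter; the value is re-validated."""
        if name not in self._PARAMS:
            raise KeyError(f"unknown parameter {name!r}; known: {self._PARAMS}")
        kwargs = {p: getattr(self.hyper, p) for p in self._PARAMS}
        kwargs[name] = float(value)
        self.hyper = Hyperparameters(**kwargs)  # re-runs validation

    def copy(self) -> "Agent":
        return copy.deepcopy(self)


def init_agent(A, B, C=None, D=None, E=None, counts_A=None, counts_B=None,
               counts_D=None, hyper=None, planning=None, inference=None) -> Agent:
    """Construct an :class:`Agent`; A and B are the only mandatory arguments."""
    return Agent(A, B, C=C, D=D, E=E, counts_A=counts_A, counts_B=counts_B,
                 counts_D=counts_D, hyper=hyper, planning=planning, inference=inference)
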