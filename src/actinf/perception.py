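"""State inference by minimising the time-specific variational free energy.

Perception is cast as variational Bayesian inference: given an observation
``o_t`` and a predictive prior p(s_t | s_{t-1}, u_{t-1}), the agent finds an
approximate posterior q(s_t) minimising the variational free energy

    F_t = E_q[ ln q(s_t) - ln p(o_t | s_t) - ln p(s_t | s_{t-1}, u_{t-1}) ],

an upper bound on the surprise -ln p(o_t). Under a mean-field factorisation
q(s_t) = prod_f q(s_t^f) over hidden-state factors, the coordinate-ascent
(fixed-point iteration, FPI) update for one factor is

    q*(s_t^f) = softmax( E_{q over other factors}[ ln p(o_t | s_t) ] + ln prior_f ),

iterated over factors until the change in F_t falls below a tolerance or a
maximum number of sweeps is reached. For a single-factor model one sweep
recovers exact Bayes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import PROB_FLOOR

__all__ = [
    "InferenceSettings",
    "joint_log_likelihood",
    "transition_prior",
    "free_energy",
    "free_energy_parts",
    "infer_states",
    "softmax",
]


@dataclass(frozen=True)
class InferenceSettings:
    """FPI stopping rule: at most ``max_iterations`` sweeps, or stop when
    the change in F_t drops below ``tolerance``."""

    max_iterations: int = 10
    tolerance: float = 0.001

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


def softmax(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    e = np.exp(x - x.max())
    return e / e.sum()


def _flog(x: np.ndarray) -> np.ndarray:
    """Log with the probability floor applied first."""
    return np.log(np.maximum(x, PROB_FLOOR))


def joint_log_likelihood(A, obs) -> np.ndarray:
    """ln p(o_t | s_t) over the full state space.

    Modalities are conditionally independent given the full state
    combination, so their log-likelihoods sum. ``obs`` is a sequence of
    1-based category indices, one per modality. Probabilities are floored
    at 1e-16 before taking logs.
    """
    num_states = A[0].shape[1:]
    ll = np.zeros(num_states)
    for m, A_m in enumerate(A):
        o = int(obs[m])
        if not 1 <= o <= A_m.shape[0]:
            raise IndexError(f"observation {o} out of range 1..{A_m.shape[0]} in modality {m + 1}")
        ll += _flog(A_m[o - 1])
    return ll


def transition_prior(B, previous, action) -> list[np.ndarray]:
    """Predictive prior p(s_t | s_{t-1}, u_{t-1}) per factor.

    ``previous`` is the per-factor posterior from the last step; ``action``
    holds one 1-based action index per factor. At the first time step the
    caller uses the state prior D instead.
    """
    prior = []
    for f, B_f in enumerate(B):
        u = int(action[f])
        if not 1 <= u <= B_f.shape[2]:
            raise IndexError(f"action {u} out of range 1..{B_f.shape[2]} in factor {f + 1}")
        prior.append(B_f[:, :, u - 1] @ previous[f])
    return prior


def _marginal_loglik(loglik: np.ndarray, q: list[np.ndarray], f: int) -> np.ndarray:
    """E over q of all factors except ``f`` of ln p(o|s), a vector over factor f."""
    out = loglik
    # contract from the highest axis down so earlier axis indices stay valid
    for g in range(len(q) - 1, -1, -1):
        if g == f:
            continue
        out = np.tensordot(out, q[g], axes=([g], [0]))
    return out


def _joint_expectation(loglik: np.ndarray, q: list[np.ndarray]) -> float:
    out = loglik
    for g in range(len(q) - 1, -1, -1):
        out = np.tensordot(out, q[g], axes=([g], [0]))
    return float(out)


def free_energy(q, prior, loglik) -> float:
    """Time-specific variational free energy under the mean-field posterior."""
    F, _, _ = free_energy_parts(q, prior, loglik)
    return F


def free_energy_parts(q, prior, loglik) -> tuple[float, float, float]:
    """Return ``(F, complexity, accuracy)``.

    accuracy = E_q[ln p(o|s)]; complexity = sum_f KL(q_f || prior_f);
    F = complexity - accuracy.
    """
    accuracy = _joint_expectation(loglik, q)
    complexity = 0.0
    for qf, pf in zip(q, prior):
        complexity += float(qf @ (_flog(qf) - _flog(pf)))
    return complexity - accuracy, complexity, accuracy


def infer_states(A, prior, obs, settings: InferenceSettings = InferenceSettings(),
                 return_history: bool = False):
    """Posterior beliefs over hidden states given one observation.

    Runs fixed-point iteration on the mean-field posterior, initialised at
    the predictive ``prior`` (so a single-factor model converges in one
    sweep), sweeping factors in ascending order. Returns ``(q, F)`` where
    ``q`` is the list of per-factor posteriors and ``F`` the variational
    free energy at the fixed point.

    If the observation has zero probability under every state combination
    (before flooring), inference degenerates to the prior and a warning is
    issued.
    """
    loglik = joint_log_likelihood(A, obs)

    # degenerate-likelihood check on the unfloored product
    lik = np.ones(loglik.shape)
    for m, A_m in enumerate(A):
        lik = lik * A_m[int(obs[m]) - 1]
    if lik.max() == 0.0:
        warnings.warn(
            "observation has zero likelihood under all states; posterior falls back to the prior",
            RuntimeWarning,
        )
        q = [pf / pf.sum() for pf in prior]
        F = free_energy(q, prior, loglik)
        return (q, F, [F]) if return_history else (q, F)

    ln_prior = [_flog(pf) for pf in prior]
    q = [np.maximum(pf, 0) / np.maximum(pf, 0).sum() for pf in prior]
    F = free_energy(q, prior, loglik)
    history = [F]
    for _ in range(settings.max_iterations):
        for f in range(len(q)):
            q[f] = softmax(_marginal_loglik(loglik, q, f) + ln_prior[f])
        F_new = free_energy(q, prior, loglik)
        history.append(F_new)
        dF, F = F - F_new, F_new
        if abs(dF) < settings.tolerance:
            break
    return (q, F, history) if return_history else (q, F)
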