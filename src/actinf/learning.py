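"""Dirichlet concentration-parameter learning for A, B and D.

Each update follows the discounted-count rule

    theta_{t+1} = omega * theta_t + eta * chi_t

where ``chi_t`` is the observed-data count realised as an outer product:
for the observation model A, the observation one-hot with the joint
(product-of-factors) state posterior; for the transition model B, the outer
product of the current and previous per-factor posteriors in the slice of
the action taken; for the state prior D, the first-step posterior itself.
``eta`` is the learning rate and ``omega`` the forgetting rate; with
omega = 1 counts only ever grow, and with eta = omega = 1 each A-update
adds exactly unit mass per learned modality.

When ``omega < 1`` the discount is applied to the entire learned component
(all rows of every learned modality/factor), not only the updated cells.
"""

from __future__ import annotations

from functools import reduce

import numpy as np

__all__ = ["update_A_counts", "update_B_counts", "update_D_counts", "joint_belief"]


def joint_belief(q) -> np.ndarray:
    """Product-of-factors joint posterior over the full state space."""
    return reduce(np.multiply.outer, q)


def _check_rates(eta: float, omega: float) -> None:
    if not 0 < eta <= 1:
        raise ValueError(f"learning rate eta must lie in (0, 1], got {eta}")
    if not 0 <= omega <= 1:
        raise ValueError(f"forgetting rate omega must lie in [0, 1], got {omega}")


def update_A_counts(counts_A, obs, q, eta=1.0, omega=1.0, learned_modalities=None):
    """Update observation-model counts from one observation and the state
    posterior that generated it.

    ``learned_modalities`` holds 1-based modality indices (default: all).
    Returns a new list of count tensors; the input is not modified.
    """
    _check_rates(eta, omega)
    if learned_modalities is None:
        learned_modalities = range(1, len(counts_A) + 1)
    learned = set(int(m) for m in learned_modalities)
    chi = joint_belief(q)
    out = []
    for m, theta in enumerate(counts_A, start=1):
        if m in learned:
            o = int(obs[m - 1])
            if not 1 <= o <= theta.shape[0]:
                raise IndexError(f"observation {o} out of range in modality {m}")
            new = omega * theta
            new[o - 1] += eta * chi
        else:
            new = omega * theta if omega < 1 else theta.copy()
        out.append(new)
    return out


def update_B_counts(counts_B, q_now, q_prev, action, eta=1.0, omega=1.0, learned_factors=None):
    """Update transition-model counts from the inferred state transition
    under the action taken (1-based per-factor indices)."""
    _check_rates(eta, omega)
    if learned_factors is None:
        learned_factors = range(1, len(counts_B) + 1)
    learned = set(int(f) for f in learned_factors)
    out = []
    for f, theta in enumerate(counts_B, start=1):
        if f in learned:
            u = int(action[f - 1])
            if not 1 <= u <= theta.shape[2]:
                raise IndexError(f"action {u} out of range in factor {f}")
            new = omega * theta
            new[:, :, u - 1] += eta * np.outer(q_now[f - 1], q_prev[f - 1])
        else:
            new = omega * theta if omega < 1 else theta.copy()
        out.append(new)
    return out


def update_D_counts(counts_D, q_first, eta=1.0, omega=1.0, learned_factors=None):
    """Update state-prior counts from the posterior at the first time step."""
    _check_rates(eta, omega)
    if learned_factors is None:
        learned_factors = range(1, len(counts_D) + 1)
    learned = set(int(f) for f in learned_factors)
    out = []
    for f, theta in enumerate(counts_D, start=1):
        if f in learned:
            new = omega * theta + eta * q_first[f - 1]
        else:
            new = omega * theta if omega < 1 else theta.copy()
        out.append(new)
    return out
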