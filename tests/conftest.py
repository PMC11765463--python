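"""Shared fixtures: random model generators and exact-enumeration oracles."""

import numpy as np
import pytest

from actinf.model import ModelShape, create_templates


def random_categorical(rng, n):
    x = rng.random(n) + 1e-3
    return x / x.sum()


def random_model(rng, num_obs, num_states, num_controls=None, policy_length=1):
    """Random column-stochastic A/B, random C (log-preferences), random D,
    uniform E, for arbitrary factor/modality structure."""
    if num_controls is None:
        num_controls = [1] * len(num_states)
    shape = ModelShape(
        num_obs=tuple(num_obs),
        num_states=tuple(num_states),
        num_controls=tuple(num_controls),
        policy_length=policy_length,
    )
    A, B, C, D, E = create_templates(shape, fill="zeros")
    for m in range(len(A)):
        flat = A[m].reshape(A[m].shape[0], -1)
        for j in range(flat.shape[1]):
            flat[:, j] = random_categorical(rng, flat.shape[0])
    for f in range(len(B)):
        for u in range(B[f].shape[2]):
            for j in range(B[f].shape[1]):
                B[f][:, j, u] = random_categorical(rng, B[f].shape[0])
    C = [rng.normal(size=no) for no in num_obs]
    D = [random_categorical(rng, ns) for ns in num_states]
    E = np.full(len(E), 1.0 / len(E)) if len(E) else E
    return A, B, C, D, E, shape


def exact_posterior(A, prior, obs):
    """Brute-force Bayes over the full (joint) state space.

    Returns the joint posterior tensor and the model evidence p(o).
    """
    from functools import reduce

    joint_prior = reduce(np.multiply.outer, prior)
    lik = np.ones(joint_prior.shape)
    for m, A_m in enumerate(A):
        lik = lik * A_m[int(obs[m]) - 1]
    joint = lik * joint_prior
    evidence = joint.sum()
    return joint / evidence, evidence


def brute_force_vfe(q, prior, A, obs, floor=1e-16):
    """Direct evaluation of F = sum_s q(s) [ln q(s) - ln p(o, s)] by
    enumerating the joint state space under the mean-field product q."""
    from functools import reduce

    qj = reduce(np.multiply.outer, q)
    pj = reduce(np.multiply.outer, prior)
    lik = np.ones(qj.shape)
    for m, A_m in enumerate(A):
        lik = lik * np.maximum(A_m[int(obs[m]) - 1], floor)
    ln_joint = np.log(lik) + np.log(np.maximum(pj, floor))
    mask = qj > 0
    return float((qj[mask] * (np.log(np.maximum(qj, floor))[mask] - ln_joint[mask])).sum())


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
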