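"""Generative-model components for discrete state-space (POMDP) active inference.

A POMDP generative model is specified by five sets of parameters:

* ``A`` — the observation model: one tensor per observation modality ``m`` of
  shape ``(num_obs[m], *num_states)``, each column (fixed state combination)
  a categorical distribution over observations, p(o | s).
* ``B`` — the transition model: one tensor per hidden-state factor ``f`` of
  shape ``(num_states[f], num_states[f], num_controls[f])``; slice
  ``B[:, j, u]`` is the distribution over next states given previous state
  ``j`` and action ``u``, p(s_t | s_{t-1}, u_{t-1}).
* ``C`` — the preference prior: one vector per modality of *unnormalised
  log-preferences* over observations (0 = neutral); it is passed through a
  softmax only inside pragmatic-value / risk computations.
* ``D`` — the state prior: one probability vector per factor, the belief
  about the initial hidden state.
* ``E`` — the habit prior: a single probability vector over policies.

Beliefs about A, B and D can themselves be uncertain, represented by
Dirichlet concentration parameters (pseudo-counts) of the same shapes; their
normalised means give the expected model used for inference.

All user-facing category and action indices are 1-based (matching the
behavioural data tables this package reads and writes); numpy array storage
is 0-based with conversion at the indexing site.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "ModelShape",
    "DirichletCounts",
    "create_templates",
    "onehot",
    "construct_policies",
    "num_policies",
    "validate_model",
    "dirichlet_expected",
    "normalize_columns",
    "save_model",
    "load_model",
]

#: probability floor applied before every logarithm
PROB_FLOOR = 1e-16

STOCH_TOL = 1e-10


@dataclass(frozen=True)
class ModelShape:
    """Dimensions of a multi-factor, multi-modality POMDP.

    Parameters
    ----------
    num_obs
        Number of observation categories per modality.
    num_states
        Number of hidden states per factor.
    num_controls
        Number of allowable actions per factor; an uncontrollable factor
        has entry 1.
    policy_length
        Temporal depth of planning (length of each policy).
    """

    num_obs: tuple[int, ...]
    num_states: tuple[int, ...]
    num_controls: tuple[int, ...]
    policy_length: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "num_obs", tuple(int(n) for n in self.num_obs))
        object.__setattr__(self, "num_states", tuple(int(n) for n in self.num_states))
        object.__setattr__(self, "num_controls", tuple(int(n) for n in self.num_controls))
        for name in ("num_obs", "num_states", "num_controls"):
            vals = getattr(self, name)
            if len(vals) == 0 or any(n < 1 for n in vals):
                raise ValueError(f"{name} must be non-empty with all entries >= 1, got {vals}")
        if len(self.num_controls) != len(self.num_states):
            raise ValueError("num_controls must have one entry per state factor")
        if self.policy_length < 1:
            raise ValueError("policy_length must be >= 1")

    @property
    def num_modalities(self) -> int:
        return len(self.num_obs)

    @property
    def num_factors(self) -> int:
        return len(self.num_states)

    @property
    def controllable_factors(self) -> tuple[int, ...]:
        """0-based indices of factors with more than one allowable action."""
        return tuple(f for f, nc in enumerate(self.num_controls) if nc > 1)


@dataclass
class DirichletCounts:
    """Dirichlet concentration parameters (pseudo-counts) over A, B and D.

    Any of the three blocks may be ``None``, meaning the corresponding model
    component is treated as known (not learned). Counts act like occurrence
    counts: their column-normalised means give the expected categorical
    model, and their overall scale sets the prior precision of the belief.
    """

    A: list[np.ndarray] | None = None
    B: list[np.ndarray] | None = None
    D: list[np.ndarray] | None = None

    def copy(self) -> "DirichletCounts":
        cp = lambda block: None if block is None else [x.copy() for x in block]
        return DirichletCounts(A=cp(self.A), B=cp(self.B), D=cp(self.D))


def onehot(index: int, length: int) -> np.ndarray:
    """Probability vector with all mass on category ``index`` (1-based)."""
    if not 1 <= index <= length:
        raise IndexError(f"onehot index {index} out of range 1..{length}")
    v = np.zeros(length)
    v[index - 1] = 1.0
    return v


def num_policies(shape: ModelShape) -> int:
    """Closed-form policy count: (prod_f num_controls[f]) ** policy_length."""
    per_step = int(np.prod(shape.num_controls))
    return per_step ** shape.policy_length


def create_templates(shape: ModelShape, fill: str = "uniform"):
    """Build A, B, C, D, E tensors of the correct dimensions.

    ``fill='uniform'`` gives column-stochastic tensors (uniform categorical
    distributions) and uniform D/E; ``fill='zeros'`` gives all-zero tensors
    that the caller populates by hand. C is always returned as neutral
    (all-zero) log-preferences.
    """
    if fill not in ("uniform", "zeros"):
        raise ValueError(f"fill must be 'uniform' or 'zeros', got {fill!r}")
    A = []
    for no in shape.num_obs:
        t = np.zeros((no, *shape.num_states))
        if fill == "uniform":
            t += 1.0 / no
        A.append(t)
    B = []
    for ns, nc in zip(shape.num_states, shape.num_controls):
        t = np.zeros((ns, ns, nc))
        if fill == "uniform":
            t += 1.0 / ns
        B.append(t)
    C = [np.zeros(no) for no in shape.num_obs]
    if fill == "uniform":
        D = [np.full(ns, 1.0 / ns) for ns in shape.num_states]
        E = np.full(num_policies(shape), 1.0 / num_policies(shape))
    else:
        D = [np.zeros(ns) for ns in shape.num_states]
        E = np.zeros(num_policies(shape))
    return A, B, C, D, E


def construct_policies(num_controls: Sequence[int], policy_length: int) -> list[np.ndarray]:
    """Exhaustively enumerate all policies.

    A policy is a ``(policy_length, num_factors)`` integer array of 1-based
    action indices. Enumeration is lexicographic over (time step, factor,
    action index), so the ordering is reproducible across runs.
    """
    if policy_length < 1:
        raise ValueError("policy_length must be >= 1")
    if any(nc < 1 for nc in num_controls):
        raise ValueError("num_controls entries must be >= 1")
    per_step = itertools.product(*(range(1, nc + 1) for nc in num_controls))
    return [
        np.array(p, dtype=int)
        for p in itertools.product(list(per_step), repeat=policy_length)
    ]


def _column_sums(tensor: np.ndarray) -> np.ndarray:
    """Sums over the leading (category) axis."""
    return tensor.sum(axis=0)


def validate_model(A, B, C, D, E, shape: ModelShape) -> list[str]:
    """Check shape and stochasticity invariants; return a list of violations.

    An empty list means the model is valid. Violations are human-readable
    strings naming the component, the offending slice and the failed
    constraint; nothing is raised.
    """
    v: list[str] = []
    if len(A) != shape.num_modalities:
        v.append(f"A: expected {shape.num_modalities} modalities, got {len(A)}")
    if len(B) != shape.num_factors:
        v.append(f"B: expected {shape.num_factors} factors, got {len(B)}")

    for m, A_m in enumerate(A):
        want = (shape.num_obs[m], *shape.num_states)
        if A_m.shape != want:
            v.append(f"A[modality {m + 1}]: shape {A_m.shape} != {want}")
            continue
        if np.any(A_m < 0):
            idx = np.argwhere(A_m < 0)[0]
            v.append(f"A[modality {m + 1}]: negative entry at index {tuple(idx + 1)}")
        sums = _column_sums(A_m)
        bad = np.argwhere(np.abs(sums - 1.0) > STOCH_TOL)
        if bad.size:
            s = tuple(bad[0] + 1)
            v.append(
                f"A[modality {m + 1}]: column for state combination {s} sums to "
                f"{sums[tuple(bad[0])]:.6g}, expected 1"
            )
    for f, B_f in enumerate(B):
        ns, nc = shape.num_states[f], shape.num_controls[f]
        want = (ns, ns, nc)
        if B_f.shape != want:
            v.append(f"B[factor {f + 1}]: shape {B_f.shape} != {want}")
            continue
        if np.any(B_f < 0):
            idx = np.argwhere(B_f < 0)[0]
            v.append(f"B[factor {f + 1}]: negative entry at index {tuple(idx + 1)}")
        sums = _column_sums(B_f)
        bad = np.argwhere(np.abs(sums - 1.0) > STOCH_TOL)
        if bad.size:
            j, u = bad[0]
            v.append(
                f"B[factor {f + 1}]: column (previous state {j + 1}, action {u + 1}) "
                f"sums to {sums[j, u]:.6g}, expected 1"
            )
    if len(C) != shape.num_modalities:
        v.append(f"C: expected {shape.num_modalities} modalities, got {len(C)}")
    else:
        for m, C_m in enumerate(C):
            if C_m.shape != (shape.num_obs[m],):
                v.append(f"C[modality {m + 1}]: shape {C_m.shape} != ({shape.num_obs[m]},)")
            elif not np.all(np.isfinite(C_m)):
                v.append(f"C[modality {m + 1}]: non-finite entries")
    if len(D) != shape.num_factors:
        v.append(f"D: expected {shape.num_factors} factors, got {len(D)}")
    else:
        for f, D_f in enumerate(D):
            if D_f.shape != (shape.num_states[f],):
                v.append(f"D[factor {f + 1}]: shape {D_f.shape} != ({shape.num_states[f]},)")
            elif np.any(D_f < 0) or abs(D_f.sum() - 1.0) > STOCH_TOL:
                v.append(f"D[factor {f + 1}]: not a probability vector (sum {D_f.sum():.6g})")
    n_pi = num_policies(shape)
    E = np.asarray(E)
    if E.shape != (n_pi,):
        v.append(f"E: shape {E.shape} != ({n_pi},)")
    elif np.any(E < 0) or abs(E.sum() - 1.0) > STOCH_TOL:
        v.append(f"E: not a probability vector (sum {E.sum():.6g})")
    return v


def normalize_columns(tensor: np.ndarray) -> np.ndarray:
    """Normalise each leading-axis column to sum to 1 (Dirichlet mean)."""
    sums = tensor.sum(axis=0, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("degenerate counts: a column sums to zero")
    return tensor / sums


def dirichlet_expected(counts: DirichletCounts):
    """Expected model under Dirichlet beliefs: column-normalised counts.

    Returns an ``(A, B, D)`` triple, with ``None`` in any slot whose counts
    block is absent.
    """
    A = None if counts.A is None else [normalize_columns(a) for a in counts.A]
    B = None if counts.B is None else [normalize_columns(b) for b in counts.B]
    D = None if counts.D is None else [d / d.sum() if d.sum() > 0 else _raise_deg() for d in counts.D]
    return A, B, D


def _raise_deg():
    raise ValueError("degenerate counts: a column sums to zero")


# ---------------------------------------------------------------------------
# plain-text (YAML) serialisation


def save_model(path, A, B, C, D, E, shape: ModelShape) -> None:
    """Serialise the five model components with explicit shape metadata."""
    doc = {
        "shape": {
            "num_obs": list(shape.num_obs),
            "num_states": list(shape.num_states),
            "num_controls": list(shape.num_controls),
            "policy_length": shape.policy_length,
        },
        "A": [a.tolist() for a in A],
        "B": [b.tolist() for b in B],
        "C": [c.tolist() for c in C],
        "D": [d.tolist() for d in D],
        "E": np.asarray(E).tolist(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, default_flow_style=None)


def load_model(path):
    """Load model components from YAML and re-validate them.

    Returns ``(A, B, C, D, E, shape)``. Raises ``ValueError`` listing all
    violations if validation fails.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    shape = ModelShape(**doc["shape"])
    A = [np.asarray(a, dtype=float) for a in doc["A"]]
    B = [np.asarray(b, dtype=float) for b in doc["B"]]
    C = [np.asarray(c, dtype=float) for c in doc["C"]]
    D = [np.asarray(d, dtype=float) for d in doc["D"]]
    E = np.asarray(doc["E"], dtype=float)
    violations = validate_model(A, B, C, D, E, shape)
    if violations:
        raise ValueError("invalid model: " + "; ".join(violations))
    return A, B, C, D, E, shape
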