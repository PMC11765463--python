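"""T-maze generative process and whole-dataset simulation.

The T-maze is a minimal explore–exploit task: a centre location, a cue
location at the bottom of the T, and two arms, one of which (the reward
condition) yields a reward with high probability while the other yields a
loss. The cue location reveals the reward condition; visiting it costs a
step, so the epistemic value of the cue must outweigh the pragmatic cost of
delaying the arm visit.

State factors, observation modalities and actions (all 1-based):

* location states/observations/actions: 1 centre, 2 right arm, 3 left arm,
  4 cue location
* reward condition states: 1 right, 2 left
* reward observations: 1 no reward, 2 reward, 3 loss
* cue observations: 1 cue right, 2 cue left

This module also builds the matching agent generative model (identical in
structure to the generative process, but agnostic about arm outcomes so
that the reward mapping must be learned from Dirichlet counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agent import Agent
from .model import ModelShape, create_templates, onehot
from .perception import InferenceSettings
from .planning import Hyperparameters, PlanningSettings

__all__ = [
    "LOC_CENTRE", "LOC_RIGHT", "LOC_LEFT", "LOC_CUE",
    "COND_RIGHT", "COND_LEFT",
    "REW_NONE", "REW_REWARD", "REW_LOSS",
    "CUE_RIGHT", "CUE_LEFT",
    "TMazeConfig", "TMazeEnv",
    "tmaze_shape", "tmaze_model", "make_tmaze_agent",
    "simulate_dataset",
]

LOC_CENTRE, LOC_RIGHT, LOC_LEFT, LOC_CUE = 1, 2, 3, 4
COND_RIGHT, COND_LEFT = 1, 2
REW_NONE, REW_REWARD, REW_LOSS = 1, 2, 3
CUE_RIGHT, CUE_LEFT = 1, 2

#: observation modality columns and action factor columns of the long-format
#: behavioural table
OBS_COLUMNS = ("Location", "Reward", "Cue")
ACTION_COLUMNS = ("Action_Location", "Action_Reward")
SUBJECT_COLUMN = "SubjectID"


@dataclass(frozen=True)
class TMazeConfig:
    """Generative-process parameters.

    reward_probability : chance of a reward (vs loss) in the rewarding arm;
        the other arm is mirrored (loss with the same probability).
    cue_validity : chance the cue indicates the true reward condition.
    reward_condition : 'right', 'left', or None to sample it at reset.
    """

    reward_probability: float = 0.95
    cue_validity: float = 1.0
    reward_condition: str | None = None

    def __post_init__(self):
        for name in ("reward_probability", "cue_validity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.reward_condition not in (None, "right", "left"):
            raise ValueError("reward_condition must be 'right', 'left' or None")


class TMazeEnv:
    """The data-generating process the agent interacts with."""

    def __init__(self, config: TMazeConfig = TMazeConfig()):
        self.config = config
        self.location: int | None = None
        self.condition: int | None = None

    def reset(self, rng: np.random.Generator) -> tuple[int, ...]:
        """Place the agent at the centre, fix the reward condition, and
        return the initial observation."""
        self.location = LOC_CENTRE
        if self.config.reward_condition is None:
            self.condition = COND_RIGHT if rng.random() < 0.5 else COND_LEFT
        else:
            self.condition = COND_RIGHT if self.config.reward_condition == "right" else COND_LEFT
        return self._observe(rng)

    def step(self, action: int, rng: np.random.Generator) -> tuple[int, ...]:
        """Move to the location named by ``action`` (1..4) and observe."""
        if self.location is None:
            raise RuntimeError("environment must be reset before stepping")
        if not 1 <= int(action) <= 4:
            raise IndexError(f"action {action} out of range 1..4")
        self.location = int(action)
        return self._observe(rng)

    def _observe(self, rng: np.random.Generator) -> tuple[int, ...]:
        loc = self.location
        # reward: only the arms pay out; the rewarding arm rewards w.p. p,
        # the other arm mirrors (loss w.p. p)
        if loc in (LOC_CENTRE, LOC_CUE):
            reward = REW_NONE
        else:
            rewarding_arm = LOC_RIGHT if self.condition == COND_RIGHT else LOC_LEFT
            p = self.config.reward_probability
            if loc == rewarding_arm:
                reward = REW_REWARD if rng.random() < p else REW_LOSS
            else:
                reward = REW_LOSS if rng.random() < p else REW_REWARD
        # cue: informative only at the cue location
        if loc == LOC_CUE:
            truthful = rng.random() < self.config.cue_validity
            cue_true = CUE_RIGHT if self.condition == COND_RIGHT else CUE_LEFT
            cue = cue_true if truthful else (CUE_LEFT if cue_true == CUE_RIGHT else CUE_RIGHT)
        else:
            cue = CUE_RIGHT if rng.random() < 0.5 else CUE_LEFT
        return (loc, reward, cue)


def tmaze_shape(policy_length: int = 2) -> ModelShape:
    return ModelShape(
        num_obs=(4, 3, 2),
        num_states=(4, 2),
        num_controls=(4, 1),
        policy_length=policy_length,
    )


def tmaze_model(reward_preference: float = 3.0):
    """The agent's generative model of the T-maze.

    The location modality and the location transitions are known exactly;
    the reward modality is agnostic about the arms (0.5 reward / 0.5 loss
    in both conditions) so the payout contingency must be learned; the cue
    modality is truthful at the cue location and uninformative elsewhere.
    Preferences: +reward_preference log-preference for reward,
    -reward_preference for loss, neutral otherwise.

    Returns ``(A, B, C, D, E, shape)``.
    """
    shape = tmaze_shape()
    A, B, C, D, E = create_templates(shape, fill="zeros")

    # location modality: identity over locations in both conditions
    for cond in range(2):
        A[0][:, :, cond] = np.eye(4)
    # reward modality: certain "no reward" off-arm, agnostic in the arms
    for cond in range(2):
        A[1][REW_NONE - 1, LOC_CENTRE - 1, cond] = 1.0
        A[1][REW_NONE - 1, LOC_CUE - 1, cond] = 1.0
        for arm in (LOC_RIGHT, LOC_LEFT):
            A[1][REW_REWARD - 1, arm - 1, cond] = 0.5
            A[1][REW_LOSS - 1, arm - 1, cond] = 0.5
    # cue modality: uniform everywhere except the cue location
    A[2][:, :, :] = 0.5
    A[2][:, LOC_CUE - 1, :] = 0.0
    A[2][CUE_RIGHT - 1, LOC_CUE - 1, COND_RIGHT - 1] = 1.0
    A[2][CUE_LEFT - 1, LOC_CUE - 1, COND_LEFT - 1] = 1.0

    # location transitions: the action picks the next location deterministically
    for u in range(4):
        B[0][u, :, u] = 1.0
    # reward condition never changes
    B[1][:, :, 0] = np.eye(2)

    C[1][REW_REWARD - 1] = reward_preference
    C[1][REW_LOSS - 1] = -reward_preference

    D[0] = onehot(LOC_CENTRE, 4)
    D[1] = np.full(2, 0.5)

    E = np.full(16, 1.0 / 16)
    return A, B, C, D, E, shape


def make_tmaze_agent(
    alpha: float = 16.0,
    gamma: float = 16.0,
    eta_A: float = 1.0,
    prior_scale: float = 2.0,
    reward_preference: float = 3.0,
    policy_length: int = 2,
) -> Agent:
    """Standard T-maze agent: Dirichlet prior on A = prior_scale * A with
    learning restricted to the reward modality, state and parameter
    information gain enabled, planning two steps ahead."""
    A, B, C, D, E, _ = tmaze_model(reward_preference)
    counts_A = [prior_scale * a for a in A]
    return Agent(
        A, B, C=C, D=D, E=E,
        counts_A=counts_A,
        hyper=Hyperparameters(gamma=gamma, alpha=alpha, eta_A=eta_A),
        planning=PlanningSettings(
            policy_length=policy_length,
            use_state_info_gain=True,
            use_param_info_gain=True,
            learned_modalities=(2,),
        ),
        inference=InferenceSettings(),
    )


def run_episode(agent: Agent, env: TMazeEnv, T: int, rng: np.random.Generator) -> pd.DataFrame:
    """Run one agent for T steps in a fresh environment; returns the
    long-format record of observations and actions."""
    obs = env.reset(rng)
    rows = []
    for t in range(1, T + 1):
        action = agent.step(obs, rng)
        full_action = action if len(action) == 2 else (action[0], 1)
        rows.append(
            {
                "t": t,
                "Location": obs[0],
                "Reward": obs[1],
                "Cue": obs[2],
                "Action_Location": full_action[0],
                "Action_Reward": full_action[1],
            }
        )
        obs = env.step(action[0], rng)
    return pd.DataFrame(rows)


def simulate_dataset(
    group_specs,
    T: int,
    config: TMazeConfig = TMazeConfig(),
    seed: int = 0,
    agent_factory=make_tmaze_agent,
):
    """Simulate groups of agents with Gaussian-distributed action precisions.

    ``group_specs`` is a list of ``(n_agents, alpha_mean, alpha_sd)``
    triples. For each agent an action precision alpha is drawn (negative
    draws are rejected and redrawn), a fresh agent and T-maze are created,
    and the agent is run for ``T`` steps. Returns ``(dataset, truth)``:
    the long-format behavioural table (one row per time step per subject)
    and the table of generative parameter values per subject.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    frames, truth = [], []
    subject = 0
    for g, (n_agents, mean, sd) in enumerate(group_specs, start=1):
        for _ in range(int(n_agents)):
            subject += 1
            alpha = float(rng.normal(mean, sd))
            while alpha <= 0:
                alpha = float(rng.normal(mean, sd))
            agent = agent_factory(alpha=alpha)
            env = TMazeEnv(config)
            df = run_episode(agent, env, T, rng)
            df[SUBJECT_COLUMN] = subject
            frames.append(df)
            truth.append({"SubjectID": subject, "group": g, "alpha": alpha})
    data = pd.concat(frames, ignore_index=True)
    data = data[["t", *OBS_COLUMNS, *ACTION_COLUMNS, SUBJECT_COLUMN]]
    return data, pd.DataFrame(truth)
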