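"""Behavioural-data CSV readers/writers and YAML configuration.

Behavioural tables are long format: one row per time step per subject, one
column per observation modality, one column per action factor, and a
subject identifier. All category codes are 1-based integers, matching the
convention of the rest of the package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_behavioural_csv",
    "write_behavioural_csv",
    "load_config",
    "DEFAULT_CONFIG",
]

#: default column mapping and study settings for the T-maze recovery study
DEFAULT_CONFIG = {
    "columns": {
        "observations": ["Location", "Reward", "Cue"],
        "actions": ["Action_Location", "Action_Reward"],
        "subject": "SubjectID",
    },
    "shape": {"num_obs": [4, 3, 2], "num_controls": [4, 1]},
    "environment": {"reward_probability": 0.95, "cue_validity": 1.0},
    "agent": {"gamma": 16.0, "alpha": 16.0, "eta_A": 1.0, "prior_scale": 2.0,
              "reward_preference": 3.0, "policy_length": 2},
    "simulation": {"T": 300, "groups": [[5, 8.0, 2.0], [5, 24.0, 2.0]]},
    "priors": {"alpha": {"family": "truncated_normal", "params": [5.0, 5.0],
                         "bounds": [0.0, 20.0]}},
    "sampler": {"n_chains": 2, "n_draws": 1000, "n_warmup": 500},
}


class SchemaError(ValueError):
    """A declared column is missing or a code is out of range."""


def read_behavioural_csv(
    path,
    obs_columns=("Location", "Reward", "Cue"),
    action_columns=("Action_Location", "Action_Reward"),
    subject_column="SubjectID",
    num_obs=None,
    num_controls=None,
) -> pd.DataFrame:
    """Read a long-format behavioural table, validating codes.

    ``num_obs`` / ``num_controls`` optionally give per-modality /
    per-factor category counts; codes outside ``1..n`` raise a
    :class:`SchemaError` naming the offending row.
    """
    df = pd.read_csv(path)
    declared = [*obs_columns, *action_columns, subject_column]
    missing = [c for c in declared if c not in df.columns]
    if missing:
        raise SchemaError(f"missing declared column(s): {missing}")
    for cols, bounds, kind in (
        (obs_columns, num_obs, "observation"),
        (action_columns, num_controls, "action"),
    ):
        if bounds is None:
            continue
        for col, n in zip(cols, bounds):
            codes = df[col].to_numpy()
            bad = np.where((codes < 1) | (codes > n))[0]
            if bad.size:
                r = int(bad[0])
                raise SchemaError(
                    f"{kind} code {codes[r]} in column {col!r}, row {r + 2} "
                    f"(1-based with header) outside 1..{n}"
                )
    return df


def write_behavioural_csv(path, dataset: pd.DataFrame) -> None:
    """Write a behavioural table as RFC-4180 CSV with a header row."""
    dataset.to_csv(path, index=False)


def load_config(path=None) -> dict:
    """Load a YAML config, filling unspecified blocks from the defaults."""
    cfg = {k: (dict(v) if isinstance(v, dict) else list(v)) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg
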