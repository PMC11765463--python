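"""Per-subject Bayesian estimation of agent hyper-parameters from behaviour.

The estimation is meta-Bayesian: the analyst's model of the subject is the
active inference agent itself. For a candidate parameter value the agent is
replayed through the subject's recorded observations, and at every time
step the probability it assigns to the action the subject actually took
(after the action-precision softmax) contributes to the log-likelihood;
the agent is then advanced with the *observed* action (teacher forcing),
which keeps the likelihood well defined. Posteriors are drawn per subject
with an adaptive random-walk Metropolis sampler (the replay likelihood is
not assumed differentiable) and summarised with standard MCMC diagnostics.

When the only free parameter is the action precision alpha, the replayed
action marginals do not depend on it, so they are computed once per subject
and the likelihood of any alpha is then available in closed form. This is
an exact shortcut: it equals the full replay likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .model import PROB_FLOOR
from .planning import action_distribution

__all__ = [
    "Prior",
    "SamplerSettings",
    "FitResult",
    "action_sequence_loglik",
    "precompute_action_marginals",
    "alpha_pointwise_loglik",
    "fit_subjects",
    "summarize_posterior",
    "recovery_report",
    "psis_loo",
]


def _flog(x):
    return np.log(np.maximum(x, PROB_FLOOR))


# --------------------------------------------------------------------- priors


@dataclass(frozen=True)
class Prior:
    """Prior distribution descriptor for one free parameter.

    Supported families: ``normal(mu, sd)``, ``truncated_normal(mu, sd)``
    with ``bounds=(low, high)``, ``gamma(shape, scale)`` and
    ``uniform(low, high)``.
    """

    family: str
    params: tuple
    bounds: tuple | None = None

    def frozen(self):
        if self.family == "normal":
            mu, sd = self.params
            return stats.norm(mu, sd)
        if self.family == "truncated_normal":
            mu, sd = self.params
            low, high = self.bounds if self.bounds is not None else (-np.inf, np.inf)
            return stats.truncnorm((low - mu) / sd, (high - mu) / sd, loc=mu, scale=sd)
        if self.family == "gamma":
            shape, scale = self.params
            return stats.gamma(shape, scale=scale)
        if self.family == "uniform":
            low, high = self.params
            return stats.uniform(low, high - low)
        raise ValueError(f"unsupported prior family {self.family!r}")

    def logpdf(self, x: float) -> float:
        return float(self.frozen().logpdf(x))

    def sample(self, rng: np.random.Generator) -> float:
        return float(self.frozen().rvs(random_state=rng))

    def std(self) -> float:
        return float(self.frozen().std())


@dataclass(frozen=True)
class SamplerSettings:
    n_chains: int = 2
    n_draws: int = 1000
    n_warmup: int = 500
    seed: int = 0
    algorithm: str = "rw_metropolis"
    target_accept: float = 0.4

    def __post_init__(self):
        if self.algorithm != "rw_metropolis":
            raise ValueError(f"unsupported algorithm {self.algorithm!r}")


# ----------------------------------------------------------------- likelihood


def action_sequence_loglik(params, agent, observations, actions, pointwise=False):
    """Replay log-likelihood of an observed action sequence.

    ``params`` maps hyper-parameter names (alpha, gamma, eta_A, ...) to
    candidate values, applied to a fresh copy of ``agent``. At each time
    step the agent infers states, learns, evaluates policies and produces
    per-factor action marginals; the log-probability of the observed action
    under the alpha-softmax of those marginals is accumulated over the
    controllable factors, and the agent is then advanced with the observed
    action. Probabilities are floored at 1e-16, so the result is finite.
    """
    agent = agent.copy()
    agent.reset()
    for name, value in params.items():
        agent.set_parameter(name, value)
    alpha = agent.hyper.alpha
    controllable = agent.shape.controllable_factors
    observations = np.asarray(observations, dtype=int)
    actions = np.asarray(actions, dtype=int)
    lls = np.zeros(len(observations))
    for t in range(len(observations)):
        marginals = agent.action_marginals(observations[t])
        dists = action_distribution(marginals, alpha)
        for f in controllable:
            lls[t] += _flog(dists[f])[actions[t, f] - 1]
        agent.commit_action(actions[t])
    return lls if pointwise else float(lls.sum())


def precompute_action_marginals(agent, observations, actions):
    """Replay once with ``agent``'s fixed parameters and record, per step,
    the marginal action probabilities of each controllable factor.

    The marginals depend on the model, gamma and the learning rates but not
    on alpha, so they can be reused to evaluate the likelihood of any alpha.
    Returns ``{factor_index: (T, num_controls) array}`` (0-based factor keys).
    """
    agent = agent.copy()
    agent.reset()
    observations = np.asarray(observations, dtype=int)
    actions = np.asarray(actions, dtype=int)
    controllable = agent.shape.controllable_factors
    store = {f: np.zeros((len(observations), agent.shape.num_controls[f])) for f in controllable}
    for t in range(len(observations)):
        marginals = agent.action_marginals(observations[t])
        for f in controllable:
            store[f][t] = marginals[f]
        agent.commit_action(actions[t])
    return store


def alpha_pointwise_loglik(alpha, marginals, actions):
    """Closed-form per-step log-likelihood of alpha given precomputed
    marginals: ln softmax(alpha * ln p)[a_t], summed over factors."""
    actions = np.asarray(actions, dtype=int)
    T = len(actions)
    lls = np.zeros(T)
    for f, probs in marginals.items():
        logits = alpha * _flog(probs)  # (T, num_controls)
        lse = logsumexp(logits, axis=1)
        taken = logits[np.arange(T), actions[:, f] - 1]
        lls += taken - lse
    return lls


# -------------------------------------------------------------------- sampler


def _rw_metropolis(logpost, priors, settings: SamplerSettings, seed_seq):
    """Adaptive random-walk Metropolis: one proposal scale per parameter,
    adapted during warmup toward the target acceptance rate."""
    names = list(priors)
    chains = np.zeros((settings.n_chains, settings.n_draws, len(names)))
    accept = np.zeros(settings.n_chains)
    for c, child in enumerate(seed_seq.spawn(settings.n_chains)):
        rng = np.random.default_rng(child)
        # initialise from the prior at a point of finite posterior density
        for attempt in range(100):
            theta = np.array([priors[n].sample(rng) for n in names])
            lp = logpost(dict(zip(names, theta)))
            if np.isfinite(lp):
                break
        else:
            raise RuntimeError("could not initialise chain: non-finite posterior after 100 draws")
        log_scale = np.log(np.array([max(priors[n].std() / 4.0, 1e-3) for n in names]))
        n_acc = 0
        total = settings.n_warmup + settings.n_draws
        for i in range(total):
            prop = theta + rng.normal(size=len(names)) * np.exp(log_scale)
            lp_prop = logpost(dict(zip(names, prop)))
            accepted = np.log(rng.random()) < lp_prop - lp
            if accepted:
                theta, lp = prop, lp_prop
            if i < settings.n_warmup:
                # Robbins–Monro adaptation of the proposal scale
                log_scale += (float(accepted) - settings.target_accept) / (i + 1) ** 0.6
            else:
                chains[c, i - settings.n_warmup] = theta
                n_acc += int(accepted)
        accept[c] = n_acc / settings.n_draws
    return {n: chains[:, :, j] for j, n in enumerate(names)}, accept


@dataclass
class FitResult:
    """Posterior samples per subject.

    ``samples[subject][param]`` is a ``(n_chains, n_draws)`` array;
    ``accept_rates`` maps subject to per-chain acceptance fractions.
    """

    samples: dict
    accept_rates: dict
    priors: dict
    settings: SamplerSettings

    @property
    def subjects(self):
        return list(self.samples)


def fit_subjects(
    dataset: pd.DataFrame,
    priors: dict,
    settings: SamplerSettings = SamplerSettings(),
    agent_factory=None,
    obs_columns=("Location", "Reward", "Cue"),
    action_columns=("Action_Location", "Action_Reward"),
    subject_column="SubjectID",
) -> FitResult:
    """Independent per-subject MCMC estimation of agent hyper-parameters.

    ``dataset`` is a long-format behavioural table with one column per
    observation modality, one per action factor, and a subject identifier
    (1-based category codes). ``priors`` maps free-parameter names to
    :class:`Prior` descriptors. ``agent_factory`` builds the (fixed) agent
    template; it defaults to the standard T-maze agent.

    Uses the exact alpha shortcut (marginals precomputed once) when alpha
    is the only free parameter; otherwise every posterior evaluation
    replays the full sequence.
    """
    if agent_factory is None:
        from .envs import make_tmaze_agent
        agent_factory = make_tmaze_agent
    samples, accepts = {}, {}
    seed_seq = np.random.SeedSequence(settings.seed)
    subject_ids = sorted(dataset[subject_column].unique())
    subject_seeds = dict(zip(subject_ids, seed_seq.spawn(len(subject_ids))))
    for sid in subject_ids:
        sub = dataset[dataset[subject_column] == sid]
        if "t" in sub.columns:
            sub = sub.sort_values("t")
        obs = sub[list(obs_columns)].to_numpy(dtype=int)
        acts = sub[list(action_columns)].to_numpy(dtype=int)
        template = agent_factory()
        if set(priors) == {"alpha"}:
            marginals = precompute_action_marginals(template, obs, acts)

            def logpost(params, _m=marginals, _a=acts):
                lp = priors["alpha"].logpdf(params["alpha"])
                if not np.isfinite(lp):
                    return -np.inf
                return lp + float(alpha_pointwise_loglik(params["alpha"], _m, _a).sum())

        else:

            def logpost(params, _t=template, _o=obs, _a=acts):
                lp = sum(priors[n].logpdf(v) for n, v in params.items())
                if not np.isfinite(lp):
                    return -np.inf
                return lp + action_sequence_loglik(params, _t, _o, _a)

        samples[sid], accepts[sid] = _rw_metropolis(
            logpost, priors, settings, subject_seeds[sid]
        )
    return FitResult(samples=samples, accept_rates=accepts, priors=priors, settings=settings)


# ------------------------------------------------------------------ summaries


def _chain_stats(arr: np.ndarray) -> dict:
    """Summary statistics for one parameter's (n_chains, n_draws) samples."""
    import arviz as az

    flat = arr.ravel()
    out = {
        "mean": float(flat.mean()),
        "std": float(flat.std(ddof=1)) if flat.size > 1 else 0.0,
        "median": float(np.median(flat)),
        "q2.5": float(np.quantile(flat, 0.025)),
        "q97.5": float(np.quantile(flat, 0.975)),
    }
    if np.ptp(flat) == 0.0:
        # degenerate chains: diagnostics are trivially perfect
        out.update(mcse=0.0, ess_bulk=float(flat.size), ess_tail=float(flat.size), rhat=1.0)
        return out
    out["mcse"] = float(np.asarray(az.mcse(arr)).ravel()[0])
    out["ess_bulk"] = float(az.ess(arr, method="bulk"))
    out["ess_tail"] = float(az.ess(arr, method="tail"))
    out["rhat"] = float(az.rhat(arr))
    return out


def summarize_posterior(result) -> pd.DataFrame:
    """Posterior summary table (mean, std, mcse, ess_bulk, ess_tail, rhat,
    quantiles) per subject and parameter.

    Accepts a :class:`FitResult` or a plain ``{param: (n_chains, n_draws)}``
    dict (summarised as a single anonymous subject).
    """
    if isinstance(result, FitResult):
        items = result.samples.items()
    else:
        items = [(None, result)]
    rows = []
    for sid, params in items:
        for name, arr in params.items():
            row = {"SubjectID": sid, "parameter": name}
            row.update(_chain_stats(np.asarray(arr, dtype=float)))
            rows.append(row)
    return pd.DataFrame(rows)


def recovery_report(truth: pd.DataFrame, summary: pd.DataFrame, parameter: str = "alpha"):
    """Compare posterior medians with the generative parameter values.

    ``truth`` must contain ``SubjectID`` and a column named after the
    parameter (plus optionally ``group``). Returns ``(table, spearman_rho)``
    where the table holds, per subject, the generative value, the posterior
    median and summary statistics — the data behind an estimated-vs-true
    scatter plot.
    """
    est = summary[summary["parameter"] == parameter][
        ["SubjectID", "mean", "median", "std", "rhat"]
    ]
    cols = ["SubjectID", parameter] + (["group"] if "group" in truth.columns else [])
    table = truth[cols].merge(est, on="SubjectID")
    table = table.rename(columns={parameter: "true_value", "median": "estimated_median"})
    rho = float(stats.spearmanr(table["true_value"], table["estimated_median"]).statistic)
    return table, rho


def psis_loo(pointwise_loglik: np.ndarray):
    """Pareto-smoothed importance-sampling estimate of leave-one-out
    expected log predictive density (PSIS-LOO).

    ``pointwise_loglik`` has shape ``(n_chains, n_draws, n_observations)``.
    Returns ``(elpd_loo, pareto_k)``. If the likelihood is constant across
    draws the importance weights are uniform and the estimate reduces to
    the sum of the pointwise values (Pareto k is undefined, returned as 0).
    """
    import arviz as az

    pointwise_loglik = np.asarray(pointwise_loglik, dtype=float)
    if pointwise_loglik.ndim != 3:
        raise ValueError("expected shape (n_chains, n_draws, n_observations)")
    if np.ptp(pointwise_loglik.reshape(-1, pointwise_loglik.shape[-1]), axis=0).max() == 0.0:
        elpd = float(pointwise_loglik[0, 0].sum())
        return elpd, np.zeros(pointwise_loglik.shape[-1])
    idata = az.from_dict(log_likelihood={"obs": pointwise_loglik})
    res = az.loo(idata, pointwise=True, reff=1.0)
    return float(res.elpd_loo), np.asarray(res.pareto_k)
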