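"""Reinforcement-learning models of peer-adjustment behavior.

Each revision opportunity is treated as a binary choice between
``converge`` (move toward / stay with the peer) and ``not_converge``.
Option values follow a Rescorla-Wagner update

    Q[k] <- Q[k] + alpha * (r - Q[k])

and choice probabilities come from a softmax with inverse-temperature
tau in (0, 2], p[k] proportional to exp(tau * Q[k]).  Three reward models
share this machinery and differ only in the reward signal:

* M1 - pursuit of convergence: +1 when the participant either kept an
  estimate already equal to the peer's or moved so that the dyad's gap
  shrank; -1 otherwise.
* M2 - relative adjustment: +1 / -1 when the participant moved more /
  less than the peer; 0 when both stayed put (and, by our convention,
  for equal nonzero moves).
* M3 - convergence outcome: +1 when the gap shrank (or stayed at the
  maximum, i.e. zero); -1 when it grew; 0 when unchanged and nonzero.

Models are fit per participant by maximum likelihood and compared with
BIC = -2*logLL + k_m*log(T) and Tukey-adjusted pairwise log-likelihood
contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .task_behavior import AdjustmentRecord, Session, compute_adjustments

logger = logging.getLogger(__name__)

CONVERGE, NOT_CONVERGE = 0, 1
MODELS = ("M1", "M2", "M3")

ALPHA_BOUNDS = (0.0, 1.0)
TAU_BOUNDS = (1e-6, 2.0)  # open at 0: softmax is defined for tau > 0 only

#: floor on per-event choice probabilities inside the likelihood
PROB_EPS = 1e-12


@dataclass(frozen=True)
class RLParams:
    """Learning rate alpha in [0, 1] and softmax temperature tau in (0, 2]."""

    alpha: float
    tau: float

    def __post_init__(self) -> None:
        if not (ALPHA_BOUNDS[0] <= self.alpha <= ALPHA_BOUNDS[1]):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not (0.0 < self.tau <= TAU_BOUNDS[1]):
            raise ValueError(f"tau must be in (0, 2], got {self.tau}")


@dataclass
class RLFitResult:
    """Maximum-likelihood fit of one model to one participant."""

    model: str
    params: RLParams
    loglik: float
    bic: float
    pe_series: np.ndarray  # prediction error r_t - Q_t[k], pre-update
    n_events: int
    trial_index: np.ndarray
    opportunity: np.ndarray  # "FB1->FB2" / "FB2->FB3" per event


# ---------------------------------------------------------------------------
# Rewards


def reward_m1(adj: AdjustmentRecord) -> int:
    """+1 for convergent action (kept an already-matching estimate, or
    moved and the gap shrank); -1 otherwise."""
    if adj.change_self == 0:
        return 1 if adj.convergence_before == 0 else -1
    return 1 if adj.convergence_after < adj.convergence_before else -1


def reward_m2(adj: AdjustmentRecord) -> int:
    """Relative adjustment: sign of |own move| - |peer move|; 0 on ties."""
    a, b = abs(adj.change_self), abs(adj.change_peer)
    if a > b:
        return 1
    if a < b:
        return -1
    return 0


def reward_m3(adj: AdjustmentRecord) -> int:
    """Convergence outcome: +1 if the gap shrank or is held at zero,
    -1 if it grew, 0 if unchanged and nonzero."""
    if adj.convergence_after < adj.convergence_before:
        return 1
    if adj.convergence_after > adj.convergence_before:
        return -1
    return 1 if adj.convergence_after == 0 else 0


REWARD_FUNCS = {"M1": reward_m1, "M2": reward_m2, "M3": reward_m3}


def choice_label(adj: AdjustmentRecord) -> int:
    """Dichotomous choice label (CONVERGE / NOT_CONVERGE).

    The label follows the M1 convergence criterion for every model, so
    likelihoods stay comparable across models: only the reward signal
    differs between M1/M2/M3.
    """
    return CONVERGE if reward_m1(adj) == 1 else NOT_CONVERGE


# ---------------------------------------------------------------------------
# Core update / choice rule


def q_update(q: np.ndarray, k: int, r: float, alpha: float) -> np.ndarray:
    """Rescorla-Wagner update of option ``k``; other options unchanged."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    out = np.array(q, dtype=float)
    out[k] = out[k] + alpha * (r - out[k])
    return out


def softmax_prob(q: np.ndarray, tau: float) -> np.ndarray:
    """p[k] = exp(tau*q[k]) / sum_i exp(tau*q[i]).

    tau -> 0 gives uniform choice; larger tau makes the higher-valued
    option increasingly deterministic.
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    q = np.asarray(q, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("non-finite Q values")
    z = tau * q
    z = z - z.max()  # overflow-safe
    e = np.exp(z)
    return e / e.sum()


def bic(loglik: float, k_m: int, n: int) -> float:
    """Bayesian information criterion, -2*logLL + k_m*log(n)."""
    return -2.0 * loglik + k_m * np.log(n)


# ---------------------------------------------------------------------------
# Likelihood and fitting


def _event_arrays(session: Session, model: str):
    """Choice labels and rewards for all valid events, in temporal order."""
    reward_fn = REWARD_FUNCS[model]
    adjustments = [a for a in compute_adjustments(session) if a.valid]
    k = np.array([choice_label(a) for a in adjustments], dtype=np.intp)
    r = np.array([reward_fn(a) for a in adjustments], dtype=float)
    trial = np.array([a.trial_index for a in adjustments], dtype=np.intp)
    opp = np.array([a.opportunity for a in adjustments])
    return k, r, trial, opp


def _nll_from_events(alpha: float, tau: float, k: np.ndarray, r: np.ndarray,
                     return_pe: bool = False):
    q = np.zeros(2)
    nll = 0.0
    pe = np.empty(len(k)) if return_pe else None
    for t in range(len(k)):
        z = tau * q
        z = z - z.max()
        e = np.exp(z)
        p = e[k[t]] / (e[0] + e[1])
        nll -= np.log(max(p, PROB_EPS))
        if return_pe:
            pe[t] = r[t] - q[k[t]]
        q[k[t]] += alpha * (r[t] - q[k[t]])
    return (nll, pe) if return_pe else nll


def negative_log_likelihood(
    params: RLParams, session: Session, model: str
) -> float:
    """Sequential NLL of the observed convergence choices under ``model``.

    Q starts at (0, 0).  Per event: softmax choice probability of the
    observed option is accumulated, then the chosen option's Q is updated
    with the model's reward.  Event probabilities are floored at
    ``PROB_EPS``.
    """
    k, r, _, _ = _event_arrays(session, model)
    return float(_nll_from_events(params.alpha, params.tau, k, r))


def fit_rl(
    session: Session,
    model: str,
    n_restarts: int = 10,
    seed: int = 0,
    t_mode: str = "events",
) -> RLFitResult:
    """Fit (alpha, tau) by bounded ML with multi-start local optimization.

    ``t_mode`` selects the sample-size term of the BIC: "events" uses the
    number of modeled choice events (two per trial; the default),
    "trials" the number of trials.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    k, r, trial, opp = _event_arrays(session, model)
    if len(k) == 0:
        raise ValueError("session has no valid choice events")
    params, loglik = fit_event_stream(k, r, n_restarts=n_restarts, seed=seed)
    alpha_hat, tau_hat = params.alpha, params.tau
    _, pe = _nll_from_events(alpha_hat, tau_hat, k, r, return_pe=True)
    n_trials = len(np.unique(trial))
    t_count = len(k) if t_mode == "events" else n_trials
    return RLFitResult(
        model=model,
        params=RLParams(alpha_hat, tau_hat),
        loglik=loglik,
        bic=float(bic(loglik, k_m=2, n=t_count)),
        pe_series=pe,
        n_events=len(k),
        trial_index=trial,
        opportunity=opp,
    )


def simulate_m1_process(
    params: RLParams, n_events: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a choice/reward stream from the M1 model itself.

    Under M1 the observable reward is locked to the choice label (+1 for
    a convergent action, -1 otherwise), so the model fully specifies the
    generative process: choices come from the softmax over the running Q
    values.  This is the correctly-specified stream used for parameter
    recovery of the fitting machinery.
    """
    rng = np.random.default_rng(seed)
    q = np.zeros(2)
    k = np.empty(n_events, dtype=np.intp)
    r = np.empty(n_events)
    for t in range(n_events):
        p = softmax_prob(q, params.tau)
        k[t] = CONVERGE if rng.random() < p[CONVERGE] else NOT_CONVERGE
        r[t] = 1.0 if k[t] == CONVERGE else -1.0
        q[k[t]] += params.alpha * (r[t] - q[k[t]])
    return k, r


def fit_event_stream(
    k: np.ndarray, r: np.ndarray, n_restarts: int = 10, seed: int = 0
) -> tuple[RLParams, float]:
    """Bounded ML fit of (alpha, tau) to a raw choice/reward stream.

    A coarse (alpha, tau) grid seeds a local search, followed by
    ``n_restarts`` random restarts; deterministic given ``seed``.
    Returns the parameters and the log-likelihood.
    """
    rng = np.random.default_rng(seed)

    def objective(x):
        return _nll_from_events(x[0], x[1], k, r)

    starts = [
        (a, t)
        for a in np.linspace(0.02, 0.98, 13)
        for t in np.linspace(0.1, TAU_BOUNDS[1], 10)
    ]
    grid_best = min(starts, key=objective)
    x0s = [grid_best] + [
        (rng.uniform(*ALPHA_BOUNDS), rng.uniform(0.05, TAU_BOUNDS[1]))
        for _ in range(n_restarts)
    ]
    best = None
    for x0 in x0s:
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                bounds=[ALPHA_BOUNDS, TAU_BOUNDS])
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"optimizer failed on all {len(x0s)} starts")
    alpha_hat = float(np.clip(best.x[0], *ALPHA_BOUNDS))
    tau_hat = float(np.clip(best.x[1], *TAU_BOUNDS))
    return RLParams(alpha_hat, tau_hat), -float(best.fun)


def fit_all_models(
    session: Session, n_restarts: int = 10, seed: int = 0, t_mode: str = "events"
) -> dict[str, RLFitResult]:
    return {
        m: fit_rl(session, m, n_restarts=n_restarts, seed=seed + i, t_mode=t_mode)
        for i, m in enumerate(MODELS)
    }


def pe_frame(fit: RLFitResult, participant_id: str) -> pd.DataFrame:
    """Long prediction-error table keyed by participant, trial, rep.

    PE at the FB1->FB2 opportunity is aligned to FB2, FB2->FB3 to FB3.
    """
    rep = np.where(fit.opportunity == "FB1->FB2", 2, 3)
    return pd.DataFrame(
        dict(
            participant_id=participant_id,
            model=fit.model,
            trial=fit.trial_index,
            rep=rep,
            pe=fit.pe_series,
        )
    )


# ---------------------------------------------------------------------------
# Model comparison


def pairwise_ll_contrasts(loglik_table: pd.DataFrame) -> pd.DataFrame:
    """Tukey pairwise contrasts of per-participant log-likelihood means.

    ``loglik_table`` has one row per participant with one column per model
    (summed log-likelihood).  The model factor is within-participant: the
    error term is the participant x model interaction mean square of the
    repeated-measures decomposition, with df = (n-1)(m-1), and p-values
    use the studentized-range distribution with m means.

    Returns a frame with columns contrast, estimate, se, df, t, p_adj,
    sign convention estimate = mean(first) - mean(second).
    """
    models = list(loglik_table.columns)
    data = loglik_table.to_numpy(dtype=float)
    data = data[~np.isnan(data).any(axis=1)]
    n, m = data.shape
    if n < 2:
        raise ValueError("need at least 2 participants with all models fitted")
    grand = data.mean()
    subj_mean = data.mean(axis=1, keepdims=True)
    model_mean = data.mean(axis=0, keepdims=True)
    resid = data - subj_mean - model_mean + grand
    df_err = (n - 1) * (m - 1)
    mse = float((resid**2).sum() / df_err)
    se = np.sqrt(2.0 * mse / n)
    rows = []
    for i in range(m):
        for j in range(i + 1, m):
            est = float(model_mean[0, i] - model_mean[0, j])
            t = est / se if se > 0 else (0.0 if est == 0 else np.inf)
            # Tukey HSD: q = |t| * sqrt(2) referred to the studentized range
            q = abs(t) * np.sqrt(2.0)
            p = float(stats.studentized_range.sf(q, m, df_err)) if se > 0 else (
                1.0 if est == 0 else 0.0
            )
            rows.append(
                dict(
                    contrast=f"{models[i]}-{models[j]}",
                    estimate=est,
                    se=se,
                    df=df_err,
                    t=t,
                    p_adj=min(p, 1.0),
                )
            )
    return pd.DataFrame(rows)


def loglik_table(fits: dict[str, dict[str, RLFitResult]]) -> pd.DataFrame:
    """Participant x model log-likelihood table from nested fit results
    (``fits[participant][model]``); participants missing any model are
    dropped with a log message."""
    rows = {}
    for pid, per_model in fits.items():
        if set(per_model) >= set(MODELS):
            rows[pid] = {m: per_model[m].loglik for m in MODELS}
        else:
            logger.warning("participant %s missing model fits; dropped", pid)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(MODELS))
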