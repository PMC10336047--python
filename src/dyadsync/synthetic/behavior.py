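"""Generative model of dyadic convergence behavior.

Two softmax/Rescorla-Wagner agents play the number-line estimation task
against each other.  Per trial both start from noisy readings of the true
dot position; at each of the two revision opportunities each agent samples
converge / not-converge from the softmax over its Q values, moves a fixed
fraction of the current gap toward the peer when converging, and updates
the chosen option's value with the configured reward model.  The emitted
logs have exactly the study's structure: 4 blocks x 25 trials x 3
feedback repetitions per participant.

Everything needed to check downstream stages against ground truth (true
parameters, per-event choices, rewards and prediction errors) is returned
in a :class:`GroundTruthManifest`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .. import rl_models
from ..task_behavior import (
    FeedbackEvent,
    N_BLOCKS,
    Session,
    TRIALS_PER_BLOCK,
    TrialSpec,
)


@dataclass
class BehaviorSimConfig:
    """Study conditions for the behavior generator.

    ``alpha``/``tau`` apply to every simulated agent unless per-participant
    overrides are given via ``params`` (list of (alpha, tau) pairs, two per
    dyad, in participant order).  ``step_fraction`` is the share of the
    current self-peer gap closed when the agent chooses to converge; a
    (low, high) tuple draws one fraction per participant, modeling the
    inter-individual variation in adjustment willingness that makes the
    relative-adjustment reward informative.  ``init_noise_sd`` is the
    s.d. (number-line units) of the perceptual noise on the first
    estimate.
    """

    n_dyads: int = 1
    alpha: float = 0.3
    tau: float = 1.5
    params: list[tuple[float, float]] | None = None
    model: str = "M1"
    step_fraction: float | tuple[float, float] = (0.2, 0.45)
    init_noise_sd: float = 10.0
    n_trials: int = N_BLOCKS * TRIALS_PER_BLOCK
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in rl_models.MODELS:
            raise ValueError(f"unknown reward model {self.model!r}")
        lo, hi = self.step_bounds
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("step_fraction must lie in (0, 1]")
        pairs = self.params or [(self.alpha, self.tau)] * (2 * self.n_dyads)
        if len(pairs) != 2 * self.n_dyads:
            raise ValueError("params must list one (alpha, tau) per participant")
        for a, t in pairs:
            rl_models.RLParams(a, t)  # bounds check

    @property
    def step_bounds(self) -> tuple[float, float]:
        if isinstance(self.step_fraction, (int, float)):
            return float(self.step_fraction), float(self.step_fraction)
        lo, hi = self.step_fraction
        return float(lo), float(hi)


@dataclass
class GroundTruthManifest:
    """Everything the generator knows that downstream stages must recover."""

    seed: int
    model: str
    participants: dict[str, dict] = field(default_factory=dict)
    coupling: list[dict] = field(default_factory=list)

    def pe(self, participant_id: str) -> np.ndarray:
        return np.asarray(self.participants[participant_id]["pe"], dtype=float)


class _Agent:
    def __init__(self, alpha: float, tau: float):
        self.alpha, self.tau = alpha, tau
        self.q = np.zeros(2)
        self.choices: list[int] = []
        self.rewards: list[float] = []
        self.pe: list[float] = []

    def decide(self, rng: np.random.Generator) -> int:
        """Sample the converge / not-converge intent from the softmax."""
        p = rl_models.softmax_prob(self.q, self.tau)
        return rl_models.CONVERGE if rng.random() < p[rl_models.CONVERGE] \
            else rl_models.NOT_CONVERGE

    def learn(self, intent: int, reward: float) -> None:
        """Update the intended option with the realized reward.

        The agent knows which option it chose even when the dyad's joint
        outcome makes the realized move look different (e.g. keeping an
        estimate the peer just matched), so learning operates on the
        intent while the reward is the one the task actually delivered.
        """
        self.choices.append(intent)
        self.rewards.append(reward)
        self.pe.append(reward - self.q[intent])
        self.q = rl_models.q_update(self.q, intent, reward, self.alpha)


def _converged_move(est: float, peer: float, frac: float) -> float:
    """Move toward the peer by ``frac`` of the gap, at least one unit,
    never overshooting (integer estimates, as typed on a keypad)."""
    gap = peer - est
    if gap == 0:
        return est
    step = np.sign(gap) * max(1.0, round(abs(gap) * frac))
    if abs(step) > abs(gap):
        step = gap
    return est + step


def _reward(model: str, change_self, change_peer, conv_before, conv_after) -> int:
    from ..task_behavior import AdjustmentRecord

    rec = AdjustmentRecord(0, "FB1->FB2", change_self, change_peer,
                           conv_before, conv_after)
    return rl_models.REWARD_FUNCS[model](rec)


def simulate_dyad_behavior(
    config: BehaviorSimConfig,
) -> tuple[list[tuple[Session, Session]], GroundTruthManifest]:
    """Simulate ``n_dyads`` dyads; returns paired sessions and the manifest."""
    rng = np.random.default_rng(config.seed)
    pairs = config.params or [(config.alpha, config.tau)] * (2 * config.n_dyads)
    manifest = GroundTruthManifest(seed=config.seed, model=config.model)
    dyads: list[tuple[Session, Session]] = []
    n_trials = config.n_trials
    trials_per_block = min(TRIALS_PER_BLOCK, n_trials)

    for d in range(config.n_dyads):
        dyad_id = f"dyad{d:02d}"
        pids = (f"{dyad_id}_A", f"{dyad_id}_B")
        agents = [_Agent(*pairs[2 * d]), _Agent(*pairs[2 * d + 1])]
        lo, hi = config.step_bounds
        step_fracs = [float(rng.uniform(lo, hi)) for _ in range(2)]
        trials: list[TrialSpec] = []
        fb: tuple[list[FeedbackEvent], list[FeedbackEvent]] = ([], [])

        for t in range(n_trials):
            span = int(rng.integers(40, 51))
            low = int(rng.integers(0, 150 - span + 1))
            high = low + span
            dot = float(rng.uniform(low, high))
            trials.append(
                TrialSpec(
                    trial_index=t,
                    block=t // trials_per_block + 1,
                    orientation=str(rng.choice(["vertical", "horizontal"])),
                    endpoint_low=low,
                    endpoint_high=high,
                    dot_position=dot,
                )
            )
            est = [
                float(np.clip(round(dot + rng.normal(0, config.init_noise_sd)),
                              low, high))
                for _ in range(2)
            ]
            marker = 3 * t
            for i in range(2):
                fb[i].append(FeedbackEvent(t, 1, est[i], est[1 - i], marker))
            for rep in (2, 3):
                prev = list(est)
                choices = [ag.decide(rng) for ag in agents]
                for i in range(2):
                    if choices[i] == rl_models.CONVERGE:
                        est[i] = _converged_move(prev[i], prev[1 - i],
                                                 step_fracs[i])
                conv_before = abs(prev[0] - prev[1])
                conv_after = abs(est[0] - est[1])
                for i in range(2):
                    from ..task_behavior import AdjustmentRecord

                    rec = AdjustmentRecord(
                        t, "FB1->FB2",
                        est[i] - prev[i], est[1 - i] - prev[1 - i],
                        conv_before, conv_after,
                    )
                    r = rl_models.REWARD_FUNCS[config.model](rec)
                    agents[i].learn(choices[i], r)
                    fb[i].append(
                        FeedbackEvent(t, rep, est[i], est[1 - i], marker + rep - 1)
                    )

        sessions = []
        for i, role in enumerate("AB"):
            s = Session(
                participant_id=pids[i], dyad_id=dyad_id, role=role,
                trials=list(trials), feedback=fb[i],
            )
            if n_trials == N_BLOCKS * TRIALS_PER_BLOCK:
                s.validate()
            sessions.append(s)
            ag = agents[i]
            manifest.participants[pids[i]] = dict(
                alpha=ag.alpha,
                tau=ag.tau,
                step_fraction=step_fracs[i],
                choices=list(ag.choices),
                rewards=list(ag.rewards),
                pe=list(ag.pe),
            )
        dyads.append((sessions[0], sessions[1]))
    return dyads, manifest
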