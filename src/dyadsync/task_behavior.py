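"""Data model for the dyadic number-line estimation task.

Two participants repeatedly estimate the position of a dot on a number
line.  Each trial has three feedback moments (FB1, FB2, FB3) at which both
see each other's current estimates and may revise their own.  The two
revision opportunities (FB1->FB2 and FB2->FB3) are the behavioral events
from which adjustment and convergence measures are derived; those measures
feed both the reinforcement-learning layer and the trial-level statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The two revision opportunities within a trial.
OPPORTUNITIES = ("FB1->FB2", "FB2->FB3")

#: Feedback repetition labels in temporal order.
FEEDBACK_REPS = (1, 2, 3)

N_BLOCKS = 4
TRIALS_PER_BLOCK = 25
TRIALS_PER_SESSION = N_BLOCKS * TRIALS_PER_BLOCK


@dataclass(frozen=True)
class TrialSpec:
    """Stimulus configuration of one trial.

    The line endpoints lie in [0, 150] and are 40-50 units apart; the dot
    sits between them.
    """

    trial_index: int
    block: int
    orientation: str  # "vertical" | "horizontal"
    endpoint_low: int
    endpoint_high: int
    dot_position: float

    def __post_init__(self) -> None:
        if not (0 <= self.endpoint_low < self.endpoint_high <= 150):
            raise ValueError(
                f"endpoints must satisfy 0 <= low < high <= 150, got "
                f"({self.endpoint_low}, {self.endpoint_high})"
            )
        span = self.endpoint_high - self.endpoint_low
        if not (40 <= span <= 50):
            raise ValueError(f"endpoint span must be in [40, 50], got {span}")
        if not (self.endpoint_low <= self.dot_position <= self.endpoint_high):
            raise ValueError("dot_position must lie within the endpoints")
        if self.orientation not in ("vertical", "horizontal"):
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass(frozen=True)
class FeedbackEvent:
    """One feedback display: both estimates become mutually visible.

    ``rep`` is 1, 2 or 3 (FB1..FB3).  ``est_self``/``est_peer`` are the
    estimates shown at that moment; NaN marks a missing response.
    ``timestamp_marker`` is the event id used to align EEG epochs.
    """

    trial_index: int
    rep: int
    est_self: float
    est_peer: float
    timestamp_marker: int = -1

    def __post_init__(self) -> None:
        if self.rep not in FEEDBACK_REPS:
            raise ValueError(f"rep must be one of {FEEDBACK_REPS}, got {self.rep}")


@dataclass
class Session:
    """One participant's complete behavioral record for a session."""

    participant_id: str
    dyad_id: str
    role: str  # "A" | "B"
    trials: list[TrialSpec] = field(default_factory=list)
    feedback: list[FeedbackEvent] = field(default_factory=list)

    def validate(self) -> None:
        """Check the session counting invariants (100 trials x 3 feedbacks)."""
        if len(self.trials) != TRIALS_PER_SESSION:
            raise ValueError(
                f"expected {TRIALS_PER_SESSION} trials, got {len(self.trials)}"
            )
        if len(self.feedback) != 3 * TRIALS_PER_SESSION:
            raise ValueError(
                f"expected {3 * TRIALS_PER_SESSION} feedback events, "
                f"got {len(self.feedback)}"
            )
        for t, trial in enumerate(self.trials):
            if trial.trial_index != t:
                raise ValueError("trials must be ordered by trial_index")
        for i, ev in enumerate(self.feedback):
            if ev.trial_index != i // 3 or ev.rep != i % 3 + 1:
                raise ValueError(
                    "feedback must be ordered (trial asc, rep FB1<FB2<FB3)"
                )

    def feedback_for_trial(self, trial_index: int) -> list[FeedbackEvent]:
        return [ev for ev in self.feedback if ev.trial_index == trial_index]


@dataclass(frozen=True)
class AdjustmentRecord:
    """Behavioral derivatives of one revision opportunity.

    ``change_*`` are signed displacements (est_next - est_prev) in number
    line units; ``convergence_*`` are absolute self-peer distances before
    and after the revision.  ``valid`` is False when an estimate was
    missing; such records are excluded downstream, never imputed.
    """

    trial_index: int
    opportunity: str
    change_self: float
    change_peer: float
    convergence_before: float
    convergence_after: float
    valid: bool = True


@dataclass(frozen=True)
class AdjustmentLabel:
    """Trial-level adjustment class from the participant's own median split."""

    trial_index: int
    label: str  # "high_high" | "low_low" | "mixed"


def compute_adjustments(session: Session) -> list[AdjustmentRecord]:
    """Derive one :class:`AdjustmentRecord` per trial per opportunity.

    A full session yields 200 records (100 trials x 2 opportunities).  The
    post-revision convergence of FB1->FB2 equals the pre-revision
    convergence of FB2->FB3 by construction.
    """
    records: list[AdjustmentRecord] = []
    by_trial: dict[int, dict[int, FeedbackEvent]] = {}
    for ev in session.feedback:
        by_trial.setdefault(ev.trial_index, {})[ev.rep] = ev
    for trial_index in sorted(by_trial):
        evs = by_trial[trial_index]
        for opp, (rep_prev, rep_next) in zip(OPPORTUNITIES, ((1, 2), (2, 3))):
            prev, nxt = evs.get(rep_prev), evs.get(rep_next)
            if prev is None or nxt is None or any(
                not np.isfinite(v)
                for v in (prev.est_self, prev.est_peer, nxt.est_self, nxt.est_peer)
            ):
                records.append(
                    AdjustmentRecord(trial_index, opp, np.nan, np.nan,
                                     np.nan, np.nan, valid=False)
                )
                continue
            records.append(
                AdjustmentRecord(
                    trial_index=trial_index,
                    opportunity=opp,
                    change_self=nxt.est_self - prev.est_self,
                    change_peer=nxt.est_peer - prev.est_peer,
                    convergence_before=abs(prev.est_self - prev.est_peer),
                    convergence_after=abs(nxt.est_self - nxt.est_peer),
                )
            )
    return records


def label_adjustment_trials(
    session: Session, adjustments: list[AdjustmentRecord] | None = None
) -> list[AdjustmentLabel]:
    """Median-split each trial into high_high / low_low / mixed.

    The adjustment magnitude of an opportunity is ``|change_self|``.  The
    median is taken over all of this participant's valid magnitudes across
    both opportunities (pooled).  A trial is ``high_high`` iff both
    opportunities strictly exceed the median, ``low_low`` iff both are <=
    the median, else ``mixed``.  Ties therefore go to low.  Mixed trials
    are excluded from the adjustment-type contrast downstream.
    """
    if adjustments is None:
        adjustments = compute_adjustments(session)
    valid = [a for a in adjustments if a.valid]
    magnitudes = np.array([abs(a.change_self) for a in valid])
    if magnitudes.size == 0:
        return []
    median = float(np.median(magnitudes))
    if np.all(magnitudes == 0):
        warnings.warn(
            "all adjustment magnitudes are zero: degenerate median split, "
            "every trial labeled low_low",
            stacklevel=2,
        )
    by_trial: dict[int, list[float]] = {}
    for a in valid:
        by_trial.setdefault(a.trial_index, []).append(abs(a.change_self))
    labels = []
    for trial_index in sorted(by_trial):
        mags = by_trial[trial_index]
        if len(mags) < 2:
            label = "mixed"  # incomplete trial cannot be consistently classed
        elif all(m > median for m in mags):
            label = "high_high"
        elif all(m <= median for m in mags):
            label = "low_low"
        else:
            label = "mixed"
        labels.append(AdjustmentLabel(trial_index, label))
    return labels


# ---------------------------------------------------------------------------
# Long-format TSV interchange (one row per feedback event)

LOG_COLUMNS = [
    "dyad_id", "participant_id", "block", "trial", "rep",
    "est_self", "est_peer", "orientation", "end_low", "end_high", "dot",
]


def session_to_frame(session: Session) -> pd.DataFrame:
    """Serialize a session to the long behavior-log format."""
    trial_map = {t.trial_index: t for t in session.trials}
    rows = []
    for ev in session.feedback:
        t = trial_map[ev.trial_index]
        rows.append(
            dict(
                dyad_id=session.dyad_id,
                participant_id=session.participant_id,
                block=t.block,
                trial=ev.trial_index,
                rep=ev.rep,
                est_self=ev.est_self,
                est_peer=ev.est_peer,
                orientation=t.orientation,
                end_low=t.endpoint_low,
                end_high=t.endpoint_high,
                dot=t.dot_position,
            )
        )
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


def sessions_from_frame(frame: pd.DataFrame) -> list[Session]:
    """Reconstruct sessions from a long behavior log (inverse of
    :func:`session_to_frame`); one session per participant_id."""
    missing = set(LOG_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"behavior log missing columns: {sorted(missing)}")
    sessions = []
    for pid, grp in frame.groupby("participant_id", sort=True):
        grp = grp.sort_values(["trial", "rep"])
        dyad_id = str(grp["dyad_id"].iloc[0])
        trials, seen = [], set()
        for _, row in grp.iterrows():
            if row["trial"] not in seen:
                seen.add(row["trial"])
                trials.append(
                    TrialSpec(
                        trial_index=int(row["trial"]),
                        block=int(row["block"]),
                        orientation=str(row["orientation"]),
                        endpoint_low=int(row["end_low"]),
                        endpoint_high=int(row["end_high"]),
                        dot_position=float(row["dot"]),
                    )
                )
        feedback = [
            FeedbackEvent(
                trial_index=int(r["trial"]),
                rep=int(r["rep"]),
                est_self=float(r["est_self"]),
                est_peer=float(r["est_peer"]),
            )
            for _, r in grp.iterrows()
        ]
        sessions.append(
            Session(
                participant_id=str(pid), dyad_id=dyad_id, role="A",
                trials=trials, feedback=feedback,
            )
        )
    return sessions


def write_behavior_tsv(sessions: list[Session], path) -> None:
    pd.concat([session_to_frame(s) for s in sessions]).to_csv(
        path, sep="\t", index=False
    )


def read_behavior_tsv(path) -> list[Session]:
    return sessions_from_frame(pd.read_csv(path, sep="\t"))
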