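"""Rapid event-related experimental design: trials, runs, and sessions.

The experiment presents short (3 s) videos in 4 s trials (3 s video + 1 s
inter-trial interval) interleaved with 4 s null trials at a 25% rate.  A
training set of videos is shown a few times each and a smaller testing set
many times each, distributed over sessions that each contain a fixed number
of training and testing runs.  This module builds such schedules with the
scheduling constraints of the study design (no video on consecutive trials,
no two testing runs back to back) and computes the volume arithmetic that
the simulator and the GLM rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Condition label used for null (fixation) trials in events tables.
NULL_CONDITION = "n/a"

TRIAL_S = 4.0
LEAD_IN_S = 4.0
TEST_LEAD_OUT_S = 13.0
TRAIN_LEAD_OUT_S = 12.5
ACQ_TR_S = 1.75


class InfeasibleConfigurationError(ValueError):
    """Counts do not tile into the requested sessions and runs."""


class ConstraintViolationError(RuntimeError):
    """An ordering constraint could not be satisfied within bounded retries."""


@dataclass(frozen=True)
class TrialEvent:
    onset_s: float
    duration_s: float
    condition_id: str | None  # None for null trials
    repetition_index: int  # 1-based; 0 for null trials

    @property
    def is_null(self) -> bool:
        return self.condition_id is None


@dataclass
class RunSchedule:
    run_type: str  # train | test | localizer | rest
    events: list[TrialEvent]
    lead_in_s: float
    lead_out_s: float
    tr_s: float
    n_volumes: int
    run_index: int = 0

    @property
    def duration_s(self) -> float:
        return self.lead_in_s + sum(e.duration_s for e in self.events) + self.lead_out_s

    def stimulus_events(self) -> list[TrialEvent]:
        return [e for e in self.events if not e.is_null]


@dataclass
class SessionSchedule:
    session_index: int  # 1-based
    runs: list[RunSchedule] = field(default_factory=list)


def compute_run_volumes(
    n_trials: int,
    trial_s: float,
    lead_in_s: float,
    lead_out_s: float,
    tr_s: float,
) -> int:
    """Number of acquisition volumes covering a run (ceiling division).

    For the canonical parameter sets the division is exact: a testing run of
    113 trials gives (4 + 113*4 + 13) / 1.75 = 268 volumes and a training run
    of 100 trials gives (4 + 100*4 + 12.5) / 1.75 = 238 volumes.
    """
    if n_trials <= 0 or trial_s <= 0 or tr_s <= 0:
        raise ValueError("trial count, trial duration and TR must be positive")
    if lead_in_s < 0 or lead_out_s < 0:
        raise ValueError("lead-in/lead-out must be non-negative")
    total = lead_in_s + n_trials * trial_s + lead_out_s
    return int(math.ceil(total / tr_s - 1e-9))


def _total_trials_for_stimuli(n_stim: int, null_fraction: float) -> int:
    """Smallest trial count n with n - round(null_fraction * n) == n_stim."""
    for n in range(n_stim, 2 * n_stim + 2):
        if n - int(math.floor(null_fraction * n + 0.5)) == n_stim:
            return n
    raise InfeasibleConfigurationError(
        f"no trial count realizes {n_stim} stimulus trials at null fraction {null_fraction}"
    )


def _assign_sessions(
    n_videos: int, reps: int, n_sessions: int, rng: np.random.Generator
) -> list[list[int]]:
    """Per-session presentation counts for each video, balanced exactly.

    Each video receives ``reps // n_sessions`` presentations in every session
    plus ``reps % n_sessions`` extras spread greedily so every session ends up
    with exactly ``n_videos * reps / n_sessions`` presentations.  With
    reps <= n_sessions no video repeats within a session.
    """
    base, extra = divmod(reps, n_sessions)
    counts = [[base] * n_sessions for _ in range(n_videos)]
    if extra:
        load = np.zeros(n_sessions, dtype=int)
        order = rng.permutation(n_videos)
        for v in order:
            # e least-loaded sessions; ties broken by session index
            chosen = np.lexsort((np.arange(n_sessions), load))[:extra]
            for s in chosen:
                counts[v][s] += 1
                load[s] += 1
    return counts


def _order_run_trials(
    stim: list[str], n_null: int, rng: np.random.Generator, max_attempts: int
) -> list[str | None]:
    """Randomize stimulus + null trial order, no video on consecutive trials."""
    seq: list[str | None] = list(stim) + [None] * n_null
    for _ in range(max_attempts):
        rng.shuffle(seq)
        ok = all(
            not (a is not None and a == b) for a, b in zip(seq, seq[1:])
        )
        if ok:
            return seq
    raise ConstraintViolationError(
        "could not order run trials without consecutive repeats"
    )


def _order_runs(
    n_test: int, n_train: int, rng: np.random.Generator, max_attempts: int
) -> list[str]:
    types = ["test"] * n_test + ["train"] * n_train
    if n_train == 0 or n_test <= 1:
        rng.shuffle(types)
        return types
    for _ in range(max_attempts):
        rng.shuffle(types)
        if all(not (a == b == "test") for a, b in zip(types, types[1:])):
            return types
    raise ConstraintViolationError("could not order runs without adjacent test runs")


def build_session_schedule(
    n_train_videos: int,
    n_test_videos: int,
    train_reps: int,
    test_reps: int,
    n_sessions: int,
    seed: int,
    *,
    train_runs_per_session: int = 10,
    test_runs_per_session: int = 3,
    null_fraction: float = 0.25,
    trial_s: float = TRIAL_S,
    lead_in_s: float = LEAD_IN_S,
    test_lead_out_s: float = TEST_LEAD_OUT_S,
    train_lead_out_s: float = TRAIN_LEAD_OUT_S,
    tr_s: float = ACQ_TR_S,
    max_attempts: int = 10_000,
) -> list[SessionSchedule]:
    """Build the full multi-session schedule for one participant.

    Every training video is scheduled exactly ``train_reps`` times and every
    testing video exactly ``test_reps`` times across sessions.  Null trials
    are inserted per run at ``round(null_fraction * n_trials)``.  The
    canonical configuration is (1000, 102, 3, 10, 4) with 10 training and 3
    testing runs per session.
    """
    rng = np.random.default_rng(seed)

    def per_run(n_videos: int, reps: int, runs_per_session: int, label: str) -> int:
        if n_videos == 0:
            return 0
        total = n_videos * reps
        if runs_per_session <= 0 or total % (n_sessions * runs_per_session):
            raise InfeasibleConfigurationError(
                f"{label}: {total} presentations do not tile into "
                f"{n_sessions} sessions x {runs_per_session} runs"
            )
        return total // (n_sessions * runs_per_session)

    stim_per_train_run = per_run(n_train_videos, train_reps, train_runs_per_session, "train")
    stim_per_test_run = per_run(n_test_videos, test_reps, test_runs_per_session, "test")
    if n_train_videos == 0:
        train_runs_per_session = 0
    if n_test_videos == 0:
        test_runs_per_session = 0

    train_ids = [f"train_{i:04d}" for i in range(n_train_videos)]
    test_ids = [f"test_{i:03d}" for i in range(n_test_videos)]
    train_counts = _assign_sessions(n_train_videos, train_reps, n_sessions, rng)
    test_counts = _assign_sessions(n_test_videos, test_reps, n_sessions, rng)

    sessions: list[SessionSchedule] = []
    for s in range(n_sessions):
        train_pool = [vid for v, vid in enumerate(train_ids) for _ in range(train_counts[v][s])]
        test_pool = [vid for v, vid in enumerate(test_ids) for _ in range(test_counts[v][s])]
        rng.shuffle(train_pool)
        rng.shuffle(test_pool)

        run_types = _order_runs(test_runs_per_session, train_runs_per_session, rng, max_attempts)
        session = SessionSchedule(session_index=s + 1)
        ti = ei = 0
        for r, rtype in enumerate(run_types):
            if rtype == "test":
                stim = test_pool[ei : ei + stim_per_test_run]
                ei += stim_per_test_run
                lead_out = test_lead_out_s
            else:
                stim = train_pool[ti : ti + stim_per_train_run]
                ti += stim_per_train_run
                lead_out = train_lead_out_s
            n_total = _total_trials_for_stimuli(len(stim), null_fraction)
            seq = _order_run_trials(stim, n_total - len(stim), rng, max_attempts)
            events = [
                TrialEvent(
                    onset_s=lead_in_s + j * trial_s,
                    duration_s=trial_s,
                    condition_id=c,
                    repetition_index=0,
                )
                for j, c in enumerate(seq)
            ]
            session.runs.append(
                RunSchedule(
                    run_type=rtype,
                    events=events,
                    lead_in_s=lead_in_s,
                    lead_out_s=lead_out,
                    tr_s=tr_s,
                    n_volumes=compute_run_volumes(n_total, trial_s, lead_in_s, lead_out, tr_s),
                    run_index=r + 1,
                )
            )
        sessions.append(session)

    _assign_repetition_indices(sessions)
    return sessions


def _assign_repetition_indices(sessions: list[SessionSchedule]) -> None:
    seen: dict[str, int] = {}
    for sess in sessions:
        for run in sess.runs:
            new_events = []
            for e in run.events:
                if e.is_null:
                    new_events.append(e)
                    continue
                seen[e.condition_id] = seen.get(e.condition_id, 0) + 1
                new_events.append(
                    TrialEvent(e.onset_s, e.duration_s, e.condition_id, seen[e.condition_id])
                )
            run.events = new_events


def count_trials(
    schedules: list[SessionSchedule],
    scope: str = "per_participant",
    n_subjects: int = 1,
):
    """Count stimulus (non-null) presentations.

    scope='per_session' returns a DataFrame (session x {train, test, total});
    'per_participant' the total stimulus presentations for one participant;
    'total' that number multiplied by ``n_subjects``.
    """
    if not schedules or all(not s.runs for s in schedules):
        raise ValueError("empty schedule")
    rows = []
    for sess in schedules:
        ntr = sum(len(r.stimulus_events()) for r in sess.runs if r.run_type == "train")
        nte = sum(len(r.stimulus_events()) for r in sess.runs if r.run_type == "test")
        rows.append({"session": sess.session_index, "train": ntr, "test": nte, "total": ntr + nte})
    table = pd.DataFrame(rows).set_index("session")
    if scope == "per_session":
        return table
    per_participant = int(table["total"].sum())
    if scope == "per_participant":
        return per_participant
    if scope == "total":
        return per_participant * n_subjects
    raise ValueError(f"unknown scope {scope!r}")


def events_frame(run: RunSchedule, session_index: int) -> pd.DataFrame:
    """One run's events as a BIDS-events-like table."""
    return pd.DataFrame(
        {
            "onset": [round(e.onset_s, 3) for e in run.events],
            "duration": [e.duration_s for e in run.events],
            "condition": [NULL_CONDITION if e.is_null else e.condition_id for e in run.events],
            "repetition": [e.repetition_index for e in run.events],
            "run": run.run_index,
            "session": session_index,
        }
    )


def write_events_tables(schedules: list[SessionSchedule], out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sess in schedules:
        for run in sess.runs:
            path = out_dir / f"ses-{sess.session_index:02d}_run-{run.run_index:02d}_events.tsv"
            events_frame(run, sess.session_index).to_csv(
                path, sep="\t", index=False, float_format="%.3f"
            )
            paths.append(path)
    return paths


def canonical_schedule(seed: int = 0) -> list[SessionSchedule]:
    """The full-scale participant schedule: 1000 training videos x 3 reps,
    102 testing videos x 10 reps, 4 sessions of 10 training + 3 testing runs."""
    return build_session_schedule(1000, 102, 3, 10, 4, seed)
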