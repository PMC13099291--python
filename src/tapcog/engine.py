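"""Event-driven session engine.

The engine consumes a planned schedule and an ordered stream of tap events
and emits one outcome per trial plus a replayable event log. Its input
contract is the debouncing rule that fixed a field-testing defect in the
choice tasks, where a second rapid tap could register as the response to
the *next* stimulus before it appeared, yielding impossibly fast reaction
times (~79 ms):

* response keys are inactive before stimulus onset — any pre-onset tap is
  counted as suppressed, never as a response;
* the first valid in-window tap is the trial's single response; every later
  tap in the same trial is suppressed;
* suppressed taps never carry into subsequent trials.

Timestamps are integer milliseconds from session start and must be
non-decreasing. The trial timeline is a pure function of the schedule
(a trial always closes at ``onset + response_window``), so replaying a
log's tap stream reproduces its outcomes exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

from .config import TaskKind, TASK_ORDER
from .schedule import BatterySchedule, TrialSpec

#: Keys a respondent can legally press during each task; taps on other
#: keys are logged and suppressed (touch noise), not errors.
KEYS_BY_TASK = {
    TaskKind.SVRT: frozenset({"stimulus_area"}),
    TaskKind.GONOGO: frozenset({"stimulus_area"}),
    TaskKind.VISUAL_RECOGNITION: frozenset({"yes", "no"}),
    TaskKind.SIMON: frozenset({"left", "right"}),
    TaskKind.INTERFERENCE: frozenset({"left", "right"}),
}

CLASSIFICATIONS = ("hit", "correct_rejection", "omission", "false_alarm", "wrong_key")


class InputError(ValueError):
    """Raised for malformed tap streams (e.g. decreasing timestamps)."""


class IntegrityError(RuntimeError):
    """Raised when a log fails replay verification."""


@dataclass(frozen=True)
class InputEvent:
    timestamp_ms: int
    kind: str  # tap | stimulus_onset | stimulus_offset | trial_open | trial_close | block_start
    key: Optional[str] = None  # taps only
    trial_index: Optional[int] = None  # non-tap events
    task: Optional[TaskKind] = None


@dataclass(frozen=True)
class TrialOutcome:
    """Classification of a single trial.

    Carries enough schedule context (task, block, target/congruency flags)
    that scoring needs no side lookup into the schedule.
    """

    trial_index: int
    task: TaskKind
    responded: bool
    response_key: Optional[str]
    rt_ms: Optional[int]
    classification: str
    n_suppressed_taps: int = 0
    block_index: int = 0
    is_target: bool = True
    congruent: Optional[bool] = None


@dataclass
class EventLog:
    """Replayable record of one session: events in time order plus outcomes."""

    session_id: str
    seed: int
    schedule: BatterySchedule
    events: list[InputEvent] = field(default_factory=list)
    outcomes: list[TrialOutcome] = field(default_factory=list)

    def taps(self) -> list[InputEvent]:
        return [e for e in self.events if e.kind == "tap"]


@dataclass(frozen=True)
class TrialWindow:
    """Absolute timing of one trial within the session, in ms."""

    trial: TrialSpec
    open_ms: int
    onset_ms: int
    close_ms: int


def build_timeline(schedule: BatterySchedule) -> list[TrialWindow]:
    """Lay the battery's trials end to end on an absolute ms clock.

    Each trial opens when the previous one closes, its stimulus appears
    ``onset_delay_s`` later, and it closes ``response_window_s`` after
    onset regardless of responding.
    """
    timeline: list[TrialWindow] = []
    t = 0
    for task in TASK_ORDER:
        for trial in schedule.trials[task]:
            open_ms = t
            onset_ms = open_ms + round(trial.onset_delay_s * 1000)
            close_ms = onset_ms + round(trial.response_window_s * 1000)
            timeline.append(TrialWindow(trial, open_ms, onset_ms, close_ms))
            t = close_ms
    return timeline


def classify_response(trial: TrialSpec, key: str, rt_ms: int) -> str:
    """Classify a registered in-window response for any task."""
    if trial.task is TaskKind.SVRT:
        return "hit"
    if trial.task is TaskKind.GONOGO:
        return "hit" if trial.stimulus.is_target else "false_alarm"
    if trial.task is TaskKind.VISUAL_RECOGNITION:
        if key == trial.correct_key:
            return "hit"
        return "false_alarm" if key == "yes" else "wrong_key"
    # Simon / interference: correct key per the trial's block rule
    return "hit" if key == trial.correct_key else "wrong_key"


def classify_no_response(trial: TrialSpec) -> str:
    """Classify a trial with no in-window tap."""
    if trial.task is TaskKind.GONOGO and not trial.stimulus.is_target:
        return "correct_rejection"
    return "omission"


def run_session(
    schedule: BatterySchedule,
    tap_stream: Iterable[InputEvent],
    session_id: str = "session",
    seed: int = 0,
) -> EventLog:
    """Run a tap stream through the battery and classify every trial.

    Raises :class:`InputError` on decreasing timestamps. Taps before a
    trial's onset, after its response, after its window closes, or on keys
    the task does not define are suppressed and counted, never classified.
    """
    taps = [e for e in tap_stream if e.kind == "tap"]
    for e in taps:
        if e.key is None:
            raise InputError(f"tap at {e.timestamp_ms} ms carries no key")
    for a, b in zip(taps, taps[1:]):
        if b.timestamp_ms < a.timestamp_ms:
            raise InputError(
                f"tap timestamps decrease: {a.timestamp_ms} → {b.timestamp_ms} ms"
            )

    timeline = build_timeline(schedule)
    outcomes: list[TrialOutcome] = []
    events: list[InputEvent] = []
    ti = 0  # tap pointer
    prev_block: dict[TaskKind, int] = {}

    for win in timeline:
        trial = win.trial
        task = trial.task
        if prev_block.get(task) != trial.block_index:
            prev_block[task] = trial.block_index
            events.append(
                InputEvent(
                    timestamp_ms=win.open_ms,
                    kind="block_start",
                    trial_index=trial.trial_index,
                    task=task,
                )
            )
        events.append(
            InputEvent(win.open_ms, "trial_open", trial_index=trial.trial_index, task=task)
        )
        events.append(
            InputEvent(
                win.onset_ms, "stimulus_onset", trial_index=trial.trial_index, task=task
            )
        )

        responded = False
        response_key: Optional[str] = None
        rt_ms: Optional[int] = None
        n_suppressed = 0
        valid_keys = KEYS_BY_TASK[task]

        while ti < len(taps) and taps[ti].timestamp_ms < win.close_ms:
            tap = taps[ti]
            ti += 1
            events.append(tap)
            if tap.timestamp_ms < win.onset_ms:
                n_suppressed += 1  # key inactive before onset
            elif responded:
                n_suppressed += 1  # single-response law
            elif tap.key not in valid_keys:
                n_suppressed += 1  # undefined key: logged, never a response
            else:
                responded = True
                response_key = tap.key
                rt_ms = tap.timestamp_ms - win.onset_ms

        if responded:
            classification = classify_response(trial, response_key, rt_ms)
        else:
            classification = classify_no_response(trial)

        events.append(
            InputEvent(
                win.close_ms, "stimulus_offset", trial_index=trial.trial_index, task=task
            )
        )
        events.append(
            InputEvent(
                win.close_ms, "trial_close", trial_index=trial.trial_index, task=task
            )
        )
        outcomes.append(
            TrialOutcome(
                trial_index=trial.trial_index,
                task=task,
                responded=responded,
                response_key=response_key,
                rt_ms=rt_ms,
                classification=classification,
                n_suppressed_taps=n_suppressed,
                block_index=trial.block_index,
                is_target=trial.stimulus.is_target,
                congruent=trial.stimulus.congruent,
            )
        )

    # taps after the last trial window: logged, never classified
    while ti < len(taps):
        events.append(taps[ti])
        ti += 1

    events.sort(key=lambda e: e.timestamp_ms)
    return EventLog(
        session_id=session_id, seed=seed, schedule=schedule,
        events=events, outcomes=outcomes,
    )


def replay(log: EventLog, strict: bool = True) -> EventLog:
    """Re-run a log's tap stream through the engine.

    With ``strict`` (default), raises :class:`IntegrityError` if the
    recomputed outcomes differ from the stored ones — the determinism
    regression check for recorded sessions.
    """
    new = run_session(log.schedule, log.taps(), session_id=log.session_id, seed=log.seed)
    if strict and new.outcomes != log.outcomes:
        diffs = [
            i for i, (a, b) in enumerate(zip(new.outcomes, log.outcomes)) if a != b
        ]
        raise IntegrityError(
            f"replay mismatch in {len(diffs)} trial(s), first at index "
            f"{diffs[0] if diffs else len(new.outcomes)}"
        )
    return new


def outcome_to_dict(o: TrialOutcome) -> dict:
    d = asdict(o)
    d["task"] = o.task.value
    return d


def event_to_dict(e: InputEvent) -> dict:
    d = asdict(e)
    d["task"] = e.task.value if e.task is not None else None
    return d
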