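"""Per-task and battery-level performance metrics.

Reaction-time aggregates use hit trials only (wrong-key presses and false
alarms are excluded from RT means, the standard convention). No outlier
trimming is applied by default — the engine already forbids pre-onset
responses — but optional trim bounds are available on every scorer.

Interference contrasts:

* Simon: mean RT(incongruent hits) − mean RT(congruent hits), and the
  corresponding error-rate difference;
* interference task: block 2 (reversed rule) versus blocks 0–1 pooled
  (both congruent-rule blocks), same two contrasts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np

from .config import TaskKind, TASK_ORDER
from .engine import EventLog, TrialOutcome
from .schedule import VRSequence


class ScoringError(RuntimeError):
    """Raised for structurally invalid outcome sets (e.g. a missing block)."""


@dataclass(frozen=True)
class TaskScore:
    task: TaskKind
    n_trials: int
    mean_rt_ms: Optional[float]
    median_rt_ms: Optional[float]
    n_hits: int
    n_omissions: int
    n_false_alarms: int
    n_wrong_key: int
    n_correct_rejections: int
    accuracy: Optional[float] = None  # visual recognition only
    interference_effect_ms: Optional[float] = None  # Simon / interference only
    interference_error_cost: Optional[float] = None
    per_block_accuracy: Optional[tuple[float, ...]] = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["task"] = self.task.value
        return d


@dataclass(frozen=True)
class BatteryReport:
    session_id: str
    participant_id: Optional[str]
    scores: tuple[TaskScore, ...]
    complete: bool
    total_duration_min: float

    def to_dict(self) -> dict:
        return {
            "session_id": self.session_id,
            "participant_id": self.participant_id,
            "complete": self.complete,
            "total_duration_min": self.total_duration_min,
            "scores": [s.to_dict() for s in self.scores],
        }


def _check_task(outcomes: Sequence[TrialOutcome], task: TaskKind) -> None:
    bad = [o.task for o in outcomes if o.task is not task]
    if bad:
        raise ScoringError(f"expected only {task.value} outcomes, found {bad[0].value}")


def _hit_rts(
    outcomes: Sequence[TrialOutcome],
    trim_ms: Optional[tuple[float, float]],
) -> np.ndarray:
    rts = np.array(
        [o.rt_ms for o in outcomes if o.classification == "hit"], dtype=float
    )
    if trim_ms is not None and rts.size:
        lo, hi = trim_ms
        rts = rts[(rts >= lo) & (rts <= hi)]
    return rts


def _counts(outcomes: Sequence[TrialOutcome]) -> dict[str, int]:
    c = {k: 0 for k in ("hit", "correct_rejection", "omission", "false_alarm", "wrong_key")}
    for o in outcomes:
        c[o.classification] += 1
    return c


def _base_score(
    outcomes: Sequence[TrialOutcome],
    task: TaskKind,
    trim_ms: Optional[tuple[float, float]] = None,
    **extra,
) -> TaskScore:
    c = _counts(outcomes)
    rts = _hit_rts(outcomes, trim_ms)
    return TaskScore(
        task=task,
        n_trials=len(outcomes),
        mean_rt_ms=float(np.mean(rts)) if rts.size else None,
        median_rt_ms=float(np.median(rts)) if rts.size else None,
        n_hits=c["hit"],
        n_omissions=c["omission"],
        n_false_alarms=c["false_alarm"],
        n_wrong_key=c["wrong_key"],
        n_correct_rejections=c["correct_rejection"],
        **extra,
    )


def score_svrt(
    outcomes: Sequence[TrialOutcome],
    trim_ms: Optional[tuple[float, float]] = None,
) -> TaskScore:
    """Mean/median RT over responded trials plus the omission count.

    An all-omission session yields undefined RT fields, not an error.
    """
    _check_task(outcomes, TaskKind.SVRT)
    return _base_score(outcomes, TaskKind.SVRT, trim_ms)


def score_gonogo(
    outcomes: Sequence[TrialOutcome],
    trim_ms: Optional[tuple[float, float]] = None,
) -> TaskScore:
    """RT over hits; omissions on targets, false alarms on non-targets."""
    _check_task(outcomes, TaskKind.GONOGO)
    return _base_score(outcomes, TaskKind.GONOGO, trim_ms)


def score_vr(
    outcomes: Sequence[TrialOutcome],
    sequences: Optional[Sequence[VRSequence]] = None,
) -> TaskScore:
    """Recognition accuracy: correct yes/no responses over all probes.

    If ``sequences`` are supplied, the probe count is cross-checked and
    per-sequence accuracies are reported.
    """
    _check_task(outcomes, TaskKind.VISUAL_RECOGNITION)
    if sequences is not None:
        n_probes = sum(len(s.probe_ids) for s in sequences)
        if n_probes != len(outcomes):
            raise ScoringError(
                f"probe/outcome misalignment: {n_probes} probes, "
                f"{len(outcomes)} outcomes"
            )
    n = len(outcomes)
    n_correct = sum(o.classification == "hit" for o in outcomes)
    per_block = None
    if sequences is not None:
        per_block = []
        for s in sequences:
            blk = [o for o in outcomes if o.block_index == s.sequence_index - 1]
            per_block.append(
                sum(o.classification == "hit" for o in blk) / len(blk) if blk else math.nan
            )
        per_block = tuple(per_block)
    return _base_score(
        outcomes,
        TaskKind.VISUAL_RECOGNITION,
        None,
        accuracy=n_correct / n if n else None,
        per_block_accuracy=per_block,
    )


def _contrast(
    base: Sequence[TrialOutcome], conflict: Sequence[TrialOutcome]
) -> tuple[Optional[float], Optional[float]]:
    rt_base = [o.rt_ms for o in base if o.classification == "hit"]
    rt_conf = [o.rt_ms for o in conflict if o.classification == "hit"]
    effect = (
        float(np.mean(rt_conf) - np.mean(rt_base))
        if rt_base and rt_conf
        else None
    )
    err_base = sum(o.classification != "hit" for o in base) / len(base)
    err_conf = sum(o.classification != "hit" for o in conflict) / len(conflict)
    return effect, err_conf - err_base


def score_simon(
    outcomes: Sequence[TrialOutcome],
    trim_ms: Optional[tuple[float, float]] = None,
) -> TaskScore:
    """Simon congruency contrast: incongruent − congruent, RT and errors.

    Requires both congruency levels; a level with zero hits leaves the RT
    effect undefined (None) while the error cost is still reported.
    """
    _check_task(outcomes, TaskKind.SIMON)
    congruent = [o for o in outcomes if o.congruent is True]
    incongruent = [o for o in outcomes if o.congruent is False]
    if not congruent or not incongruent:
        raise ScoringError("Simon scoring needs both congruency levels")
    effect, err_cost = _contrast(congruent, incongruent)
    return _base_score(
        outcomes,
        TaskKind.SIMON,
        trim_ms,
        interference_effect_ms=effect,
        interference_error_cost=err_cost,
    )


def score_interference(
    outcomes: Sequence[TrialOutcome],
    trim_ms: Optional[tuple[float, float]] = None,
    baseline: str = "pooled",
) -> TaskScore:
    """Rule-reversal contrast: block 2 versus the congruent-rule baseline.

    ``baseline="pooled"`` (default) pools blocks 0–1; ``baseline="first"``
    uses block 0 only. A missing block raises :class:`ScoringError`.
    """
    _check_task(outcomes, TaskKind.INTERFERENCE)
    blocks = {b: [o for o in outcomes if o.block_index == b] for b in (0, 1, 2)}
    missing = [b for b, blk in blocks.items() if not blk]
    if missing:
        raise ScoringError(f"interference block(s) missing: {missing}")
    base = blocks[0] if baseline == "first" else blocks[0] + blocks[1]
    effect, err_cost = _contrast(base, blocks[2])
    return _base_score(
        outcomes,
        TaskKind.INTERFERENCE,
        trim_ms,
        interference_effect_ms=effect,
        interference_error_cost=err_cost,
    )


_SCORERS = {
    TaskKind.SVRT: score_svrt,
    TaskKind.GONOGO: score_gonogo,
    TaskKind.SIMON: score_simon,
    TaskKind.INTERFERENCE: score_interference,
}


def summarize_battery(
    log: EventLog, participant_id: Optional[str] = None
) -> BatteryReport:
    """Score all five tasks of a session and report total duration.

    An incomplete session (a task without outcomes, or an unscorable task)
    yields a report with ``complete=False`` and whatever scores exist.
    """
    by_task = {
        task: [o for o in log.outcomes if o.task is task] for task in TASK_ORDER
    }
    scores: list[TaskScore] = []
    complete = True
    for task in TASK_ORDER:
        outs = by_task[task]
        if not outs:
            complete = False
            continue
        try:
            if task is TaskKind.VISUAL_RECOGNITION:
                scores.append(score_vr(outs, log.schedule.vr_sequences))
            else:
                scores.append(_SCORERS[task](outs))
        except ScoringError:
            complete = False
    if log.events:
        duration = (log.events[-1].timestamp_ms - log.events[0].timestamp_ms) / 60_000
    else:
        duration = 0.0
        complete = False
    return BatteryReport(
        session_id=log.session_id,
        participant_id=participant_id,
        scores=tuple(scores),
        complete=complete,
        total_duration_min=duration,
    )
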