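"""File formats: schedule JSON, event-log JSONL, cohort CSV, run manifests.

All formats are open text. Event logs are JSON-lines with a header record
followed by one record per input event and per trial outcome, so sessions
are diff-able and replayable. Every reader validates on load and reports
the offending line or row in its error message.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import __version__
from .config import BatteryConfig, TaskKind
from .engine import (
    EventLog,
    InputEvent,
    TrialOutcome,
    event_to_dict,
    outcome_to_dict,
)
from .schedule import BatterySchedule, StimulusSpec, TrialSpec, VRSequence

PathLike = Union[str, Path]


class ValidationError(ValueError):
    """Raised when a file fails schema validation."""


# -- schedules ---------------------------------------------------------------

def write_schedule(schedule: BatterySchedule, path: PathLike) -> None:
    Path(path).write_text(schedule.to_json())


def _stimulus_from_dict(d: dict) -> StimulusSpec:
    d = dict(d)
    if d.get("image_ids") is not None:
        d["image_ids"] = tuple(d["image_ids"])
    return StimulusSpec(**d)


def _trial_from_dict(d: dict) -> TrialSpec:
    d = dict(d)
    d["task"] = TaskKind(d["task"])
    d["stimulus"] = _stimulus_from_dict(d["stimulus"])
    if d.get("key_layout") is not None:
        d["key_layout"] = tuple(d["key_layout"])
    return TrialSpec(**d)


def schedule_from_dict(d: dict) -> BatterySchedule:
    try:
        config = BatteryConfig(**d["config"])
        trials = {
            TaskKind(task): tuple(_trial_from_dict(t) for t in ts)
            for task, ts in d["trials"].items()
        }
        sequences = tuple(
            VRSequence(
                sequence_index=s["sequence_index"],
                encoding_ids=tuple(s["encoding_ids"]),
                display_duration_s=s["display_duration_s"],
                probe_ids=tuple(s["probe_ids"]),
                probe_truth=tuple(s["probe_truth"]),
                version=s["version"],
            )
            for s in d["vr_sequences"]
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValidationError(f"malformed schedule document: {exc}") from exc
    return BatterySchedule(
        seed=d["seed"], config=config, trials=trials, vr_sequences=sequences
    )


def read_schedule(path: PathLike) -> BatterySchedule:
    return schedule_from_dict(json.loads(Path(path).read_text()))


# -- event logs --------------------------------------------------------------

def write_eventlog(log: EventLog, path: PathLike) -> None:
    with open(path, "w") as fh:
        header = {
            "type": "header",
            "session_id": log.session_id,
            "seed": log.seed,
            "schedule": log.schedule.to_dict(),
        }
        fh.write(json.dumps(header) + "\n")
        for e in log.events:
            fh.write(json.dumps({"type": "event", **event_to_dict(e)}) + "\n")
        for o in log.outcomes:
            fh.write(json.dumps({"type": "outcome", **outcome_to_dict(o)}) + "\n")


def read_eventlog(path: PathLike) -> EventLog:
    events: list[InputEvent] = []
    outcomes: list[TrialOutcome] = []
    header: Optional[dict] = None
    last_ts = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"line {lineno}: invalid JSON: {exc}") from exc
            kind = rec.pop("type", None)
            if kind == "header":
                header = rec
            elif kind == "event":
                if rec.get("task") is not None:
                    rec["task"] = TaskKind(rec["task"])
                ev = InputEvent(**rec)
                if last_ts is not None and ev.timestamp_ms < last_ts:
                    raise ValidationError(
                        f"line {lineno}: timestamps decrease "
                        f"({last_ts} → {ev.timestamp_ms} ms)"
                    )
                last_ts = ev.timestamp_ms
                events.append(ev)
            elif kind == "outcome":
                rec["task"] = TaskKind(rec["task"])
                outcomes.append(TrialOutcome(**rec))
            else:
                raise ValidationError(f"line {lineno}: unknown record type {kind!r}")
    if header is None:
        raise ValidationError("event log has no header record")
    return EventLog(
        session_id=header["session_id"],
        seed=header["seed"],
        schedule=schedule_from_dict(header["schedule"]),
        events=events,
        outcomes=outcomes,
    )


# -- cohort tables -----------------------------------------------------------

_SUS_ITEM_COLS = [f"sus_q{i}" for i in range(1, 11)]


def read_cohort_csv(path: PathLike) -> pd.DataFrame:
    """Load a participant cohort table.

    Expects one row per participant with either a precomputed ``sus``
    column or item columns ``sus_q1..sus_q10`` (integers 1–5), plus any of
    ``age``, ``education_years``/``education``, ``moca``. Items are scored
    into a ``sus`` column on load.
    """
    from .usability import score_sus

    df = pd.read_csv(path)
    if "education_years" in df.columns and "education" not in df.columns:
        df = df.rename(columns={"education_years": "education"})
    has_items = all(c in df.columns for c in _SUS_ITEM_COLS)
    if not has_items and "sus" not in df.columns:
        raise ValidationError(
            "cohort CSV needs either a 'sus' column or sus_q1..sus_q10"
        )
    if has_items:
        scores = []
        for idx, row in df.iterrows():
            items = [row[c] for c in _SUS_ITEM_COLS]
            try:
                scores.append(score_sus([int(v) for v in items]))
            except (ValueError, TypeError) as exc:
                raise ValidationError(f"row {idx + 2}: {exc}") from exc  # +2: header + 1-based
        df["sus"] = scores
    bad = df.index[(df["sus"] < 0) | (df["sus"] > 100)].tolist()
    if bad:
        raise ValidationError(f"row {bad[0] + 2}: sus score out of [0, 100]")
    return df


def write_cohort_csv(records, path: PathLike) -> None:
    pd.DataFrame([asdict(r) for r in records]).rename(
        columns={"sus_score": "sus", "education": "education_years"}
    ).to_csv(path, index=False)


def write_report_csv(report, path: PathLike) -> None:
    """One row per task score plus a battery summary row."""
    rows = [s.to_dict() for s in report.scores]
    for r in rows:
        r["per_block_accuracy"] = (
            ";".join(f"{a:.3f}" for a in r["per_block_accuracy"])
            if r.get("per_block_accuracy")
            else None
        )
    summary = {k: None for k in rows[0]} if rows else {}
    summary.update(
        task="battery",
        n_trials=sum(s.n_trials for s in report.scores),
    )
    df = pd.DataFrame(rows + [summary])
    df["session_id"] = report.session_id
    df["complete"] = report.complete
    df["total_duration_min"] = report.total_duration_min
    df.to_csv(path, index=False)


# -- run manifests -----------------------------------------------------------

def write_manifest(
    path: PathLike,
    command: str,
    seed: Optional[int],
    inputs: dict[str, str],
    outputs: dict[str, str],
    config: Optional[BatteryConfig] = None,
) -> None:
    """Record what a CLI invocation did: version, seeds, config hash, paths."""
    config_hash = None
    if config is not None:
        config_hash = hashlib.sha256(
            json.dumps(config.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]
    manifest = {
        "tool": "tapcog",
        "version": __version__,
        "command": command,
        "seed": seed,
        "config_sha256": config_hash,
        "inputs": inputs,
        "outputs": outputs,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(manifest, indent=1))
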