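"""Deterministic, seeded trial schedules for the five subtests.

A schedule is the full planned stimulus timeline of a battery before any
respondent interacts with it: per-trial onset delays, stimulus identities,
congruency flags, block rules, and (for visual recognition) the encoding
sequences and their probe sets. Schedules are pure functions of
``(config, seed)``: the same pair always serializes byte-for-byte
identically, which is the regression anchor for everything downstream.

Randomness is split into independent per-task substreams derived from the
battery seed, so changing one task's parameters never perturbs another
task's draws.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .config import BatteryConfig, TaskKind, TASK_ORDER

#: Fixed substream index per task (battery seed + this index seeds the task rng).
_TASK_STREAM = {
    TaskKind.SVRT: 11,
    TaskKind.GONOGO: 23,
    TaskKind.VISUAL_RECOGNITION: 37,
    TaskKind.SIMON: 53,
    TaskKind.INTERFERENCE: 71,
}

#: Abstract image identifiers available per alternate form of visual recognition.
IMAGE_POOL_SIZE = 128

#: Gap between successive recognition probes, and after sequence encoding,
#: in seconds. Probes are self-paced in deployment; a short fixed gap keeps
#: the planned timeline deterministic.
VR_PROBE_GAP_S = 0.5

#: Inter-trial delay for the self-paced Simon and interference tasks (s).
CHOICE_TASK_DELAY_S = 1.0


class GenerationError(RuntimeError):
    """Raised when a schedule cannot be generated (e.g. image pool exhausted)."""


@dataclass(frozen=True)
class StimulusSpec:
    """What appears on screen for one trial."""

    shape: str  # circle | square | image_set | colored_square
    color: str  # blue | yellow | red | green | none
    side: str  # left | right | center
    is_target: bool
    congruent: Optional[bool] = None  # Simon / interference only
    image_ids: Optional[tuple[str, ...]] = None  # visual recognition only
    display_duration_s: Optional[float] = None


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial: timing, stimulus, and (choice tasks) the response rule."""

    trial_index: int
    task: TaskKind
    onset_delay_s: float
    stimulus: StimulusSpec
    response_window_s: float
    block_index: int = 0
    correct_key: Optional[str] = None  # left|right|yes|no; None for sVRT/Go-No-Go taps
    key_layout: Optional[tuple[str, str]] = None  # (left key color, right key color)


@dataclass(frozen=True)
class VRSequence:
    """One visual-recognition sequence: encoding list plus probe set.

    ``probe_truth[i]`` is True iff ``probe_ids[i]`` appeared in
    ``encoding_ids``. Probe sets contain every encoded item plus
    ``ceil(len/2)`` distractors, shuffled.
    """

    sequence_index: int  # 1-based
    encoding_ids: tuple[str, ...]
    display_duration_s: float
    probe_ids: tuple[str, ...]
    probe_truth: tuple[bool, ...]
    version: str


@dataclass(frozen=True)
class BatterySchedule:
    """Complete planned battery: per-task trial lists plus VR sequences."""

    seed: int
    config: BatteryConfig
    trials: dict[TaskKind, tuple[TrialSpec, ...]] = field(default_factory=dict)
    vr_sequences: tuple[VRSequence, ...] = ()

    def all_trials(self) -> list[TrialSpec]:
        """Trials of every task concatenated in administration order."""
        return [t for task in TASK_ORDER for t in self.trials[task]]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": self.config.model_dump(),
            "trials": {
                task.value: [_trial_to_dict(t) for t in self.trials[task]]
                for task in TASK_ORDER
            },
            "vr_sequences": [asdict(s) for s in self.vr_sequences],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=False)


def _trial_to_dict(t: TrialSpec) -> dict:
    d = asdict(t)
    d["task"] = t.task.value
    return d


def _task_rng(seed: int, task: TaskKind) -> np.random.Generator:
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    return np.random.default_rng([seed, _TASK_STREAM[task]])


def generate_svrt_schedule(
    config: BatteryConfig, seed: int
) -> list[TrialSpec]:
    """Simple visual reaction time: a blue circle turns yellow after a
    uniform 4–8 s delay; every trial is a response trial."""
    rng = _task_rng(seed, TaskKind.SVRT)
    lo, hi = config.svrt_interval_range_s
    delays = rng.uniform(lo, hi, size=config.svrt_n_trials)
    return [
        TrialSpec(
            trial_index=i,
            task=TaskKind.SVRT,
            onset_delay_s=float(delays[i]),
            stimulus=StimulusSpec(
                shape="circle", color="yellow", side="center", is_target=True
            ),
            response_window_s=config.response_window_s,
        )
        for i in range(config.svrt_n_trials)
    ]


def generate_gonogo_schedule(
    config: BatteryConfig, seed: int
) -> list[TrialSpec]:
    """Go/No-Go: squares are targets, circles must be withheld.

    Target count is ``round(fraction * n)``; order is shuffled by the seed.
    Inter-trial delays reuse the sVRT uniform range.
    """
    rng = _task_rng(seed, TaskKind.GONOGO)
    n = config.gonogo_n_trials
    n_targets = round(config.gonogo_target_fraction * n)
    is_target = np.zeros(n, dtype=bool)
    is_target[:n_targets] = True
    rng.shuffle(is_target)
    lo, hi = config.svrt_interval_range_s
    delays = rng.uniform(lo, hi, size=n)
    return [
        TrialSpec(
            trial_index=i,
            task=TaskKind.GONOGO,
            onset_delay_s=float(delays[i]),
            stimulus=StimulusSpec(
                shape="square" if is_target[i] else "circle",
                color="none",
                side="center",
                is_target=bool(is_target[i]),
            ),
            response_window_s=config.response_window_s,
        )
        for i in range(n)
    ]


def _vr_lengths(n_sequences: int) -> list[int]:
    # Lengths grow 2, 3, ..., capped at 8; the default eight sequences give
    # (2, 3, 4, 5, 6, 7, 8, 8).
    return [min(i + 2, 8) for i in range(n_sequences)]


def generate_vr_schedule(config: BatteryConfig, seed: int) -> list[VRSequence]:
    """Visual recognition: sequences of abstract image IDs with yes/no probes.

    Sequence lengths follow the 2→8 progression; display durations
    interpolate linearly over the configured range. Alternate forms A and B
    share all structure (lengths, durations, probe order, truth pattern) but
    draw from disjoint identifier pools.
    """
    rng = _task_rng(seed, TaskKind.VISUAL_RECOGNITION)
    n = config.vr_n_sequences
    lengths = _vr_lengths(n)
    lo, hi = config.vr_duration_range_s
    durations = np.linspace(lo, hi, n) if n > 1 else np.array([lo])

    needed = sum(length + math.ceil(length / 2) for length in lengths)
    if needed > IMAGE_POOL_SIZE:
        raise GenerationError(
            f"image pool exhausted: {needed} identifiers needed, "
            f"{IMAGE_POOL_SIZE} available per form"
        )

    version = config.vr_version
    next_id = 0
    sequences: list[VRSequence] = []
    for si, length in enumerate(lengths):
        n_distractors = math.ceil(length / 2)
        block = [f"img_{version}_{next_id + k:03d}" for k in range(length + n_distractors)]
        next_id += length + n_distractors
        encoding = tuple(block[:length])
        distractors = block[length:]
        probes = list(encoding) + distractors
        truth = [True] * length + [False] * n_distractors
        order = rng.permutation(len(probes))
        sequences.append(
            VRSequence(
                sequence_index=si + 1,
                encoding_ids=encoding,
                display_duration_s=float(durations[si]),
                probe_ids=tuple(probes[k] for k in order),
                probe_truth=tuple(truth[k] for k in order),
                version=version,
            )
        )
    return sequences


def vr_probe_trials(
    sequences: Sequence[VRSequence], config: BatteryConfig
) -> list[TrialSpec]:
    """Flatten VR probe sets into trials the session engine can run.

    The first probe of each sequence is delayed by the sequence's encoding
    display duration plus a fixed gap; later probes follow at the fixed gap.
    ``block_index`` records the (0-based) sequence.
    """
    trials: list[TrialSpec] = []
    idx = 0
    for seq in sequences:
        for pi, (pid, truth) in enumerate(zip(seq.probe_ids, seq.probe_truth)):
            delay = VR_PROBE_GAP_S
            if pi == 0:
                delay += seq.display_duration_s
            trials.append(
                TrialSpec(
                    trial_index=idx,
                    task=TaskKind.VISUAL_RECOGNITION,
                    onset_delay_s=delay,
                    stimulus=StimulusSpec(
                        shape="image_set",
                        color="none",
                        side="center",
                        is_target=truth,
                        image_ids=(pid,),
                    ),
                    response_window_s=config.response_window_s,
                    block_index=seq.sequence_index - 1,
                    correct_key="yes" if truth else "no",
                )
            )
            idx += 1
    return trials


#: Color → response-key mapping of the standard Simon rule.
SIMON_KEY_FOR_COLOR = {"green": "left", "red": "right"}


def generate_simon_schedule(config: BatteryConfig, seed: int) -> list[TrialSpec]:
    """Simon task: color determines the key, position creates the conflict.

    Congruent trials place the stimulus on its key's side; incongruent
    trials on the opposite side. Colors are balanced within each congruency
    level so both colors appear on both sides.
    """
    rng = _task_rng(seed, TaskKind.SIMON)
    n = config.simon_n_trials
    n_congruent = round(config.simon_congruent_fraction * n)

    cells: list[tuple[str, bool]] = []  # (color, congruent)
    for k in range(n_congruent):
        cells.append(("green" if k % 2 == 0 else "red", True))
    for k in range(n - n_congruent):
        cells.append(("green" if k % 2 == 0 else "red", False))
    order = rng.permutation(n)

    trials = []
    for i, k in enumerate(order):
        color, congruent = cells[k]
        key = SIMON_KEY_FOR_COLOR[color]
        side = key if congruent else ("right" if key == "left" else "left")
        trials.append(
            TrialSpec(
                trial_index=i,
                task=TaskKind.SIMON,
                onset_delay_s=CHOICE_TASK_DELAY_S,
                stimulus=StimulusSpec(
                    shape="colored_square",
                    color=color,
                    side=side,
                    is_target=True,
                    congruent=congruent,
                ),
                response_window_s=config.response_window_s,
                correct_key=key,
                key_layout=("green", "red"),
            )
        )
    return trials


# Interference block rules: (left-key color, right-key color, color → key).
_INTERFERENCE_BLOCKS = (
    # block 0: green key left, red key right; respond same color
    (("green", "red"), {"green": "left", "red": "right"}, True),
    # block 1: keys swapped; still respond same color
    (("red", "green"), {"green": "right", "red": "left"}, True),
    # block 2: original layout, reversed rule — tap left for red, right for green
    (("green", "red"), {"green": "right", "red": "left"}, False),
)


def generate_interference_schedule(
    config: BatteryConfig, seed: int
) -> list[TrialSpec]:
    """Three-block interference task with a reversed-rule final block.

    Blocks 0 and 1 are congruent (the rule matches the key labels on
    screen); block 2 restores the block-0 layout but reverses the rule,
    producing the interference condition. Each trial carries its block's
    key layout and correct key so the engine stays stateless.
    """
    rng = _task_rng(seed, TaskKind.INTERFERENCE)
    per_block = config.interference_total_stimuli // 3
    trials: list[TrialSpec] = []
    idx = 0
    for bi, (layout, rule, congruent) in enumerate(_INTERFERENCE_BLOCKS):
        colors = ["green" if k % 2 == 0 else "red" for k in range(per_block)]
        order = rng.permutation(per_block)
        for k in order:
            color = colors[k]
            trials.append(
                TrialSpec(
                    trial_index=idx,
                    task=TaskKind.INTERFERENCE,
                    onset_delay_s=CHOICE_TASK_DELAY_S,
                    stimulus=StimulusSpec(
                        shape="colored_square",
                        color=color,
                        side="center",
                        is_target=True,
                        congruent=congruent,
                    ),
                    response_window_s=config.response_window_s,
                    block_index=bi,
                    correct_key=rule[color],
                    key_layout=layout,
                )
            )
            idx += 1
    return trials


def generate_battery(config: BatteryConfig, seed: int) -> BatterySchedule:
    """Generate all five task schedules in administration order."""
    vr_sequences = generate_vr_schedule(config, seed)
    trials = {
        TaskKind.SVRT: tuple(generate_svrt_schedule(config, seed)),
        TaskKind.GONOGO: tuple(generate_gonogo_schedule(config, seed)),
        TaskKind.VISUAL_RECOGNITION: tuple(vr_probe_trials(vr_sequences, config)),
        TaskKind.SIMON: tuple(generate_simon_schedule(config, seed)),
        TaskKind.INTERFERENCE: tuple(generate_interference_schedule(config, seed)),
    }
    return BatterySchedule(
        seed=seed, config=config, trials=trials, vr_sequences=tuple(vr_sequences)
    )


def planned_duration_min(config: BatteryConfig, task: TaskKind) -> float:
    """Planned task duration in minutes at the midpoint inter-stimulus
    interval, exclusive of response windows.

    For Go/No-Go at defaults this is 70 × 6 s = 7.0 min, the battery's
    advertised duration for that subtest.
    """
    if task in (TaskKind.SVRT, TaskKind.GONOGO):
        lo, hi = config.svrt_interval_range_s
        n = config.svrt_n_trials if task is TaskKind.SVRT else config.gonogo_n_trials
        return n * (lo + hi) / 2.0 / 60.0
    if task in (TaskKind.SIMON, TaskKind.INTERFERENCE):
        n = (
            config.simon_n_trials
            if task is TaskKind.SIMON
            else config.interference_total_stimuli
        )
        return n * CHOICE_TASK_DELAY_S / 60.0
    # visual recognition: encoding durations plus probe gaps
    lengths = _vr_lengths(config.vr_n_sequences)
    lo, hi = config.vr_duration_range_s
    n = config.vr_n_sequences
    durations = np.linspace(lo, hi, n) if n > 1 else [lo]
    n_probes = sum(length + math.ceil(length / 2) for length in lengths)
    return (float(np.sum(durations)) + n_probes * VR_PROBE_GAP_S) / 60.0
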