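"""Battery configuration and task identifiers.

The battery comprises five touchscreen subtests, always administered in the
same fixed order:

1. simple visual reaction time (sVRT) — tap a circle as soon as it changes
   color; 35 trials, onset after a uniform 4–8 s delay;
2. Go/No-Go — tap squares (targets), withhold to circles; 70 trials,
   same 4–8 s inter-trial interval;
3. visual recognition — eight image sequences of increasing length (2–8
   items) and display duration (2.5–10 s), each followed by yes/no
   recognition probes;
4. Simon — tap the left key for green squares and the right key for red
   squares regardless of where the square appears; spatial congruency
   between stimulus side and required key defines the interference contrast;
5. interference — three blocks of color-key responses; the final block
   reverses the stimulus–response rule (left for red, right for green),
   giving a rule-reversal interference contrast against the first two.

All tunable counts and timing ranges live in :class:`BatteryConfig`;
defaults reproduce the published task parameters.
"""

from __future__ import annotations

import enum
from typing import Literal, Tuple

from pydantic import BaseModel, Field, model_validator


class TaskKind(str, enum.Enum):
    """The five subtests, in default administration order."""

    SVRT = "svrt"
    GONOGO = "gonogo"
    VISUAL_RECOGNITION = "visual_recognition"
    SIMON = "simon"
    INTERFERENCE = "interference"


#: Default administration order of the battery.
TASK_ORDER: tuple[TaskKind, ...] = (
    TaskKind.SVRT,
    TaskKind.GONOGO,
    TaskKind.VISUAL_RECOGNITION,
    TaskKind.SIMON,
    TaskKind.INTERFERENCE,
)


class ConfigurationError(ValueError):
    """Raised when a battery configuration is invalid."""


class BatteryConfig(BaseModel, frozen=True):
    """Counts, fractions and timing ranges for every subtest.

    Parameters
    ----------
    svrt_n_trials
        Number of simple-reaction-time trials (default 35).
    svrt_interval_range_s
        Uniform range, in seconds, of the delay between trial open and
        stimulus onset for sVRT and Go/No-Go (default 4–8 s).
    gonogo_n_trials
        Number of Go/No-Go trials (default 70).
    gonogo_target_fraction
        Fraction of Go/No-Go trials that are targets (squares). Must lie
        strictly inside (0, 1) so both response and inhibition trials exist.
    vr_n_sequences
        Number of visual-recognition sequences (default 8).
    vr_duration_range_s
        Display duration of the first and last sequence; intermediate
        sequences interpolate linearly (default 2.5–10 s).
    simon_n_trials
        Number of Simon trials (default 20, filling roughly one minute of
        self-paced responding).
    simon_congruent_fraction
        Fraction of Simon trials whose stimulus side matches the required
        key side.
    interference_total_stimuli
        Total stimuli across the three interference blocks; must divide
        evenly into three blocks (default 30 → 10 per block).
    response_window_s
        Seconds after stimulus onset during which a tap counts as a
        response; later taps produce an omission (default 2.0 s).
    vr_version
        Alternate stimulus form for visual recognition. Versions share
        structure (lengths, durations, probe layout) but use disjoint
        image identifiers, for retest without item learning.
    """

    svrt_n_trials: int = Field(default=35, gt=0)
    svrt_interval_range_s: Tuple[float, float] = (4.0, 8.0)
    gonogo_n_trials: int = Field(default=70, gt=0)
    gonogo_target_fraction: float = 0.5
    vr_n_sequences: int = Field(default=8, gt=0)
    vr_duration_range_s: Tuple[float, float] = (2.5, 10.0)
    simon_n_trials: int = Field(default=20, gt=0)
    simon_congruent_fraction: float = 0.5
    interference_total_stimuli: int = Field(default=30, gt=0)
    response_window_s: float = Field(default=2.0, gt=0.0)
    vr_version: Literal["A", "B"] = "A"

    @model_validator(mode="after")
    def _check(self) -> "BatteryConfig":
        for name in ("svrt_interval_range_s", "vr_duration_range_s"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"{name}: need 0 < low < high, got ({lo}, {hi})")
        for name in ("gonogo_target_fraction", "simon_congruent_fraction"):
            f = getattr(self, name)
            if not (0.0 < f < 1.0):
                raise ValueError(f"{name}: must lie strictly in (0, 1), got {f}")
        if self.interference_total_stimuli % 3 != 0:
            raise ValueError(
                "interference_total_stimuli: must be divisible by 3 "
                f"(three equal blocks), got {self.interference_total_stimuli}"
            )
        return self


DEFAULT_CONFIG = BatteryConfig()
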