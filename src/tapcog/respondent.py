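"""Virtual respondents: tap streams with controlled psychometric structure.

The simulator is a test harness, not a cognition model. It produces tap
streams whose downstream statistics are known by construction, so the
engine and scoring can be validated end to end without human data:

* reaction times are ex-Gaussian (Gaussian mu/sigma plus exponential tail
  tau), the standard positively skewed RT model — mean mu + tau;
* incongruent Simon trials are slowed by ``simon_effect_ms``; the
  reversed-rule interference block by ``interference_cost_ms``;
* lapses (omissions), commission errors on no-go stimuli, recognition
  hit/false-alarm rates, anticipatory pre-onset taps, and accidental
  double taps are all independent Bernoulli processes.

Random draws are split across three substreams (responses, double taps,
anticipations) so that switching nuisance behaviors on or off leaves the
response draws — and hence, given a correct debouncing engine, every trial
outcome — unchanged.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field

from .config import BatteryConfig, TaskKind, DEFAULT_CONFIG
from .engine import EventLog, InputEvent, build_timeline, run_session
from .schedule import BatterySchedule, generate_battery
from .usability import ParticipantRecord, SUS_CATEGORIES


class RespondentProfile(BaseModel, frozen=True):
    """Generative parameters of one simulated participant."""

    base_rt_ms: float = Field(default=350.0, gt=0)
    rt_sigma_ms: float = Field(default=40.0, gt=0)
    rt_tau_ms: float = Field(default=60.0, gt=0)
    lapse_rate: float = Field(default=0.02, ge=0, le=1)
    commission_rate: float = Field(default=0.10, ge=0, le=1)
    simon_effect_ms: float = 30.0
    interference_cost_ms: float = 60.0
    vr_hit_rate: float = Field(default=0.90, ge=0, le=1)
    vr_false_alarm_rate: float = Field(default=0.15, ge=0, le=1)
    double_tap_rate: float = Field(default=0.0, ge=0, le=1)
    anticipation_rate: float = Field(default=0.0, ge=0, le=1)
    seed: int = Field(default=0, ge=0)


def _tap(t: int, key: str) -> InputEvent:
    return InputEvent(timestamp_ms=int(t), kind="tap", key=key)


def simulate_taps(
    schedule: BatterySchedule, profile: RespondentProfile
) -> list[InputEvent]:
    """Generate the ordered tap stream of one session.

    Deterministic under ``(schedule, profile)``. Response decisions and RT
    samples come from a substream that is consumed identically regardless
    of the nuisance rates, so two profiles differing only in
    ``double_tap_rate`` / ``anticipation_rate`` produce the same responses.
    """
    core = np.random.default_rng([profile.seed, 0])
    doubles = np.random.default_rng([profile.seed, 1])
    antic = np.random.default_rng([profile.seed, 2])

    taps: list[InputEvent] = []
    for win in build_timeline(schedule):
        trial = win.trial
        task = trial.task
        # fixed draw pattern per trial keeps the core stream aligned
        u_resp = core.uniform()
        g = core.standard_normal()
        e = core.standard_exponential()
        u_key = core.uniform()

        if task is TaskKind.GONOGO and not trial.stimulus.is_target:
            respond = u_resp < profile.commission_rate
        else:
            respond = u_resp >= profile.lapse_rate

        if respond:
            shift = 0.0
            if task is TaskKind.SIMON and trial.stimulus.congruent is False:
                shift = profile.simon_effect_ms
            elif task is TaskKind.INTERFERENCE and trial.block_index == 2:
                shift = profile.interference_cost_ms
            rt = max(
                1.0,
                profile.base_rt_ms
                + profile.rt_sigma_ms * g
                + profile.rt_tau_ms * e
                + shift,
            )
            if task in (TaskKind.SVRT, TaskKind.GONOGO):
                key = "stimulus_area"
            elif task is TaskKind.VISUAL_RECOGNITION:
                p_yes = (
                    profile.vr_hit_rate
                    if trial.stimulus.is_target
                    else profile.vr_false_alarm_rate
                )
                key = "yes" if u_key < p_yes else "no"
            else:  # Simon / interference: occasional wrong-key press
                key = trial.correct_key
                if u_key < profile.commission_rate:
                    key = "right" if key == "left" else "left"
            t = win.onset_ms + round(rt)
            taps.append(_tap(t, key))
            if doubles.uniform() < profile.double_tap_rate:
                taps.append(_tap(t + round(doubles.uniform(30, 120)), key))

        if antic.uniform() < profile.anticipation_rate:
            offset = max(1, round(antic.uniform(0, 500)))
            t_pre = max(win.open_ms, win.onset_ms - offset)
            taps.append(_tap(t_pre, _ANTICIPATION_KEY[task]))

    taps.sort(key=lambda e: e.timestamp_ms)
    return taps


#: Key an anticipatory (pre-onset) tap lands on, per task.
_ANTICIPATION_KEY = {
    TaskKind.SVRT: "stimulus_area",
    TaskKind.GONOGO: "stimulus_area",
    TaskKind.VISUAL_RECOGNITION: "yes",
    TaskKind.SIMON: "left",
    TaskKind.INTERFERENCE: "left",
}


def simulate_session(
    schedule: BatterySchedule, profile: RespondentProfile, session_id: str = "sim"
) -> EventLog:
    """Simulate taps and run them through the engine in one step."""
    taps = simulate_taps(schedule, profile)
    return run_session(schedule, taps, session_id=session_id, seed=profile.seed)


def default_profile_sampler(rng: np.random.Generator) -> RespondentProfile:
    """Draw a plausible healthy-adult profile.

    Ranges span ordinary adult performance: base RT around 380 ms,
    moderate variability, small lapse/commission rates, positive
    congruency and rule-reversal costs.
    """
    return RespondentProfile(
        base_rt_ms=float(np.clip(rng.normal(380, 60), 220, 600)),
        rt_sigma_ms=float(rng.uniform(25, 60)),
        rt_tau_ms=float(rng.uniform(30, 90)),
        lapse_rate=float(rng.uniform(0.0, 0.05)),
        commission_rate=float(rng.uniform(0.02, 0.20)),
        simon_effect_ms=float(np.clip(rng.normal(30, 10), 0, None)),
        interference_cost_ms=float(np.clip(rng.normal(60, 20), 0, None)),
        vr_hit_rate=float(rng.uniform(0.75, 0.98)),
        vr_false_alarm_rate=float(rng.uniform(0.02, 0.25)),
        double_tap_rate=float(rng.uniform(0.0, 0.10)),
        anticipation_rate=float(rng.uniform(0.0, 0.05)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    out = np.empty(size)
    for i in range(size):
        x = rng.normal(mean, sd)
        while not (lo <= x <= hi):
            x = rng.normal(mean, sd)
        out[i] = x
    return out


#: SUS value grids per band (all multiples of 2.5 within the band).
_SUS_GRIDS = {
    "marginal": np.arange(40.0, 65.1, 2.5),  # <= 67
    "good": np.arange(67.5, 82.6, 2.5),  # 68-84 band (67.5 rounds in)
    "excellent": np.arange(85.0, 100.1, 2.5),
}

#: Healthy-adult cohort defaults the synthetic generator emulates:
#: 80 adults, age 40.75 ± 17.72 (21–90), education 15.23 ± 3.2 (5–24),
#: cognitive screening 28.45 ± 1.72 (19–30), 47/80 female, 74/80
#: right-handed, region split 71/3/6 north/center/south, and SUS bands
#: filled at 20/20/60% marginal/good/excellent.
COHORT_DEFAULTS = {
    "age": (40.75, 17.72, 21, 90),
    "education": (15.23, 3.2, 5, 24),
    "moca": (28.45, 1.72, 19, 30),
    "p_female": 47 / 80,
    "p_right_handed": 74 / 80,
    "region_p": {"north": 71 / 80, "center": 3 / 80, "south": 6 / 80},
    "sus_proportions": (0.20, 0.20, 0.60),
}


def sample_participants(
    n: int,
    seed: int,
    sus_proportions: tuple[float, float, float] | None = None,
) -> list[ParticipantRecord]:
    """Draw a synthetic participant table with band-exact SUS scores.

    Demographics come from truncated normals at the cohort defaults. SUS
    band membership is assigned by exact counts (``round(p * n)`` for the
    first two bands, remainder excellent), then a score is drawn uniformly
    from the band's grid of valid multiples of 2.5. SUS is generated
    independently of every covariate.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    props = sus_proportions or COHORT_DEFAULTS["sus_proportions"]
    if abs(sum(props) - 1.0) > 1e-9:
        raise ValueError(f"SUS proportions must sum to 1, got {props}")
    rng = np.random.default_rng([seed, 97])

    n_marginal = round(props[0] * n)
    n_good = round(props[1] * n)
    bands = (
        ["marginal"] * n_marginal
        + ["good"] * n_good
        + ["excellent"] * (n - n_marginal - n_good)
    )
    rng.shuffle(bands)

    a_m, a_s, a_lo, a_hi = COHORT_DEFAULTS["age"]
    e_m, e_s, e_lo, e_hi = COHORT_DEFAULTS["education"]
    m_m, m_s, m_lo, m_hi = COHORT_DEFAULTS["moca"]
    ages = np.round(_truncated_normal(rng, a_m, a_s, a_lo, a_hi, n))
    edus = np.round(_truncated_normal(rng, e_m, e_s, e_lo, e_hi, n))
    mocas = np.round(_truncated_normal(rng, m_m, m_s, m_lo, m_hi, n))
    region_names = list(COHORT_DEFAULTS["region_p"])
    region_p = list(COHORT_DEFAULTS["region_p"].values())

    records = []
    for i in range(n):
        records.append(
            ParticipantRecord(
                id=f"p{i:04d}",
                age=float(ages[i]),
                sex="F" if rng.uniform() < COHORT_DEFAULTS["p_female"] else "M",
                education=float(edus[i]),
                handedness="R"
                if rng.uniform() < COHORT_DEFAULTS["p_right_handed"]
                else "L",
                region=str(rng.choice(region_names, p=region_p)),
                moca=float(mocas[i]),
                sus_score=float(rng.choice(_SUS_GRIDS[bands[i]])),
            )
        )
    return records


def simulate_cohort(
    n: int,
    config: BatteryConfig = DEFAULT_CONFIG,
    seed: int = 0,
    profile_sampler: Optional[
        Callable[[np.random.Generator], RespondentProfile]
    ] = None,
    sus_proportions: tuple[float, float, float] | None = None,
) -> tuple[list[EventLog], list[ParticipantRecord]]:
    """Simulate ``n`` complete battery sessions with linked demographics.

    Every participant gets an independent profile from ``profile_sampler``
    (default: :func:`default_profile_sampler`), a full simulated session on
    a per-participant schedule seed, and a synthetic demographic record.
    Deterministic under ``(n, config, seed)``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    sampler = profile_sampler or default_profile_sampler
    rng = np.random.default_rng([seed, 131])
    records = sample_participants(n, seed, sus_proportions)
    logs = []
    for i, rec in enumerate(records):
        profile = sampler(rng)
        schedule = generate_battery(config, seed=int(rng.integers(0, 2**31 - 1)))
        logs.append(simulate_session(schedule, profile, session_id=rec.id))
    return logs, records
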