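# Methods

## What the package models

`tapcog` is a headless re-implementation of a five-task tablet cognitive
screening battery. "Headless" means no rendering, touch capture or UI:
the deliverable is the deterministic core that a deployed app would sit
on top of — planned stimulus timelines, an event-driven session state
machine with a strict touch-input contract, automated scoring, and the
usability statistics used to evaluate the instrument on a cohort.

The five subtests and their scored quantities:

| task | trials (default) | scored quantities |
|---|---|---|
| simple visual reaction time (sVRT) | 35 | mean/median RT, omissions |
| Go/No-Go | 70 (35 targets) | RT over hits, omissions, false alarms |
| visual recognition | 8 sequences, 66 probes | yes/no accuracy, per-sequence accuracy |
| Simon | 20 (10 congruent) | RT/error, congruency (Simon) effect |
| interference | 30 over 3 blocks | RT/error, rule-reversal cost |

## Scheduling

A schedule is a pure function of `(BatteryConfig, seed)`. Each task draws
from an independent substream (`numpy` `default_rng([seed, task_id])`), so
reconfiguring one task never perturbs another's draws, and re-serializing
the same `(config, seed)` is byte-identical — the anchor for replayable
sessions.

Timing parameters, with defaults and provenance:

- **sVRT / Go-No-Go inter-stimulus interval**: uniform 4–8 s. The
  published battery uses this range for sVRT and "random intervals" citing
  the same source for Go/No-Go; we reuse it, which also reproduces the
  advertised ~7 min Go/No-Go duration at the 6 s midpoint
  (`planned_duration_min`, 70 × 6 s = 420 s).
- **Response window**: 2.0 s after onset, exclusive at the boundary (a tap
  at exactly `onset + window` is an omission). The published description is
  silent here; 2 s comfortably exceeds healthy-adult RTs while keeping
  sessions bounded. Configurable.
- **Simon trial count**: 20 (the source states only ~1 min; ~20 self-paced
  trials fit). **Interference "30 stimuli"**: interpreted as the total
  across the three blocks, 10/10/10 — the sentence follows the
  three-block description and matches the ~2 min total.
- **Recognition sequences**: lengths (2, 3, 4, 5, 6, 7, 8, 8) across eight
  sequences — seven distinct lengths spread over eight sequences, with the
  last repeated; display durations interpolate linearly 2.5 → 10 s. Probe
  sets contain every encoded item plus ⌈L/2⌉ distractors (the source gives
  no probe counts, only that they grow with sequence length). Alternate
  forms A/B share all structure but draw from disjoint abstract
  identifier pools (no image assets are modelled).
- **Choice-task inter-trial delay**: fixed 1.0 s (Simon/interference),
  probe gap 0.5 s (recognition); deployed versions are self-paced, but a
  fixed value keeps the planned timeline deterministic.

## The session engine and its input contract

Timestamps are integer milliseconds from session start. Trials are laid
end to end: a trial opens when the previous closes, the stimulus appears
after `onset_delay_s`, and the trial closes `response_window_s` after
onset *regardless of responding*. Making the timeline response-independent
is a deliberate simplification: it buys bit-exact replay (`replay(log)`
re-derives every outcome from the tap stream alone) at the cost of
slightly overestimating session duration for fast responders.

The debouncing contract encodes the fix for a defect observed in field
testing of the original instrument, where a second rapid tap could be
recorded as the response to the *next* stimulus before it appeared,
producing impossibly fast RTs (~79 ms):

1. keys are inactive before stimulus onset — pre-onset taps are counted
   as suppressed, never classified;
2. the first valid in-window tap is the trial's only response; later taps
   are suppressed;
3. suppressed taps never carry into later trials;
4. taps on keys the task does not define are logged and suppressed
   (ordinary touch noise), not errors.

The carry-over property is tested directly (injecting arbitrary bursts
into trial N never changes trials > N) and via the simulator's
neutrality invariant below.

## The virtual respondent

The simulator is a test harness with known ground truth, not a cognition
model (no evidence-accumulation dynamics). Reaction times are
**ex-Gaussian**: `RT = μ + σZ + τE` with `Z ~ N(0,1)`, `E ~ Exp(1)`, mean
`μ + τ` — the standard positively skewed RT model, which also hands the
usability module realistically non-normal data. Defaults (μ = 350 ms,
σ = 40 ms, τ = 60 ms) sit in the healthy-adult range. Incongruent Simon
trials add `simon_effect_ms` to the mean; the reversed-rule interference
block adds `interference_cost_ms`. Lapses, Go/No-Go commissions,
recognition hit/false-alarm rates, wrong-key presses (reusing the
commission rate — the profile defines no separate parameter), anticipatory
taps (uniform 0–500 ms before onset) and double taps (second tap 30–120 ms
after the first) are independent Bernoulli processes.

Random draws are split over three substreams — response decisions/RTs,
double taps, anticipations — and the response stream consumes a fixed
number of draws per trial. Consequently two profiles differing only in
the nuisance rates generate identical response taps, and a correct engine
must produce identical outcomes: the *debounce neutrality* invariant,
checked over many seeds.

The cohort generator emulates the instrument's published evaluation
sample: 80 healthy adults, age 40.75 ± 17.72 (21–90), education
15.23 ± 3.2 (5–24), cognitive screening total 28.45 ± 1.72 (19–30)
(truncated normals, resampling until in range), 47/80 female, 74/80
right-handed, region split 71/3/6. SUS band membership is assigned by
exact counts at 20/20/60% (marginal/good/excellent), then a score is
drawn uniformly from the band's grid of valid multiples of 2.5; SUS is
generated independently of every covariate, so the null of the
correlation analysis holds by construction. What passing tests on this
cohort do **not** show: anything about real respondents — fatigue,
learning, device variability, or genuinely correlated usability and
demographics are all absent by design.

## Scoring conventions

RT aggregates use hit trials only; wrong-key and false-alarm RTs are
excluded (standard practice; the source is silent). No outlier trimming
by default — the engine already forbids pre-onset responses — but
`trim_ms=(lo, hi)` bounds are available on every scorer. The Simon effect
is mean RT(incongruent hits) − mean RT(congruent hits); the interference
cost contrasts block 2 (reversed rule) against blocks 0–1 pooled (both
congruent-rule blocks; `baseline="first"` restricts to block 0). Error
costs are the corresponding error-rate differences. A congruency level
with zero hits leaves the RT effect undefined (`None`) rather than
raising; a missing block is a structural error.

## Usability statistics

- **SUS scoring**: canonical 0–100 formula (odd items `rating − 1`, even
  items `5 − rating`, × 2.5); every valid score is a multiple of 2.5.
- **Bands**: ≤ 67 marginal, 68–84 good, ≥ 85 excellent; the only score
  strictly between bands is 67.5, which maps to "good".
- **Normality screen**: bias-corrected sample skewness and *excess*
  kurtosis; non-normal iff |skew| > 1 or |kurtosis| > 3. The |3| threshold
  is read as excess kurtosis (normal = 0), the convention under which the
  common rule is stated; constant vectors are flagged undefined.
- **Spearman's ρ**: Pearson correlation of midranks. p-values use the
  t-approximation with n − 2 df (exact permutation enumeration available
  for n ≤ 10). The 95% CI is Fisher-z with the Bonett–Wright standard
  error √((1 + ρ²/2)/(n − 3)), a rank-correlation-specific adjustment;
  the analysis the instrument was evaluated with does not state its CI
  method, so this is a package choice. Missing covariates are deleted
  pairwise and the deletion count reported.

## Numerical and degenerate-input choices

- All schedule times are float seconds; engine timestamps integer ms.
- Simulated RTs are clipped below at 1 ms (the Gaussian component can go
  negative at extreme draws).
- ρ is clipped to [−1, 1] against float drift; |ρ| = 1 returns p = 0 and a
  degenerate CI.
- An all-omission task scores with undefined RT fields rather than
  raising; an empty session yields a report with `complete=False`.

## Problem sizes

Statistical tests and the acceptance script use: 10,000 pooled trials for
interval containment; 100 seeds × full battery for the debounce
regression; 2,000 Simon trials for 50 ms effect recovery and 500 default
sessions for the null; 10,000 Monte-Carlo replicates at n = 80 for
type-I calibration of the ρ test; exhaustive permutation checks at
n ≤ 6 plus 1,000 random tied instances at n ≤ 8 for the Spearman oracle.

## Known limitations

- Fixed, response-independent trial windows (see above).
- The respondent model has no sequential effects (no post-error slowing,
  fatigue or practice), and congruency costs are pure mean shifts.
- Recognition stimuli are abstract identifiers; perceptual similarity
  between targets and distractors is not modelled.
- The usability module makes no clinical claims; it reproduces a
  descriptive analysis pipeline (banding, screening, rank correlations).
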