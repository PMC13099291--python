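"""Usability analysis: SUS scoring and banding, normality screening, and
Spearman rank correlations between usability and participant covariates.

The System Usability Scale (SUS) is a 10-item Likert questionnaire
(1 = strongly disagree … 5 = strongly agree) with alternating item
polarity. The canonical 0–100 score is

    SUS = 2.5 * sum(adjusted items),

where odd items contribute ``rating - 1`` and even items ``5 - rating``,
so every valid score is a multiple of 2.5. Scores are banded as
marginal (≤ 67), good (68–84) and excellent (≥ 85).

Because SUS distributions are typically skewed, variables are screened for
non-normality with the moment rule |skewness| > 1 or |excess kurtosis| > 3,
and associations with covariates (age, education, cognitive screening
score) use Spearman's rank correlation with a t-approximation p-value and
a Fisher-z confidence interval using the Bonett–Wright standard error
sqrt((1 + rho^2 / 2) / (n - 3)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

SUS_CATEGORIES = ("marginal", "good", "excellent")


class SUSValidationError(ValueError):
    """Raised for malformed SUS responses."""


@dataclass(frozen=True)
class ParticipantRecord:
    """Minimal anonymized participant: demographics, cognition, usability."""

    id: str
    age: float
    sex: str  # M | F
    education: float  # years
    handedness: str  # L | R
    region: str  # north | center | south
    moca: float  # 0-30 cognitive screening total
    sus_score: float  # 0-100, multiple of 2.5


def score_sus(responses: Sequence[int]) -> float:
    """Score a 10-item SUS response on the canonical 0–100 scale.

    Odd items (1st, 3rd, …) contribute ``rating - 1``; even items
    contribute ``5 - rating``; the sum is scaled by 2.5.

    Raises :class:`SUSValidationError` for wrong length or out-of-range items.
    """
    items = list(responses)
    if len(items) != 10:
        raise SUSValidationError(f"SUS needs exactly 10 items, got {len(items)}")
    total = 0
    for i, r in enumerate(items):
        if not (isinstance(r, (int, np.integer)) and 1 <= r <= 5):
            raise SUSValidationError(
                f"item {i + 1}: rating must be an integer in [1, 5], got {r!r}"
            )
        total += (r - 1) if i % 2 == 0 else (5 - r)
    return 2.5 * total


def categorize_sus(score: float) -> str:
    """Band a SUS score: ≤67 marginal, 68–84 good, ≥85 excellent.

    Valid scores are multiples of 2.5, so the only score strictly between
    the bands is 67.5, which falls in "good".
    """
    if not (0 <= score <= 100):
        raise SUSValidationError(f"SUS score out of [0, 100]: {score}")
    if score <= 67:
        return "marginal"
    if score >= 85:
        return "excellent"
    return "good"


@dataclass(frozen=True)
class NormalityScreen:
    skewness: float
    excess_kurtosis: float
    non_normal: bool
    defined: bool  # False for (near-)constant input, where moments degenerate
    n: int


def normality_screen(values: Iterable[float]) -> NormalityScreen:
    """Moment-based non-normality flag: |skew| > 1 or |excess kurtosis| > 3.

    Sample (bias-corrected) skewness and excess kurtosis; a constant vector
    has undefined moments and is returned flagged ``defined=False``.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 4:
        raise ValueError(f"normality screen needs n >= 4, got {x.size}")
    if np.ptp(x) == 0 or np.std(x) == 0:
        return NormalityScreen(math.nan, math.nan, False, False, x.size)
    skew = float(stats.skew(x, bias=False))
    kurt = float(stats.kurtosis(x, fisher=True, bias=False))
    return NormalityScreen(skew, kurt, abs(skew) > 1 or abs(kurt) > 3, True, x.size)


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    ci_low: float
    ci_high: float
    n: int
    defined: bool = True
    method: str = "t-approximation"


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "t-approximation",
) -> SpearmanResult:
    """Spearman's rank correlation with p-value and 95% CI.

    rho is the Pearson correlation of midranks. The two-sided p-value uses
    the t-approximation with ``n - 2`` degrees of freedom
    (``method="t-approximation"``), or exact enumeration of all rank
    permutations for ``method="exact"`` (n ≤ 10). The CI is Fisher-z with
    the Bonett–Wright rank-correlation standard error.

    Degenerate inputs (constant ranks) return ``defined=False``.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    n = xa.size
    if n < 5:
        raise ValueError(f"spearman needs n >= 5, got {n}")

    rx, ry = _midranks(xa), _midranks(ya)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return SpearmanResult(math.nan, math.nan, math.nan, math.nan, n, defined=False)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))

    if method == "exact":
        if n > 10:
            raise ValueError("exact permutation p only available for n <= 10")
        count = 0
        total = 0
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
        observed = abs(float(rx_c @ ry_c) / denom)
        for perm in permutations(range(n)):
            r = abs(float(rx_c[list(perm)] @ ry_c) / denom)
            count += r >= observed - 1e-12
            total += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho * rho))
            p = 2 * stats.t.sf(abs(t), df=n - 2)

    if n > 3 and abs(rho) < 1.0:
        se = math.sqrt((1 + rho * rho / 2) / (n - 3))
        z = math.atanh(rho)
        ci_low = math.tanh(z - 1.959963984540054 * se)
        ci_high = math.tanh(z + 1.959963984540054 * se)
    else:
        ci_low = ci_high = rho
    return SpearmanResult(rho, float(p), ci_low, ci_high, n, method=method)


@dataclass
class UsabilityResult:
    """Full cohort analysis: distribution screens, correlations, SUS bands."""

    n: int
    normality: dict[str, NormalityScreen]
    correlations: dict[str, SpearmanResult]  # covariate -> SUS association
    category_counts: dict[str, int]
    category_fractions: dict[str, float]
    summary: dict[str, dict[str, float]]  # variable -> mean/sd/min/max
    n_missing: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "normality": {
                k: {
                    "skewness": v.skewness,
                    "excess_kurtosis": v.excess_kurtosis,
                    "non_normal": v.non_normal,
                    "defined": v.defined,
                }
                for k, v in self.normality.items()
            },
            "correlations": {
                k: {
                    "rho": v.rho,
                    "p": v.p,
                    "ci95": [v.ci_low, v.ci_high],
                    "n": v.n,
                }
                for k, v in self.correlations.items()
            },
            "category_counts": self.category_counts,
            "category_fractions": self.category_fractions,
            "summary": self.summary,
            "n_missing": self.n_missing,
        }


_COVARIATES = ("age", "education", "moca")


def analyze_cohort(
    records: Sequence[ParticipantRecord] | pd.DataFrame,
) -> UsabilityResult:
    """Run the usability analysis on a participant cohort.

    Screens SUS and covariates for non-normality, correlates SUS with age,
    education and the cognitive screening score (Spearman, pairwise
    deletion of missing values), and tabulates the SUS usability bands.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            {
                "age": [r.age for r in records],
                "education": [r.education for r in records],
                "moca": [r.moca for r in records],
                "sus": [r.sus_score for r in records],
            }
        )
    if "sus" not in df.columns:
        raise ValueError("cohort table needs a 'sus' column")
    if df["sus"].isna().any():
        raise ValueError("SUS must be present for all participants")
    n = len(df)
    if n < 5:
        raise ValueError(f"cohort analysis needs n >= 5, got {n}")

    normality = {
        var: normality_screen(df[var].dropna())
        for var in ("sus", *_COVARIATES)
        if var in df.columns
    }

    correlations: dict[str, SpearmanResult] = {}
    n_missing: dict[str, int] = {}
    for var in _COVARIATES:
        if var not in df.columns:
            continue
        mask = df[var].notna()
        n_missing[var] = int((~mask).sum())
        correlations[var] = spearman(df.loc[mask, var], df.loc[mask, "sus"])

    cats = [categorize_sus(s) for s in df["sus"]]
    counts = {c: cats.count(c) for c in SUS_CATEGORIES}
    fractions = {c: counts[c] / n for c in SUS_CATEGORIES}

    summary = {
        var: {
            "mean": float(df[var].mean()),
            "sd": float(df[var].std(ddof=1)),
            "min": float(df[var].min()),
            "max": float(df[var].max()),
        }
        for var in ("sus", *_COVARIATES)
        if var in df.columns
    }

    return UsabilityResult(
        n=n,
        normality=normality,
        correlations=correlations,
        category_counts=counts,
        category_fractions=fractions,
        summary=summary,
        n_missing=n_missing,
    )


def format_tables(result: UsabilityResult) -> str:
    """Human-readable cohort summary and correlation tables."""
    lines = [f"Cohort (N = {result.n})", "-" * 40]
    for var, s in result.summary.items():
        lines.append(
            f"{var:>10}: {s['mean']:.2f} ± {s['sd']:.2f} "
            f"({s['min']:g}–{s['max']:g})"
        )
    lines.append("")
    lines.append("SUS usability bands")
    for cat in SUS_CATEGORIES:
        lines.append(
            f"{cat:>10}: n = {result.category_counts[cat]:3d} "
            f"({100 * result.category_fractions[cat]:.0f}%)"
        )
    lines.append("")
    lines.append("Spearman correlations with SUS")
    for var, r in result.correlations.items():
        lines.append(
            f"{var:>10}: rho = {r.rho:+.2f}, 95% CI [{r.ci_low:+.2f}, "
            f"{r.ci_high:+.2f}], p = {r.p:.3f} (n = {r.n})"
        )
    return "\n".join(lines)
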