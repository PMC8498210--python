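"""Baseline-vs-subsequent risk-band shift classification.

A participant's baseline risk band is the band of their first balance
score; their subsequent band is the band of the *median* of all later
scores.  A shift is a change of band; "improved" means the subsequent
band carries lower risk than baseline.  Because medians over an even
number of integer scores can land on half-integers between bands, the
band rule for medians is declared explicitly:

    high  : median < 3.5
    moderate : 3.5 <= median < 6.5
    low   : median >= 6.5

so a half-point median resolves toward the lower-risk band (entering a
band counts as reaching it).  On integer medians this agrees exactly
with the integer score bands (1-3 / 4-6 / 7-10).
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
import statistics
from dataclasses import dataclass

from .cop_signal import CATEGORY_HIGH, CATEGORY_LOW, CATEGORY_MODERATE, categorize_score

logger = logging.getLogger(__name__)

_RISK_RANK = {CATEGORY_HIGH: 0, CATEGORY_MODERATE: 1, CATEGORY_LOW: 2}

DIRECTION_IMPROVED = "improved"
DIRECTION_WORSENED = "worsened"
DIRECTION_NONE = "none"


@dataclass(frozen=True)
class ScoreHistory:
    """Date-ordered balance-score record of one participant."""

    participant_id: str
    entries: tuple[tuple[_dt.date, int], ...]

    def __post_init__(self) -> None:
        dates = [d for d, _ in self.entries]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError(
                f"participant {self.participant_id}: test dates must be "
                f"strictly increasing"
            )
        for _, s in self.entries:
            if not 1 <= s <= 10:
                raise ValueError(
                    f"participant {self.participant_id}: score {s} outside [1, 10]"
                )


@dataclass(frozen=True)
class ShiftResult:
    baseline_category: str
    subsequent_median: float
    subsequent_category: str
    shifted: bool
    direction: str
    days_to_shift: int | None = None
    inconsistent: bool = False

    def __post_init__(self) -> None:
        if self.shifted and self.subsequent_category == self.baseline_category:
            raise ValueError("shifted result must change category")
        if self.days_to_shift is not None and self.direction != DIRECTION_IMPROVED:
            raise ValueError("days_to_shift applies to improved shifts only")


def categorize_median(median: float) -> str:
    """Band of a (possibly half-integer) median score."""
    if not 1 <= median <= 10:
        raise ValueError(f"median score {median} outside [1, 10]")
    if median < 3.5:
        return CATEGORY_HIGH
    if median < 6.5:
        return CATEGORY_MODERATE
    return CATEGORY_LOW


def classify_shift(history: ScoreHistory) -> ShiftResult:
    """Classify one participant's risk-band shift.

    Baseline band from the first score; subsequent band from the median
    of all later scores.  For improved shifts the time to shift (days
    from baseline to the first test scoring in a lower-risk band) is
    attached; if no single test ever crossed the band despite an
    improved median, the result is flagged inconsistent and the days are
    omitted.

    Raises
    ------
    ValueError
        For a single-entry history (no subsequent scores to take a
        median of) — callers summarizing cohorts should catch this and
        count the participant as unclassifiable.
    """
    if len(history.entries) < 2:
        raise ValueError(
            f"participant {history.participant_id}: need a baseline plus at "
            f"least one subsequent score"
        )
    baseline_date, baseline_score = history.entries[0]
    baseline_cat = categorize_score(baseline_score)
    median = float(statistics.median(s for _, s in history.entries[1:]))
    subsequent_cat = categorize_median(median)

    shifted = subsequent_cat != baseline_cat
    if not shifted:
        direction = DIRECTION_NONE
    elif _RISK_RANK[subsequent_cat] > _RISK_RANK[baseline_cat]:
        direction = DIRECTION_IMPROVED
    else:
        direction = DIRECTION_WORSENED

    days = None
    inconsistent = False
    if direction == DIRECTION_IMPROVED:
        for date, score in history.entries[1:]:
            if _RISK_RANK[categorize_score(score)] > _RISK_RANK[baseline_cat]:
                days = (date - baseline_date).days
                break
        else:
            logger.warning(
                "participant %s: improved median band but no single test "
                "crossed the band", history.participant_id,
            )
            inconsistent = True

    return ShiftResult(
        baseline_category=baseline_cat,
        subsequent_median=median,
        subsequent_category=subsequent_cat,
        shifted=shifted,
        direction=direction,
        days_to_shift=days,
        inconsistent=inconsistent,
    )


def days_to_shift(history: ScoreHistory, result: ShiftResult) -> int:
    """Days from baseline to the first test in a lower-risk band.

    Precondition: ``result`` is an improved shift for this history.
    """
    if not (result.shifted and result.direction == DIRECTION_IMPROVED):
        raise ValueError("days_to_shift applies to improved shifts only")
    if result.days_to_shift is None:
        raise ValueError("improved median but no band-crossing test recorded")
    return result.days_to_shift


@dataclass(frozen=True)
class ShiftGroupSummary:
    baseline_category: str
    status: str                      # improved / worsened / none
    n: int
    fraction_of_baseline: float
    median_days_to_shift: float | None
    mean_participation_days: float | None
    se_participation_days: float | None
    fraction_with_fall: float | None


def shift_summary(
    histories,
    participation_days: dict[str, int] | None = None,
    fell_prospectively: dict[str, bool] | None = None,
) -> dict:
    """Summarize shifts per baseline-band x shift-status group.

    For each group: participant count, fraction of that baseline band,
    median days-to-shift (improved groups), mean +- SE participation
    days, and the fraction experiencing at least one prospective fall.
    Single-entry histories are unclassifiable and excluded, with a
    logged count.
    """
    participation_days = participation_days or {}
    fell_prospectively = fell_prospectively or {}

    results: dict[str, ShiftResult] = {}
    unclassifiable = 0
    for h in histories:
        try:
            results[h.participant_id] = classify_shift(h)
        except ValueError:
            unclassifiable += 1
    if unclassifiable:
        logger.info("%d participants unclassifiable (single test)", unclassifiable)

    groups: dict[tuple[str, str], list[str]] = {}
    for pid, res in results.items():
        groups.setdefault((res.baseline_category, res.direction), []).append(pid)

    baseline_totals: dict[str, int] = {}
    for res in results.values():
        baseline_totals[res.baseline_category] = (
            baseline_totals.get(res.baseline_category, 0) + 1
        )

    summaries = []
    for cat in (CATEGORY_HIGH, CATEGORY_MODERATE, CATEGORY_LOW):
        for status in (DIRECTION_IMPROVED, DIRECTION_WORSENED, DIRECTION_NONE):
            pids = groups.get((cat, status), [])
            total = baseline_totals.get(cat, 0)
            if not pids:
                summaries.append(ShiftGroupSummary(
                    baseline_category=cat, status=status, n=0,
                    fraction_of_baseline=0.0 if total else float("nan"),
                    median_days_to_shift=None,
                    mean_participation_days=None,
                    se_participation_days=None,
                    fraction_with_fall=None,
                ))
                continue
            days = [results[p].days_to_shift for p in pids
                    if results[p].days_to_shift is not None]
            part = [participation_days[p] for p in pids if p in participation_days]
            mean_part = sum(part) / len(part) if part else None
            se_part = (
                statistics.stdev(part) / math.sqrt(len(part))
                if len(part) > 1 else None
            )
            fell = [fell_prospectively.get(p, False) for p in pids]
            summaries.append(ShiftGroupSummary(
                baseline_category=cat, status=status, n=len(pids),
                fraction_of_baseline=len(pids) / total,
                median_days_to_shift=float(statistics.median(days)) if days else None,
                mean_participation_days=mean_part,
                se_participation_days=se_part,
                fraction_with_fall=(sum(fell) / len(fell)) if fell_prospectively else None,
            ))

    return {
        "groups": summaries,
        "n_classified": len(results),
        "n_unclassifiable": unclassifiable,
        "results": results,
    }
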