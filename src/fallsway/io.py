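"""CSV/JSON readers and writers for the project's data dialects.

All dialects are comma-separated UTF-8 with a mandatory header; dates
are ISO-8601.  Readers validate and reject with row context rather than
silently coercing; every writer's output round-trips through its reader.

Dialects
--------
COP trace      ``t_s,cop_ml_mm,cop_ap_mm`` — one file per test,
               filename ``<participant>_<ISO date>.csv``.
Roster         ``id,site,sex,age,first_test,last_test,n_tests,
               falls_retro_6m,falls_retro_12m``.
Fall log       ``id,event_date,period,syncope_excluded`` with period in
               {retro6, retro12, prospective}.  A retro6 tag means the
               recalled event fell in the six months before enrollment;
               12-month recall counts cover both retro tags.
Score history  ``id,test_date,score``.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cop_signal import CopTrace
from .fall_epi import (
    PERIOD_PROSPECTIVE,
    VALID_PERIODS,
    CohortReport,
    FallRecord,
    Participant,
)
from .risk_shift import ScoreHistory

COP_COLUMNS = ["t_s", "cop_ml_mm", "cop_ap_mm"]
ROSTER_COLUMNS = ["id", "site", "sex", "age", "first_test", "last_test",
                  "n_tests", "falls_retro_6m", "falls_retro_12m"]
FALL_LOG_COLUMNS = ["id", "event_date", "period", "syncope_excluded"]
SCORE_COLUMNS = ["id", "test_date", "score"]


class DataFormatError(ValueError):
    """Malformed input file (bad header, cell, or cross-file reference)."""


def _require_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    if list(df.columns) != expected:
        raise DataFormatError(
            f"{path}: expected header {','.join(expected)}, "
            f"got {','.join(map(str, df.columns))}"
        )


def _parse_date(value, path, row: int, column: str) -> _dt.date:
    try:
        return _dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise DataFormatError(
            f"{path} row {row}: bad ISO-8601 date in {column!r}: {value!r}"
        ) from exc


# ---------------------------------------------------------------------------
# COP traces
# ---------------------------------------------------------------------------

def read_cop_csv(path) -> CopTrace:
    """Read one COP trace; participant id and test date come from the
    ``<participant>_<date>.csv`` filename."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise DataFormatError(f"{path}: no samples")
    _require_columns(df, COP_COLUMNS, path)
    for col in COP_COLUMNS:
        bad = df.index[df[col].isna() | ~np.isfinite(df[col].astype(float))]
        if len(bad):
            raise DataFormatError(
                f"{path} row {bad[0] + 2}: non-finite value in {col!r}"
            )
    t = df["t_s"].to_numpy(float)
    dt_steps = np.diff(t)
    if len(dt_steps) and np.any(dt_steps <= 0):
        row = int(np.nonzero(dt_steps <= 0)[0][0])
        raise DataFormatError(
            f"{path} row {row + 3}: time column not strictly increasing"
        )
    stem = path.stem
    pid, _, datestr = stem.rpartition("_")
    if not pid:
        raise DataFormatError(
            f"{path}: filename must follow <participant>_<ISO date>.csv"
        )
    test_date = _parse_date(datestr, path, 0, "filename date")
    n = len(t)
    duration = n * (t[-1] - t[0]) / (n - 1) if n > 1 else 1.0
    rate = (n - 1) / (t[-1] - t[0]) if n > 1 else 1.0
    return CopTrace(
        participant_id=pid,
        test_date=test_date,
        sample_rate_hz=rate,
        duration_s=duration,
        ml=df["cop_ml_mm"].to_numpy(float),
        ap=df["cop_ap_mm"].to_numpy(float),
    )


def write_cop_csv(trace: CopTrace, path) -> Path:
    path = Path(path)
    t = np.arange(trace.n_samples) / trace.sample_rate_hz
    pd.DataFrame(
        {"t_s": t, "cop_ml_mm": trace.ml, "cop_ap_mm": trace.ap}
    ).to_csv(path, index=False, float_format="%.9g")
    return path


def cop_trace_filename(trace: CopTrace) -> str:
    return f"{trace.participant_id}_{trace.test_date.isoformat()}.csv"


# ---------------------------------------------------------------------------
# roster / fall log / score history
# ---------------------------------------------------------------------------

def read_roster(path) -> list[Participant]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ROSTER_COLUMNS, path)
    participants = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        rownum = i + 2
        pid = str(row["id"])
        if pid in seen:
            raise DataFormatError(f"{path} row {rownum}: duplicate id {pid!r}")
        seen.add(pid)
        first = _parse_date(row["first_test"], path, rownum, "first_test")
        last = _parse_date(row["last_test"], path, rownum, "last_test")
        try:
            participants.append(Participant(
                id=pid, site=str(row["site"]), sex=str(row["sex"]),
                age_years=float(row["age"]),
                first_test_date=first, last_test_date=last,
                n_tests=int(row["n_tests"]),
                falls_retro_6m=int(row["falls_retro_6m"]),
                falls_retro_12m=int(row["falls_retro_12m"]),
            ))
        except ValueError as exc:
            raise DataFormatError(f"{path} row {rownum}: {exc}") from exc
    return participants


def write_roster(participants, path) -> Path:
    path = Path(path)
    pd.DataFrame([
        {
            "id": p.id, "site": p.site, "sex": p.sex, "age": p.age_years,
            "first_test": p.first_test_date.isoformat(),
            "last_test": p.last_test_date.isoformat(),
            "n_tests": p.n_tests,
            "falls_retro_6m": p.falls_retro_6m,
            "falls_retro_12m": p.falls_retro_12m,
        }
        for p in participants
    ], columns=ROSTER_COLUMNS).to_csv(path, index=False)
    return path


def read_fall_log(path, roster: list[Participant] | None = None) -> list[FallRecord]:
    """Read a fall log; syncope-flagged rows are kept but flagged.  With
    a roster, referential integrity (log ids subset of roster ids) is
    enforced."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, FALL_LOG_COLUMNS, path)
    known = {p.id for p in roster} if roster is not None else None
    records = []
    for i, row in df.iterrows():
        rownum = i + 2
        pid = str(row["id"])
        if known is not None and pid not in known:
            raise DataFormatError(
                f"{path} row {rownum}: participant {pid!r} not in roster"
            )
        period = str(row["period"])
        if period not in VALID_PERIODS:
            raise DataFormatError(
                f"{path} row {rownum}: period {period!r} not in "
                f"{sorted(VALID_PERIODS)}"
            )
        flag = row["syncope_excluded"]
        if isinstance(flag, str):
            if flag.lower() not in ("true", "false"):
                raise DataFormatError(
                    f"{path} row {rownum}: syncope_excluded must be true/false"
                )
            flag = flag.lower() == "true"
        records.append(FallRecord(
            participant_id=pid,
            event_date=_parse_date(row["event_date"], path, rownum, "event_date"),
            period=period,
            syncope_excluded=bool(flag),
        ))
    return records


def write_fall_log(records, path) -> Path:
    path = Path(path)
    pd.DataFrame([
        {
            "id": r.participant_id,
            "event_date": r.event_date.isoformat(),
            "period": r.period,
            "syncope_excluded": str(bool(r.syncope_excluded)).lower(),
        }
        for r in records
    ], columns=FALL_LOG_COLUMNS).to_csv(path, index=False)
    return path


def attach_prospective_falls(
    participants: list[Participant], fall_log: list[FallRecord]
) -> list[Participant]:
    """Return participants with their prospective fall records attached
    (retro-period records inform the roster's recall counts and are not
    attached)."""
    by_pid: dict[str, list[FallRecord]] = {}
    for r in fall_log:
        if r.period == PERIOD_PROSPECTIVE:
            by_pid.setdefault(r.participant_id, []).append(r)
    return [
        replace(p, prospective_falls=tuple(by_pid.get(p.id, ())))
        for p in participants
    ]


def read_score_history(path, roster: list[Participant] | None = None) -> list[ScoreHistory]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, SCORE_COLUMNS, path)
    known = {p.id for p in roster} if roster is not None else None
    rows_by_pid: dict[str, list[tuple[_dt.date, int]]] = {}
    order: list[str] = []
    for i, row in df.iterrows():
        rownum = i + 2
        pid = str(row["id"])
        if known is not None and pid not in known:
            raise DataFormatError(
                f"{path} row {rownum}: participant {pid!r} not in roster"
            )
        score = int(row["score"])
        if not 1 <= score <= 10:
            raise DataFormatError(
                f"{path} row {rownum}: score {score} outside [1, 10]"
            )
        if pid not in rows_by_pid:
            order.append(pid)
        rows_by_pid.setdefault(pid, []).append(
            (_parse_date(row["test_date"], path, rownum, "test_date"), score)
        )
    histories = []
    for pid in order:
        entries = sorted(rows_by_pid[pid])
        try:
            histories.append(ScoreHistory(pid, tuple(entries)))
        except ValueError as exc:
            raise DataFormatError(f"{path}: participant {pid}: {exc}") from exc
    return histories


def write_score_history(histories, path) -> Path:
    path = Path(path)
    pd.DataFrame([
        {"id": h.participant_id, "test_date": d.isoformat(), "score": s}
        for h in histories for d, s in h.entries
    ], columns=SCORE_COLUMNS).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _rate_result_dict(res) -> dict:
    return {
        "ir_retro": round(res.ir_retro, 3),
        "ir_pros": round(res.ir_pros, 3),
        "irr": round(res.irr, 3),
        "normalized_pros_count": round(res.normalized_pros_count, 3),
        "ci_95": ([round(res.ci_low, 3), round(res.ci_high, 3)]
                  if res.ci_defined else None),
        "ci_defined": res.ci_defined,
        "percent_reduction": round(res.percent_reduction, 1),
    }


def report_to_dict(report: CohortReport) -> dict:
    out = {
        "cohort": {
            "n": report.ledger.n,
            "person_years_retrospective": round(report.ledger.py_retro, 2),
            "person_years_prospective": round(report.ledger.py_pros, 2),
            "falls_retrospective": report.ledger.falls_retro,
            "falls_prospective": report.ledger.falls_pros,
            "fallers_retrospective": report.ledger.fallers_retro,
            "fallers_prospective": report.ledger.fallers_pros,
        },
        "falls": _rate_result_dict(report.falls),
        "fallers": _rate_result_dict(report.fallers),
        "notes": list(report.notes),
    }
    if report.by_site:
        out["by_site"] = {
            site: (None if pair is None else {
                "falls": _rate_result_dict(pair[0]),
                "fallers": _rate_result_dict(pair[1]),
            })
            for site, pair in report.by_site.items()
        }
    if report.matched:
        out["matched_periods"] = {
            str(w): {
                "n": m.n,
                "mean_age": round(m.mean_age, 1),
                "falls_retro": m.falls_retro,
                "falls_pros": round(float(m.falls_pros), 3),
                "percent_reduction_falls": round(m.percent_reduction_falls, 1),
                "fallers_retro": m.fallers_retro,
                "fallers_pros": round(float(m.fallers_pros), 3),
                "percent_reduction_fallers": round(m.percent_reduction_fallers, 1),
            }
            for w, m in report.matched.items()
        }
    return out


def report_to_markdown(report: CohortReport) -> str:
    """Human-readable rate table (incidence rates to 3 dp, percents to
    1 dp)."""
    f, fl = report.falls, report.fallers

    def ci(res):
        return (f"[{res.ci_low:.3f}-{res.ci_high:.3f}]"
                if res.ci_defined else "[undefined]")

    lines = [
        f"# Fall incidence report — {report.ledger.label}",
        "",
        f"Participants: {report.ledger.n}  |  person-years "
        f"retro/pros: {report.ledger.py_retro:.2f} / {report.ledger.py_pros:.2f}",
        "",
        "| Quantity | Falls | Fallers |",
        "|---|---|---|",
        f"| IR retrospective (per person-year) | {f.ir_retro:.3f} | {fl.ir_retro:.3f} |",
        f"| IR prospective (per person-year) | {f.ir_pros:.3f} | {fl.ir_pros:.3f} |",
        f"| IRR [95% CI] | {f.irr:.3f} {ci(f)} | {fl.irr:.3f} {ci(fl)} |",
        f"| Percent reduction | {f.percent_reduction:.1f}% | {fl.percent_reduction:.1f}% |",
    ]
    if report.matched:
        lines += ["", "## Matched-period subsets", "",
                  "| Window | N | #falls retro | #falls pros | % red. | "
                  "#fallers retro | #fallers pros | % red. |",
                  "|---|---|---|---|---|---|---|---|"]
        for w, m in sorted(report.matched.items()):
            lines.append(
                f"| {w} months | {m.n} | {m.falls_retro} | {m.falls_pros:g} | "
                f"{m.percent_reduction_falls:.1f}% | {m.fallers_retro} | "
                f"{m.fallers_pros:g} | {m.percent_reduction_fallers:.1f}% |"
            )
    if report.notes:
        lines += ["", "## Notes", ""] + [f"- {n}" for n in report.notes]
    return "\n".join(lines) + "\n"


def write_report(report: CohortReport, out_dir, stem: str = "fall_rate_report") -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / f"{stem}.json"
    md_path = out_dir / f"{stem}.md"
    json_path.write_text(json.dumps(report_to_dict(report), indent=2) + "\n")
    md_path.write_text(report_to_markdown(report))
    return json_path, md_path
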