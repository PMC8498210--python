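"""Risk-shift summary and score-trajectory plot for the simulated cohort.

Classifies every simulated participant by baseline band versus the band
of their subsequent median score, summarizes groups (counts, shift
timing, participation, fall outcomes), writes the summary JSON, and
plots a few representative high-risk score trajectories.
"""

import dataclasses
import json
from pathlib import Path

from fallsway import io, risk_shift

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "synthetic_cohort"
RESULTS = ROOT / "results"


def main() -> None:
    roster = io.read_roster(COHORT / "roster.csv")
    log = io.read_fall_log(COHORT / "fall_log.csv", roster=roster)
    participants = io.attach_prospective_falls(roster, log)
    histories = io.read_score_history(COHORT / "score_history.csv", roster=roster)

    participation = {p.id: p.days_enrolled for p in participants}
    fell = {p.id: bool(p.counted_prospective_falls()) for p in participants}
    summary = risk_shift.shift_summary(histories, participation, fell)

    payload = {
        "n_classified": summary["n_classified"],
        "n_unclassifiable": summary["n_unclassifiable"],
        "groups": [dataclasses.asdict(g) for g in summary["groups"] if g.n],
    }
    out = RESULTS / "risk_shift_summary.json"
    out.write_text(json.dumps(payload, indent=2) + "\n")

    for g in summary["groups"]:
        if g.n:
            print(f"{g.baseline_category:>8} / {g.status:<8} n={g.n:3d} "
                  f"({100 * g.fraction_of_baseline:.1f}% of band)"
                  + (f", median shift {g.median_days_to_shift:.0f} d"
                     if g.median_days_to_shift is not None else ""))
    print(f"wrote {out}")

    _plot(histories, summary["results"])


def _plot(histories, results) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        print("matplotlib unavailable; skipping trajectory plot")
        return
    fig, ax = plt.subplots(figsize=(7, 4))
    shown = 0
    for h in histories:
        res = results.get(h.participant_id)
        if res is None or res.baseline_category != "high" or len(h.entries) < 4:
            continue
        days = [(d - h.entries[0][0]).days for d, _ in h.entries]
        scores = [s for _, s in h.entries]
        ax.plot(days, scores, marker="o", alpha=0.7,
                label=f"{h.participant_id} ({res.direction})")
        shown += 1
        if shown == 6:
            break
    ax.axhspan(0.5, 3.5, color="red", alpha=0.08)
    ax.axhspan(3.5, 6.5, color="gold", alpha=0.08)
    ax.axhspan(6.5, 10.5, color="green", alpha=0.08)
    ax.set(xlabel="days since baseline", ylabel="balance score",
           ylim=(0.5, 10.5), title="High-risk baseline score trajectories")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(RESULTS / "score_trajectories.png", dpi=120)
    print(f"wrote {RESULTS / 'score_trajectories.png'}")


if __name__ == "__main__":
    main()
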