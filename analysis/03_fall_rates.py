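"""Fall-rate analysis: reference cohort and simulated cohort.

Reproduces the reference cohort's incidence-rate table from its
aggregate counts (with the fallers point-estimate discrepancy flagged),
then runs the same analysis end-to-end on the simulated cohort written
by 01_simulate_cohort.py, reading its CSVs back through the package's
own readers.  Reports land in results/.
"""

from pathlib import Path

from fallsway import fall_epi, io, synthetic_data

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
COHORT = RESULTS / "synthetic_cohort"


def main() -> None:
    report = fall_epi.analyze_cohort_ledger(
        synthetic_data.reference_cohort_ledger(),
        published_reference=synthetic_data.PUBLISHED_REFERENCE)
    io.write_report(report, RESULTS, stem="reference_cohort_rates")
    print(io.report_to_markdown(report))

    if (COHORT / "roster.csv").exists():
        roster = io.read_roster(COHORT / "roster.csv")
        log = io.read_fall_log(COHORT / "fall_log.csv", roster=roster)
        participants = io.attach_prospective_falls(roster, log)
        sim_report = fall_epi.analyze_cohort(participants)
        io.write_report(sim_report, RESULTS, stem="synthetic_cohort_rates")
        print(io.report_to_markdown(sim_report))
    else:
        print("run 01_simulate_cohort.py first for the simulated-cohort report")


if __name__ == "__main__":
    main()
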