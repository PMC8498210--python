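"""Score simulated stabilograms across the stability range.

Simulates quiet-stance COP traces at five stability levels, runs each
through preprocessing, linear sway metrics, the sway HMM, and the
stand-in 1-10 balance score, and writes the per-trace table to
results/stabilogram_scores.csv.  The table should show scores falling
monotonically (in distribution) as the stability level drops.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fallsway import cop_signal, sway_hmm, synthetic_data

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 2
LEVELS = (1.0, 0.8, 0.6, 0.4, 0.2)
TRACES_PER_LEVEL = 6


def main() -> None:
    rng = np.random.default_rng(SEED)
    reference = cop_signal.default_reference()
    rows = []
    for level in LEVELS:
        for k in range(TRACES_PER_LEVEL):
            cfg = synthetic_data.SwaySimConfig(
                stability_level=level, seed=int(rng.integers(2**31 - 1)))
            trace = synthetic_data.simulate_cop_trace(
                cfg, participant_id=f"L{int(level * 100):03d}_{k}")
            clean = cop_signal.preprocess_trace(trace, demean=True)
            feats = cop_signal.compute_sway_features(clean)
            model = sway_hmm.fit_hmm(clean.increments(),
                                     seed=int(rng.integers(2**31 - 1)),
                                     n_restarts=2, max_iter=50)
            hf = sway_hmm.hmm_features(model, clean.increments())
            score = cop_signal.score_balance(feats, hf, reference)
            rows.append({
                "stability_level": level,
                "trace": trace.participant_id,
                "path_length_planar_mm": round(feats.path_length_planar, 1),
                "mean_velocity_mm_s": round(feats.mean_velocity_planar, 2),
                "hmm_entropy_rate": round(hf.transition_entropy_rate, 3),
                "score": score.score,
                "category": score.category,
            })
    df = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "stabilogram_scores.csv", index=False)
    print(df.groupby("stability_level")[["path_length_planar_mm", "score"]]
          .mean().round(2))
    print(f"wrote {OUT / 'stabilogram_scores.csv'}")


if __name__ == "__main__":
    main()
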