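"""Build the packaged balance-score reference population.

Simulates 1,000 quiet-stance traces spanning the stability range
(stability level uniform on [0.15, 1.0]), computes each trace's linear
sway metrics and sway-HMM descriptors, and freezes the population
means/scales and the decile edges of the weighted z-composite into
``src/fallsway/data/default_score_reference.json``.

The resulting mapping is the package's openly documented stand-in
score: quietest reference decile -> 10, most unstable -> 1.  HMM fits
here use a single restart and a loose tolerance — population deciles
are insensitive to restart-level fitting noise and the build stays
cheap.  Deterministic; rerunning reproduces the packaged file.
"""

from __future__ import annotations

import sys
import time
from pathlib import Path

import numpy as np

from fallsway import cop_signal, sway_hmm, synthetic_data

N_TRACES = 1_000
STABILITY_RANGE = (0.15, 1.0)
SEED = 20_220_101
FEATURES = (
    "mean_velocity_planar",
    "rms_jerk_ml",
    "rms_jerk_ap",
    "neg_loglik_per_sample",
    "transition_entropy_rate",
    "largest_state_scale",
)

OUT = Path(__file__).resolve().parents[1] / "src" / "fallsway" / "data" / \
    "default_score_reference.json"


def main() -> None:
    n = int(sys.argv[1]) if len(sys.argv) > 1 else N_TRACES
    rng = np.random.default_rng(SEED)
    rows = []
    t0 = time.time()
    for i in range(n):
        stability = float(rng.uniform(*STABILITY_RANGE))
        cfg = synthetic_data.SwaySimConfig(
            stability_level=stability, seed=int(rng.integers(2**31 - 1)))
        trace = synthetic_data.simulate_cop_trace(cfg)
        clean = cop_signal.preprocess_trace(trace, demean=True)
        feats = cop_signal.compute_sway_features(clean)
        model = sway_hmm.fit_hmm(
            clean.increments(), seed=int(rng.integers(2**31 - 1)),
            n_restarts=1, max_iter=30, tol=1e-3)
        hf = sway_hmm.hmm_features(model, clean.increments(),
                                   sample_rate_hz=clean.sample_rate_hz)
        rows.append(cop_signal.instability_features(feats, hf))
        if (i + 1) % 100 == 0:
            print(f"  {i + 1}/{n} traces ({time.time() - t0:.0f} s)")

    reference = cop_signal.build_reference(rows, FEATURES)
    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(reference.to_json() + "\n")
    print(f"wrote {OUT}")
    print("decile edges:", np.round(reference.decile_edges, 3))


if __name__ == "__main__":
    main()
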