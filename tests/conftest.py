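import datetime as dt

import numpy as np
import pytest

from fallsway import cop_signal, synthetic_data


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_trace(ml, ap, rate=100.0, pid="T001", date=dt.date(2022, 3, 1)):
    ml = np.asarray(ml, float)
    return cop_signal.CopTrace(
        participant_id=pid,
        test_date=date,
        sample_rate_hz=rate,
        duration_s=len(ml) / rate,
        ml=ml,
        ap=np.asarray(ap, float),
    )


@pytest.fixture(scope="session")
def sim_trace():
    cfg = synthetic_data.SwaySimConfig(stability_level=0.7, seed=99)
    return synthetic_data.simulate_cop_trace(cfg)


@pytest.fixture(scope="session")
def linear_reference():
    """Small score reference over linear sway features only (no HMM stage),
    built from 60 simulated traces spanning the stability range."""
    rng = np.random.default_rng(2024)
    rows = []
    for _ in range(60):
        cfg = synthetic_data.SwaySimConfig(
            stability_level=float(rng.uniform(0.15, 1.0)),
            seed=int(rng.integers(2**31 - 1)),
        )
        trace = synthetic_data.simulate_cop_trace(cfg)
        clean = cop_signal.preprocess_trace(trace, demean=True)
        rows.append(cop_signal.instability_features(
            cop_signal.compute_sway_features(clean)))
    return cop_signal.build_reference(
        rows, ("mean_velocity_planar", "rms_jerk_ml", "rms_jerk_ap"))


@pytest.fixture(scope="session")
def small_cohort():
    cfg = synthetic_data.CohortSimConfig(n_participants=200, seed=31)
    return synthetic_data.simulate_cohort(cfg)
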