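"""Synthetic stabilograms, score trajectories, and fall cohorts.

No participant-level data from self-monitoring balance studies is
publicly deposited, so every pipeline stage is exercised against
generators with known ground truth:

* :func:`simulate_cop_trace` — a quiet-stance stabilogram: per axis a
  discretized mean-reverting (Ornstein-Uhlenbeck) process whose
  innovation scale is modulated by a hidden sticky Markov regime chain,
  so the sway HMM has genuinely recoverable latent structure.  Lower
  ``stability_level`` means proportionally larger innovations.
* :func:`simulate_cohort` — a two-site cohort with per-participant
  Poisson fall processes (distinct retrospective and prospective rates),
  truncated-normal follow-up durations, site-specific test cadences
  (monthly vs bimonthly), and integer score trajectories in which a
  configurable fraction of high-risk baselines improve over time.

Defaults are calibrated to the margins of the two-site self-monitoring
cohort this package analyzes: 53 participants (57% senior living
facility / 43% community center), 0.70 retrospective falls per
person-year, a true prospective/retrospective rate ratio of 0.26, mean
follow-up 0.73 +- 0.6 years, 42.9% of high-risk baselines improving,
and at most one prospective fall per participant.  All are overridable
and every generator is deterministic given its seed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml
from scipy import stats as _stats

from .cop_signal import CopTrace
from .fall_epi import (
    PERIOD_PROSPECTIVE,
    PERIOD_RETRO6,
    PERIOD_RETRO12,
    SITE_SCC,
    SITE_SLF,
    CohortLedger,
    FallRecord,
    Participant,
)
from .risk_shift import ScoreHistory

_EPOCH = _dt.date(2022, 1, 1)   # arbitrary calendar anchor for simulated dates


# ---------------------------------------------------------------------------
# stabilogram generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SwaySimConfig:
    """Configuration of the regime-switching sway generator.

    ``stability_level`` in (0, 1]: 1 is the steadiest standing; the
    innovation scale of the mean-reverting COP process is proportional
    to ``base_noise_scale / stability_level``.  ``regime_scales``
    multiply that scale per hidden regime.
    """

    stability_level: float = 1.0
    n_regimes: int = 3
    regime_stickiness: float = 0.95
    ou_mean_reversion: float = 1.0          # 1/s
    base_noise_scale: float = 1.0           # mm/sqrt(s)
    regime_scales: tuple[float, ...] = (0.6, 1.0, 1.8)
    ml_attenuation: float = 0.7             # mediolateral sway < anteroposterior
    sample_rate_hz: float = 100.0
    duration_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.stability_level <= 1:
            raise ValueError("stability_level must lie in (0, 1]")
        if not 0 < self.regime_stickiness < 1:
            raise ValueError("regime_stickiness must lie in (0, 1)")
        if min(self.ou_mean_reversion, self.base_noise_scale,
               self.sample_rate_hz, self.duration_s) <= 0:
            raise ValueError("rates and scales must be positive")
        if self.n_regimes < 1 or len(self.regime_scales) != self.n_regimes:
            raise ValueError("regime_scales must have n_regimes entries")

    @classmethod
    def from_yaml(cls, path) -> "SwaySimConfig":
        return _config_from_yaml(cls, path)


def _config_from_yaml(cls, path):
    """Build a simulation config from a flat YAML key-value file;
    unknown keys are rejected, list values become tuples."""
    obj = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(obj, dict):
        raise ValueError(f"{path}: expected a mapping of config fields")
    known = {f.name for f in fields(cls)}
    unknown = set(obj) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    obj = {k: tuple(v) if isinstance(v, list) else v for k, v in obj.items()}
    return cls(**obj)


def sticky_transition_matrix(n_states: int, stickiness: float) -> np.ndarray:
    """Self-transition probability ``stickiness``, remainder uniform."""
    if n_states == 1:
        return np.array([[1.0]])
    off = (1.0 - stickiness) / (n_states - 1)
    P = np.full((n_states, n_states), off)
    np.fill_diagonal(P, stickiness)
    return P


def simulate_markov_chain(P: np.ndarray, n_steps: int, rng: np.random.Generator,
                          initial: int | None = None) -> np.ndarray:
    """Sample a state path from transition matrix ``P``."""
    P = np.asarray(P, float)
    k = P.shape[0]
    states = np.empty(n_steps, dtype=int)
    states[0] = rng.integers(k) if initial is None else initial
    cum = P.cumsum(axis=1)
    u = rng.random(n_steps)
    for t in range(1, n_steps):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t])
    return states


def simulate_cop_trace(
    config: SwaySimConfig,
    participant_id: str = "sim",
    test_date: _dt.date = _EPOCH,
    return_regimes: bool = False,
):
    """Simulate one quiet-stance COP trace.

    Euler-Maruyama discretization of an OU process per axis,
    x_{t+1} = x_t (1 - theta dt) + s_regime sqrt(dt) eps, with the
    regime chain shared between axes and the mediolateral axis
    attenuated.  Bit-reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = round(config.sample_rate_hz * config.duration_s)
    dt = 1.0 / config.sample_rate_hz

    P = sticky_transition_matrix(config.n_regimes, config.regime_stickiness)
    regimes = simulate_markov_chain(P, n, rng)
    sigma = (config.base_noise_scale / config.stability_level
             * np.asarray(config.regime_scales)[regimes])

    decay = 1.0 - config.ou_mean_reversion * dt
    noise = rng.standard_normal((n, 2)) * (sigma * np.sqrt(dt))[:, None]
    xy = np.empty((n, 2))
    xy[0] = noise[0]
    for t in range(1, n):
        xy[t] = xy[t - 1] * decay + noise[t]
    xy[:, 0] *= config.ml_attenuation

    trace = CopTrace(
        participant_id=participant_id,
        test_date=test_date,
        sample_rate_hz=config.sample_rate_hz,
        duration_s=config.duration_s,
        ml=xy[:, 0],
        ap=xy[:, 1],
    )
    return (trace, regimes) if return_regimes else trace


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSimConfig:
    """Configuration of the cohort, fall-process, and score-trajectory
    generator (defaults: the calibrated study conditions)."""

    n_participants: int = 53
    slf_fraction: float = 0.57
    age_mean_sd: dict = field(default_factory=lambda: {
        SITE_SLF: (86.7, 6.0), SITE_SCC: (72.1, 4.8)})
    female_fraction: float = 0.81
    lambda_retro: float = 0.70              # falls per person-year, recall period
    rate_ratio: float = 0.26                # true prospective/retrospective ratio
    duration_mean_years: float = 0.73
    duration_sd_years: float = 0.6
    test_cadence_days: dict = field(default_factory=lambda: {
        SITE_SLF: 30, SITE_SCC: 60})
    improving_fraction: float = 0.429       # of high-risk baselines
    improvement_timescale_days: float = 20.0
    score_jitter_prob: float = 0.08         # chance of a +-1 excursion per test
    syncope_event_prob: float = 0.03
    max_one_prospective_fall: bool = True
    seed: int = 0

    # baseline score distribution over 1..10 (roughly 26% high / 40%
    # moderate / 34% low risk)
    baseline_score_probs: tuple[float, ...] = (
        0.04, 0.10, 0.12, 0.14, 0.14, 0.12, 0.12, 0.10, 0.07, 0.05)

    def __post_init__(self) -> None:
        for frac in (self.slf_fraction, self.female_fraction,
                     self.improving_fraction, self.score_jitter_prob):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.lambda_retro < 0 or self.rate_ratio < 0:
            raise ValueError("rates must be non-negative")
        if abs(sum(self.baseline_score_probs) - 1.0) > 1e-9:
            raise ValueError("baseline_score_probs must sum to 1")

    @classmethod
    def from_yaml(cls, path) -> "CohortSimConfig":
        return _config_from_yaml(cls, path)


@dataclass(frozen=True)
class GroundTruth:
    """Generator parameters a recovery analysis should estimate back."""

    lambda_retro: float
    rate_ratio: float
    improving_fraction: float
    n_high_risk_baseline: int
    n_improvers: int


@dataclass(frozen=True)
class SimulatedCohort:
    participants: tuple[Participant, ...]
    fall_log: tuple[FallRecord, ...]
    score_histories: tuple[ScoreHistory, ...]
    ground_truth: GroundTruth


def _truncated_normal_days(rng, mean_years, sd_years, size):
    a = (0.0 - mean_years) / sd_years
    draws = _stats.truncnorm.rvs(a, np.inf, loc=mean_years, scale=sd_years,
                                 size=size, random_state=rng)
    return np.round(draws * 365.0).astype(int)


def simulate_cohort(config: CohortSimConfig, include_scores: bool = True) -> SimulatedCohort:
    """Simulate a two-site self-monitoring cohort with known ground truth.

    Retrospective 12-month falls are Poisson(``lambda_retro``) with event
    dates uniform over the year before enrollment (the last-6-months
    subset gives the 6-month recall count); prospective falls are
    Poisson(``lambda_retro * rate_ratio * exposure_years``), optionally
    capped at one per participant, with dates uniform over the monitored
    window.  Test dates follow the site cadence; participation ends at
    the last scheduled test inside the drawn follow-up duration, so
    short draws yield single-test participants with zero prospective
    exposure.  Score trajectories (``include_scores``) start from a
    baseline drawn from ``baseline_score_probs``; the configured
    fraction of high-risk baselines relaxes exponentially toward the
    moderate band, everyone else fluctuates about baseline.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    sites = np.where(rng.random(n) < config.slf_fraction, SITE_SLF, SITE_SCC)
    sexes = np.where(rng.random(n) < config.female_fraction, "F", "M")
    durations = _truncated_normal_days(
        rng, config.duration_mean_years, config.duration_sd_years, n)
    start_offsets = rng.integers(0, 365, size=n)

    baseline_scores = rng.choice(
        np.arange(1, 11), size=n, p=np.asarray(config.baseline_score_probs))
    high_risk = baseline_scores <= 3
    improver = high_risk & (rng.random(n) < config.improving_fraction)

    participants: list[Participant] = []
    fall_log: list[FallRecord] = []
    histories: list[ScoreHistory] = []

    for i in range(n):
        pid = f"P{i + 1:04d}"
        site = str(sites[i])
        first = _EPOCH + _dt.timedelta(days=int(start_offsets[i]))
        cadence = config.test_cadence_days[site]
        n_tests = 1 + int(durations[i]) // cadence
        test_days = [k * cadence for k in range(n_tests)]
        last = first + _dt.timedelta(days=test_days[-1])
        exposure_days = test_days[-1]

        mu, sigma = config.age_mean_sd[site]
        age = float(np.clip(rng.normal(mu, sigma), 60.0, 105.0))

        # retrospective falls: dated events over the year before enrollment
        n_retro = rng.poisson(config.lambda_retro)
        retro_records = []
        for back in rng.integers(1, 366, size=n_retro):
            event = first - _dt.timedelta(days=int(back))
            period = PERIOD_RETRO6 if back <= 183 else PERIOD_RETRO12
            retro_records.append(FallRecord(pid, event, period))
        falls_6m = sum(1 for r in retro_records if r.period == PERIOD_RETRO6)

        # prospective falls over the monitored window
        exposure_years = exposure_days / 365.0
        n_pros = rng.poisson(config.lambda_retro * config.rate_ratio * exposure_years)
        if config.max_one_prospective_fall:
            n_pros = min(n_pros, 1)
        pros_records = []
        if exposure_days > 0:
            for day in rng.integers(1, exposure_days + 1, size=n_pros):
                event = first + _dt.timedelta(days=int(day))
                pros_records.append(FallRecord(pid, event, PERIOD_PROSPECTIVE))
        if exposure_days > 0 and rng.random() < config.syncope_event_prob:
            day = int(rng.integers(1, exposure_days + 1))
            pros_records.append(FallRecord(
                pid, first + _dt.timedelta(days=day), PERIOD_PROSPECTIVE,
                syncope_excluded=True))

        participants.append(Participant(
            id=pid, site=site, sex=str(sexes[i]), age_years=age,
            first_test_date=first, last_test_date=last, n_tests=n_tests,
            falls_retro_6m=falls_6m, falls_retro_12m=len(retro_records),
            prospective_falls=tuple(pros_records),
        ))
        fall_log.extend(retro_records)
        fall_log.extend(pros_records)

        if include_scores:
            base = int(baseline_scores[i])
            target = min(base + 3, 6) if improver[i] else base
            entries = []
            q = config.score_jitter_prob / 2.0
            for day in test_days:
                drift = (target - base) * (
                    1.0 - np.exp(-day / config.improvement_timescale_days))
                jitter = int(rng.choice((-1, 0, 1), p=(q, 1.0 - 2 * q, q)))
                s = round(base + drift) + (jitter if day > 0 else 0)
                entries.append((first + _dt.timedelta(days=day),
                                int(np.clip(s, 1, 10))))
            histories.append(ScoreHistory(pid, tuple(entries)))

    truth = GroundTruth(
        lambda_retro=config.lambda_retro,
        rate_ratio=config.rate_ratio,
        improving_fraction=config.improving_fraction,
        n_high_risk_baseline=int(high_risk.sum()),
        n_improvers=int(improver.sum()),
    )
    return SimulatedCohort(
        participants=tuple(participants),
        fall_log=tuple(fall_log),
        score_histories=tuple(histories),
        ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# deterministic calibration fixtures
# ---------------------------------------------------------------------------

#: Externally reported rate ratios of the reference cohort, used by
#: reporting to cross-check computed estimates (see analyze_cohort notes).
PUBLISHED_REFERENCE = {"irr_falls": 0.260, "irr_fallers": 0.438}


def reference_cohort_ledger() -> CohortLedger:
    """Aggregate ledger of the two-site self-monitoring reference cohort
    the simulator defaults are calibrated to: 53 participants, 37
    retrospective falls (12-month recall) among 21 fallers, 7
    prospective falls among 7 fallers, 53 retrospective and 38.61
    prospective person-years."""
    return CohortLedger(
        n=53,
        py_retro=53.0,
        py_pros=38.61,
        falls_retro=37,
        falls_pros=7,
        fallers_retro=21,
        fallers_pros=7,
        label="reference cohort (all sites)",
    )


def matched_cohort_fixture() -> tuple[Participant, ...]:
    """Deterministic 21-participant roster reproducing the reference
    cohort's matched-period margins: the 6-month subset has 7
    retrospective falls (6 fallers) against 5 prospective falls (5
    fallers) in the first six months, and its 13-participant 12-month
    subset has 9 retrospective falls (6 fallers) against 6 prospective
    falls (5 fallers) in the first year."""
    first = _dt.date(2022, 1, 10)

    def prospective(pid: str, *days: int) -> tuple[FallRecord, ...]:
        return tuple(
            FallRecord(pid, first + _dt.timedelta(days=d), PERIOD_PROSPECTIVE)
            for d in days
        )

    # (retro6, retro12, prospective fall days, enrolled days)
    long, short = 370, 200                       # >=12 and >=6 calendar months
    rows = [
        ("M01", 2, 2, (), long),
        ("M02", 1, 2, (), long),
        ("M03", 1, 2, (), long),
        ("M04", 1, 1, (), long),
        ("M05", 1, 1, (), long),
        ("M06", 1, 1, (), long),
        ("M07", 0, 0, (100, 320), long),         # second fall beyond 6 months
        ("M08", 0, 0, (110,), long),
        ("M09", 0, 0, (120,), long),
        ("M10", 0, 0, (130,), long),
        ("M11", 0, 0, (300,), long),             # falls between 6 and 12 months
        ("M12", 0, 0, (), long),
        ("M13", 0, 0, (), long),
        ("M14", 0, 0, (140,), short),
    ] + [(f"M{i:02d}", 0, 0, (), short) for i in range(15, 22)]

    participants = []
    for pid, r6, r12, pros_days, enrolled in rows:
        participants.append(Participant(
            id=pid, site=SITE_SLF, sex="F", age_years=85.5,
            first_test_date=first,
            last_test_date=first + _dt.timedelta(days=enrolled),
            n_tests=1 + enrolled // 30,
            falls_retro_6m=r6, falls_retro_12m=r12,
            prospective_falls=prospective(pid, *pros_days),
        ))
    return tuple(participants)
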