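"""Center-of-pressure signal processing and balance scoring.

A quiet-stance trial yields a two-axis center-of-pressure (COP) trajectory
— the stabilogram.  This module preprocesses raw traces, computes the
linear sway metrics used in posturography (path length, mean velocity,
RMS acceleration and jerk, per axis and planar), and maps a trace's
combined linear + hidden-Markov descriptors onto a 1-10 balance score
with the standard three-band risk reading: 1-3 high risk ("red"),
4-6 moderate ("yellow"), 7-10 low risk ("green").

The score mapping here is an openly documented stand-in — a weighted
z-score composite binned against the deciles of a simulated reference
population — NOT any commercial posturography score.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as _sig

logger = logging.getLogger(__name__)

NOMINAL_RATE_HZ = 100.0
NOMINAL_DURATION_S = 60.0

CATEGORY_HIGH = "high"
CATEGORY_MODERATE = "moderate"
CATEGORY_LOW = "low"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CopTrace:
    """One quiet-stance stabilogram: mediolateral (ml) and anteroposterior
    (ap) COP displacement in mm, nominally 100 Hz for 60 s."""

    participant_id: str
    test_date: _dt.date
    sample_rate_hz: float
    duration_s: float
    ml: np.ndarray
    ap: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ml", np.asarray(self.ml, dtype=float))
        object.__setattr__(self, "ap", np.asarray(self.ap, dtype=float))
        validate_trace(self)

    @property
    def n_samples(self) -> int:
        return self.ml.size

    def increments(self) -> np.ndarray:
        """Per-sample (Δml, Δap) displacement increments, shape (n-1, 2)."""
        return np.column_stack([np.diff(self.ml), np.diff(self.ap)])


def validate_trace(trace: CopTrace) -> None:
    if trace.sample_rate_hz <= 0:
        raise ValueError(f"sample_rate_hz must be positive, got {trace.sample_rate_hz}")
    if trace.duration_s <= 0:
        raise ValueError(f"duration_s must be positive, got {trace.duration_s}")
    if trace.ml.ndim != 1 or trace.ap.ndim != 1:
        raise ValueError("ml and ap must be one-dimensional")
    if trace.ml.size != trace.ap.size:
        raise ValueError(
            f"axis length mismatch: ml has {trace.ml.size} samples, ap has {trace.ap.size}"
        )
    expected = round(trace.sample_rate_hz * trace.duration_s)
    if trace.ml.size != expected:
        raise ValueError(
            f"sample count {trace.ml.size} does not match "
            f"sample_rate_hz x duration_s = {expected}"
        )
    if not np.isfinite(trace.ml).all() or not np.isfinite(trace.ap).all():
        raise ValueError("trace contains non-finite samples")
    if abs(trace.duration_s - NOMINAL_DURATION_S) > 1e-9:
        logger.warning(
            "trace %s/%s has duration %.3f s (nominal %.0f s); using as measured",
            trace.participant_id, trace.test_date, trace.duration_s, NOMINAL_DURATION_S,
        )


@dataclass(frozen=True)
class SwayFeatures:
    """Linear sway metrics of one stabilogram.

    Path lengths in mm, mean velocities in mm/s, RMS accelerations in
    mm/s^2, RMS jerks in mm/s^3.  ``planar`` quantities use Euclidean
    increments over both axes.
    """

    path_length_ml: float
    path_length_ap: float
    path_length_planar: float
    mean_velocity_ml: float
    mean_velocity_ap: float
    mean_velocity_planar: float
    rms_acceleration_ml: float
    rms_acceleration_ap: float
    rms_jerk_ml: float
    rms_jerk_ap: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class BalanceScore:
    """Integer 1-10 balance score with its risk band.

    ``instability_index`` is the internal weighted z-composite the
    stand-in mapping bins into deciles; larger means more sway.
    """

    score: int
    category: str
    instability_index: float

    def __post_init__(self) -> None:
        if categorize_score(self.score) != self.category:
            raise ValueError(
                f"category {self.category!r} inconsistent with score {self.score}"
            )


@dataclass(frozen=True)
class ScoreReference:
    """Reference population statistics the stand-in score mapping bins against.

    ``feature_names`` selects entries from the instability-oriented feature
    vector (see :func:`instability_features`); ``decile_edges`` are the nine
    increasing decile cut points of the reference population's instability
    index.
    """

    feature_names: tuple[str, ...]
    feature_means: np.ndarray
    feature_scales: np.ndarray
    feature_weights: np.ndarray
    decile_edges: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature_means", np.asarray(self.feature_means, float))
        object.__setattr__(self, "feature_scales", np.asarray(self.feature_scales, float))
        object.__setattr__(self, "feature_weights", np.asarray(self.feature_weights, float))
        object.__setattr__(self, "decile_edges", np.asarray(self.decile_edges, float))
        k = len(self.feature_names)
        for name in ("feature_means", "feature_scales", "feature_weights"):
            if getattr(self, name).shape != (k,):
                raise ValueError(f"{name} must have length {k}")
        if np.any(self.feature_scales <= 0):
            raise ValueError("feature_scales must be positive")
        if np.any(self.feature_weights < 0) or not np.any(self.feature_weights > 0):
            raise ValueError("weights must be >= 0 with at least one > 0")
        if self.decile_edges.size != 9 or np.any(np.diff(self.decile_edges) <= 0):
            raise ValueError("decile_edges must be 9 strictly increasing cut points")

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": list(self.feature_names),
                "feature_means": self.feature_means.tolist(),
                "feature_scales": self.feature_scales.tolist(),
                "feature_weights": self.feature_weights.tolist(),
                "decile_edges": self.decile_edges.tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ScoreReference":
        obj = json.loads(text)
        return cls(
            feature_names=tuple(obj["feature_names"]),
            feature_means=obj["feature_means"],
            feature_scales=obj["feature_scales"],
            feature_weights=obj["feature_weights"],
            decile_edges=obj["decile_edges"],
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def preprocess_trace(
    raw: CopTrace,
    demean: bool = True,
    lowpass_cutoff_hz: float | None = None,
) -> CopTrace:
    """Demean and optionally zero-phase low-pass filter a COP trace.

    The filter is a 4th-order Butterworth applied forward-backward
    (``filtfilt``), so it adds no phase lag.  Sample count is unchanged.

    Raises
    ------
    ValueError
        If the trace contains non-finite samples, or the cutoff is at or
        above the Nyquist frequency.
    """
    ml, ap = raw.ml, raw.ap
    if lowpass_cutoff_hz is not None:
        nyquist = raw.sample_rate_hz / 2.0
        if not 0 < lowpass_cutoff_hz < nyquist:
            raise ValueError(
                f"lowpass cutoff {lowpass_cutoff_hz} Hz must lie in (0, {nyquist}) Hz"
            )
        sos = _sig.butter(4, lowpass_cutoff_hz, btype="low",
                          fs=raw.sample_rate_hz, output="sos")
        ml = _sig.sosfiltfilt(sos, ml)
        ap = _sig.sosfiltfilt(sos, ap)
    if demean:
        ml = ml - ml.mean()
        ap = ap - ap.mean()
    return replace(raw, ml=ml, ap=ap)


def _derivative(x: np.ndarray, fs: float) -> np.ndarray:
    # central differences, one-sided at the ends
    return np.gradient(x) * fs


def compute_sway_features(trace: CopTrace) -> SwayFeatures:
    """Compute the linear sway metrics of one stabilogram.

    Path length sums absolute per-axis increments (Euclidean increments
    for the planar value); mean velocity is path length over trial
    duration; acceleration and jerk are second and third central finite
    differences summarized as RMS.
    """
    if trace.n_samples < 3:
        raise ValueError(
            f"need at least 3 samples to compute jerk, got {trace.n_samples}"
        )
    fs = trace.sample_rate_hz
    dml, dap = np.diff(trace.ml), np.diff(trace.ap)
    path_ml = float(np.abs(dml).sum())
    path_ap = float(np.abs(dap).sum())
    path_planar = float(np.hypot(dml, dap).sum())

    feats = {}
    for axis, x in (("ml", trace.ml), ("ap", trace.ap)):
        vel = _derivative(x, fs)
        acc = _derivative(vel, fs)
        jerk = _derivative(acc, fs)
        feats[f"rms_acceleration_{axis}"] = float(np.sqrt(np.mean(acc**2)))
        feats[f"rms_jerk_{axis}"] = float(np.sqrt(np.mean(jerk**2)))

    return SwayFeatures(
        path_length_ml=path_ml,
        path_length_ap=path_ap,
        path_length_planar=path_planar,
        mean_velocity_ml=path_ml / trace.duration_s,
        mean_velocity_ap=path_ap / trace.duration_s,
        mean_velocity_planar=path_planar / trace.duration_s,
        **feats,
    )


def categorize_score(score: int) -> str:
    """Map a 1-10 balance score to its risk band (1-3 high, 4-6 moderate,
    7-10 low)."""
    if not (isinstance(score, (int, np.integer)) and 1 <= score <= 10):
        raise ValueError(f"score must be an integer in [1, 10], got {score!r}")
    if score <= 3:
        return CATEGORY_HIGH
    if score <= 6:
        return CATEGORY_MODERATE
    return CATEGORY_LOW


def instability_features(
    sway: SwayFeatures,
    hmm: "object | None" = None,
) -> dict[str, float]:
    """Assemble the instability-oriented feature vector for scoring.

    Every entry is oriented so that larger means *less* stable; the
    log-likelihood per sample of the sway HMM is therefore negated
    (erratic sway is less predictable under the fitted model).
    """
    out = dict(sway.as_dict())
    if hmm is not None:
        out["neg_loglik_per_sample"] = -float(hmm.loglik_per_sample)
        out["transition_entropy_rate"] = float(hmm.transition_entropy_rate)
        out["largest_state_scale"] = float(hmm.largest_state_scale)
    return out


def score_balance(
    features: SwayFeatures,
    hmm_features: "object | None",
    reference: ScoreReference,
) -> BalanceScore:
    """Score one test by decile-binning its instability composite.

    The composite is sum_j w_j (x_j - mean_j) / scale_j over the
    reference's configured feature set; the score is 10 minus the number
    of reference decile edges the composite exceeds, so the quietest
    decile of the reference population maps to 10 and the most unstable
    to 1.
    """
    vector = instability_features(features, hmm_features)
    missing = [n for n in reference.feature_names if n not in vector]
    if missing:
        raise ValueError(
            f"reference requires features {missing} absent from the computed set "
            f"(was the HMM stage skipped?)"
        )
    x = np.array([vector[n] for n in reference.feature_names])
    z = (x - reference.feature_means) / reference.feature_scales
    index = float(np.dot(reference.feature_weights, z))
    score = 10 - int(np.sum(index > reference.decile_edges))
    return BalanceScore(score=score, category=categorize_score(score),
                        instability_index=index)


def default_reference() -> ScoreReference:
    """Load the packaged score reference (simulated population deciles)."""
    text = resources.files("fallsway.data").joinpath(
        "default_score_reference.json").read_text()
    return ScoreReference.from_json(text)


def build_reference(
    feature_rows: Sequence[Mapping[str, float]],
    feature_names: Sequence[str],
    weights: Sequence[float] | None = None,
) -> ScoreReference:
    """Build a :class:`ScoreReference` from a reference population's
    instability feature vectors.

    Location/scale are the population mean and standard deviation per
    feature; decile edges are the 10th..90th percentiles of the weighted
    z-composite.  Weights default to 1.
    """
    names = tuple(feature_names)
    X = np.array([[row[n] for n in names] for row in feature_rows], dtype=float)
    if X.shape[0] < 10:
        raise ValueError("reference population must have at least 10 members")
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    if np.any(scales <= 0):
        bad = [names[i] for i in np.nonzero(scales <= 0)[0]]
        raise ValueError(f"zero-variance reference features: {bad}")
    w = np.ones(len(names)) if weights is None else np.asarray(weights, float)
    idx = (X - means) / scales @ w
    edges = np.percentile(idx, np.arange(10, 100, 10))
    if np.any(np.diff(edges) <= 0):
        # ties can collapse percentiles in tiny populations
        warnings.warn("collapsed decile edges; jittering to keep them strict")
        edges = edges + np.arange(9) * 1e-12
    return ScoreReference(
        feature_names=names,
        feature_means=means,
        feature_scales=scales,
        feature_weights=w,
        decile_edges=edges,
    )
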