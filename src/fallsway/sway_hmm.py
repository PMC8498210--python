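"""Hidden Markov characterization of postural sway dynamics.

Quiet-stance COP increments are modelled with a Gaussian hidden Markov
model (diagonal covariance): latent stability regimes with sticky Markov
transitions, each emitting sway increments at its own scale.  The fitted
model is summarized by descriptors that complement the linear sway
metrics: state occupancy, the stationary distribution, mean dwell times,
the transition entropy rate, and the per-sample log-likelihood.

Fitting is Baum-Welch (EM) via :mod:`hmmlearn`, best-of-``n_restarts``
by final log-likelihood, fully seeded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM

logger = logging.getLogger(__name__)

DEFAULT_N_STATES = 3
DEFAULT_N_RESTARTS = 5
DEFAULT_MAX_ITER = 100
DEFAULT_TOL = 1e-4


@dataclass(frozen=True)
class HmmModel:
    """A fitted Gaussian HMM over a sway observation sequence.

    ``emission_scales`` are per-state, per-dimension standard deviations
    (diagonal covariance).  ``loglik_history`` is the per-iteration EM
    log-likelihood trace of the winning restart.
    """

    n_states: int
    initial_probs: np.ndarray
    transition_matrix: np.ndarray
    emission_means: np.ndarray          # (n_states, n_dims)
    emission_scales: np.ndarray         # (n_states, n_dims)
    log_likelihood: float
    seed: int
    converged: bool
    loglik_history: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        T = np.asarray(self.transition_matrix, float)
        pi0 = np.asarray(self.initial_probs, float)
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must each sum to 1")
        if not np.isclose(pi0.sum(), 1.0, atol=1e-9):
            raise ValueError("initial probabilities must sum to 1")
        if np.any(np.asarray(self.emission_scales) <= 0):
            raise ValueError("emission scales must be positive")

    @property
    def n_dims(self) -> int:
        return np.atleast_2d(self.emission_means).shape[1]

    def _to_hmmlearn(self) -> GaussianHMM:
        m = GaussianHMM(n_components=self.n_states, covariance_type="diag")
        m.startprob_ = np.asarray(self.initial_probs, float)
        m.transmat_ = np.asarray(self.transition_matrix, float)
        m.means_ = np.atleast_2d(np.asarray(self.emission_means, float))
        m.covars_ = np.atleast_2d(np.asarray(self.emission_scales, float)) ** 2
        return m

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_states": self.n_states,
                "initial_probs": np.asarray(self.initial_probs).tolist(),
                "transition_matrix": np.asarray(self.transition_matrix).tolist(),
                "emission_means": np.asarray(self.emission_means).tolist(),
                "emission_scales": np.asarray(self.emission_scales).tolist(),
                "log_likelihood": self.log_likelihood,
                "seed": self.seed,
                "converged": self.converged,
                "loglik_history": np.asarray(self.loglik_history).tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "HmmModel":
        obj = json.loads(text)
        return cls(
            n_states=obj["n_states"],
            initial_probs=np.array(obj["initial_probs"]),
            transition_matrix=np.array(obj["transition_matrix"]),
            emission_means=np.array(obj["emission_means"]),
            emission_scales=np.array(obj["emission_scales"]),
            log_likelihood=obj["log_likelihood"],
            seed=obj["seed"],
            converged=obj["converged"],
            loglik_history=np.array(obj["loglik_history"]),
        )


@dataclass(frozen=True)
class HmmFeatures:
    """Stability descriptors extracted from a fitted sway HMM.

    ``occupancy`` — fraction of Viterbi-decoded samples per state;
    ``stationary_distribution`` — left Perron eigenvector of the
    transition matrix; ``mean_dwell_time_s`` — expected sojourn per
    state, dt / (1 - P_ii); ``transition_entropy_rate`` — nats per step;
    ``loglik_per_sample`` — model fit quality; ``largest_state_scale``
    — RMS emission scale of the most dispersed state (an amplitude cue
    the balance score uses).
    """

    occupancy: np.ndarray
    stationary_distribution: np.ndarray
    mean_dwell_time_s: np.ndarray
    transition_entropy_rate: float
    loglik_per_sample: float
    largest_state_scale: float

    def __post_init__(self) -> None:
        for name in ("occupancy", "stationary_distribution"):
            v = np.asarray(getattr(self, name), float)
            if not np.isclose(v.sum(), 1.0, atol=1e-9):
                raise ValueError(f"{name} must sum to 1, got {v.sum()}")
        occ = np.asarray(self.occupancy)
        dwell = np.asarray(self.mean_dwell_time_s)
        if np.any(dwell[occ > 0] <= 0):
            raise ValueError("dwell times of occupied states must be positive")


def _as_obs(observations) -> np.ndarray:
    X = np.asarray(observations, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("observations must be a sequence of real vectors")
    return X


def fit_hmm(
    observations,
    n_states: int = DEFAULT_N_STATES,
    seed: int = 0,
    n_restarts: int = DEFAULT_N_RESTARTS,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> HmmModel:
    """Fit a diagonal-Gaussian HMM by Baum-Welch, best of ``n_restarts``.

    The per-iteration log-likelihood of every restart is checked for the
    EM monotonicity guarantee; the winning restart's history is kept on
    the returned model.

    Raises
    ------
    ValueError
        If the sequence is shorter than ``10 * n_states``, or has zero
        variance while ``n_states > 1`` (use a single state for a
        degenerate sequence).
    """
    X = _as_obs(observations)
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if X.shape[0] < 10 * n_states:
        raise ValueError(
            f"need at least {10 * n_states} observations for {n_states} states, "
            f"got {X.shape[0]}"
        )
    if np.allclose(X.var(axis=0), 0.0):
        if n_states > 1:
            raise ValueError(
                "observation sequence has zero variance; refit with n_states=1"
            )
        mean = X.mean(axis=0)
        return HmmModel(
            n_states=1,
            initial_probs=np.array([1.0]),
            transition_matrix=np.array([[1.0]]),
            emission_means=mean[None, :],
            emission_scales=np.full((1, X.shape[1]), 1e-6),
            log_likelihood=float("inf"),
            seed=seed,
            converged=True,
        )

    rng = np.random.default_rng(seed)
    best: HmmModel | None = None
    for _ in range(max(1, n_restarts)):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        m = GaussianHMM(
            n_components=n_states,
            covariance_type="diag",
            n_iter=max_iter,
            tol=tol,
            random_state=sub_seed,
            init_params="stmc",
        )
        m.fit(X)
        history = np.asarray(m.monitor_.history, dtype=float)
        ll = float(m.score(X))
        model = HmmModel(
            n_states=n_states,
            initial_probs=m.startprob_,
            transition_matrix=m.transmat_,
            emission_means=m.means_,
            emission_scales=np.sqrt(
                np.diagonal(m.covars_, axis1=1, axis2=2)
                if m.covars_.ndim == 3 else np.atleast_2d(m.covars_)
            ),
            log_likelihood=ll,
            seed=sub_seed,
            converged=bool(m.monitor_.converged),
            loglik_history=history,
        )
        if np.any(np.diff(history) < -1e-6):
            logger.warning("EM log-likelihood decreased during a restart; "
                           "discarding that restart")
            continue
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    if best is None:
        raise RuntimeError("all EM restarts violated monotonicity")
    return best


def decode_states(model: HmmModel, observations) -> np.ndarray:
    """Viterbi-decode the maximum-probability state path."""
    X = _as_obs(observations)
    if X.shape[0] == 0:
        raise ValueError("cannot decode an empty observation sequence")
    if X.shape[1] != model.n_dims:
        raise ValueError(
            f"observation dimension {X.shape[1]} does not match model "
            f"dimension {model.n_dims}"
        )
    if model.n_states == 1:
        return np.zeros(X.shape[0], dtype=int)
    _, path = model._to_hmmlearn().decode(X, algorithm="viterbi")
    return path


def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution pi with pi P = pi.

    For a reducible (non-ergodic) chain the distribution of one
    recurrent class is returned with a logged warning.
    """
    P = np.asarray(transition_matrix, float)
    vals, vecs = np.linalg.eig(P.T)
    idx = np.isclose(vals, 1.0, atol=1e-8)
    if not idx.any():
        raise ValueError("transition matrix has no unit eigenvalue")
    candidates = []
    for i in np.nonzero(idx)[0]:
        v = np.real(vecs[:, i])
        if np.all(v >= -1e-10) or np.all(v <= 1e-10):
            v = np.abs(v)
            candidates.append(v / v.sum())
    if not candidates:
        raise ValueError("no non-negative stationary eigenvector found")
    if idx.sum() > 1:
        logger.warning(
            "transition matrix is not ergodic (%d recurrent classes); "
            "returning the stationary distribution of one recurrent class",
            int(idx.sum()),
        )
    return candidates[0]


def hmm_features(model: HmmModel, observations, sample_rate_hz: float = 100.0) -> HmmFeatures:
    """Extract the stability descriptors of a fitted sway HMM.

    Entropy rate is - sum_i pi_i sum_j P_ij log P_ij (nats/step, with
    0 log 0 = 0); dwell times are dt / (1 - P_ii), infinite for an
    absorbing state.
    """
    X = _as_obs(observations)
    path = decode_states(model, X)
    occupancy = np.bincount(path, minlength=model.n_states) / path.size
    pi = stationary_distribution(model.transition_matrix)

    P = np.asarray(model.transition_matrix, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logP = np.where(P > 0, np.log(np.where(P > 0, P, 1.0)), 0.0)
    entropy_rate = float(-(pi[:, None] * P * logP).sum())

    dt = 1.0 / sample_rate_hz
    diag = np.diag(P)
    with np.errstate(divide="ignore"):
        dwell = np.where(diag < 1.0, dt / (1.0 - diag), np.inf)

    scales = np.atleast_2d(model.emission_scales)
    largest = float(np.sqrt((scales**2).mean(axis=1)).max())
    ll = model.log_likelihood
    loglik_per_sample = float(ll / X.shape[0]) if np.isfinite(ll) else 0.0

    return HmmFeatures(
        occupancy=occupancy,
        stationary_distribution=pi,
        mean_dwell_time_s=dwell,
        transition_entropy_rate=entropy_rate,
        loglik_per_sample=loglik_per_sample,
        largest_state_scale=largest,
    )
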