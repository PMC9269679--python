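"""Unsupervised first-pass segmentation of a conditioned gait signal.

A Gaussian-emission hidden Markov model (diagonal covariance) is fit by
expectation–maximization on a small per-sample feature vector (smoothed value,
first difference, windowed RMS), and the most probable state path is decoded.
State-change times give candidate stance/swing boundaries that are presented
alongside user hints; the final partition always comes from the hint matcher
(:mod:`gaitpartition.hint_partitioner`) — this stage is advisory only.

Fitting uses a fixed number of seeded random restarts and keeps the best
likelihood, so results are bit-reproducible for a given (input, seed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from hmmlearn.hmm import GaussianHMM

logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)

from .preprocess import kz_filter
from .signal_model import SignalTrace, ValidationError

__all__ = ["SegmentationResult", "extract_features", "segment_unsupervised"]

#: defaults: 6 states (mid "5-10" range), 10 restarts, 0.25 s feature window
DEFAULT_N_STATES = 6
DEFAULT_RESTARTS = 10
DEFAULT_WINDOW_S = 0.25
EM_TOL = 1e-4
EM_MAX_ITER = 200


@dataclass(frozen=True)
class SegmentationResult:
    state_seq: np.ndarray       # per-sample labels in 0..n_states-1
    boundaries_s: tuple         # times of state transitions
    n_states: int
    log_likelihood: float

    def __post_init__(self) -> None:
        if not 2 <= self.n_states <= 16:
            raise ValidationError("n_states must be in [2, 16]")
        b = tuple(float(t) for t in self.boundaries_s)
        if any(t1 <= t0 for t0, t1 in zip(b, b[1:])):
            raise ValidationError("boundaries must be strictly ascending")
        object.__setattr__(self, "boundaries_s", b)


def extract_features(x: SignalTrace, window_s: float = DEFAULT_WINDOW_S) -> np.ndarray:
    """Per-sample (smoothed value, first difference, windowed RMS) features."""
    n = len(x.values)
    w = max(int(round(window_s * x.rate_hz)), 2)
    if w > n:
        raise ValidationError(f"feature window of {w} samples exceeds trace length {n}")
    # light symmetric smoothing only: heavier conditioning would smear state
    # edges and bias the decoded boundary positions
    smoothed = kz_filter(x, m=3, k=1).values if n >= 3 else x.values
    diff = np.empty(n)
    diff[1:] = np.diff(x.values)
    diff[0] = diff[1] if n > 1 else 0.0
    # centered windowed RMS via cumulative sum of squares
    sq = np.concatenate([[0.0], np.cumsum(x.values**2)])
    half = w // 2
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + (w - half), 0, n)
    rms = np.sqrt((sq[hi] - sq[lo]) / np.maximum(hi - lo, 1))
    feats = np.column_stack([smoothed, diff, rms])
    if not np.all(np.isfinite(feats)):
        raise ValidationError("non-finite feature values")
    return feats


def segment_unsupervised(
    x: SignalTrace,
    n_states: int = DEFAULT_N_STATES,
    seed: int = 0,
    restarts: int = DEFAULT_RESTARTS,
    window_s: float = DEFAULT_WINDOW_S,
) -> SegmentationResult:
    """Fit a Gaussian HMM to the feature sequence and decode state boundaries.

    The best of ``restarts`` EM fits (by log-likelihood) is kept.  Raises if
    no restart converges to a finite likelihood, carrying the best attempt's
    score in the message.
    """
    if len(x.values) < 10 * n_states:
        raise ValidationError(
            f"trace of {len(x.values)} samples too short for {n_states} states "
            f"(need >= {10 * n_states})"
        )
    feats = extract_features(x, window_s=window_s)
    # guard against zero-variance features (constant input): tiny jitter keeps
    # the EM covariance floor meaningful without changing decoded boundaries
    scale = np.maximum(feats.std(axis=0), 1e-12)
    z = (feats - feats.mean(axis=0)) / scale
    if np.all(np.abs(z) < 1e-9):
        # constant input: EM is degenerate, and the only defensible answer is
        # a single state with no boundaries
        return SegmentationResult(
            state_seq=np.zeros(len(z), dtype=int),
            boundaries_s=(),
            n_states=n_states,
            log_likelihood=0.0,
        )

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(restarts, 1)):
        sub = int(rng.integers(0, 2**31 - 1))
        model = GaussianHMM(
            n_components=n_states,
            covariance_type="diag",
            n_iter=EM_MAX_ITER,
            tol=EM_TOL,
            random_state=sub,
            min_covar=1e-6,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model.fit(z)
                ll = float(model.score(z))
            except (ValueError, np.linalg.LinAlgError):
                continue
        hist = model.monitor_.history
        if len(hist) >= 2 and hist[-1] < hist[-2] - 1e-6 * max(1.0, abs(hist[-2])):
            continue  # EM diverged; discard this restart
        if np.isfinite(ll) and (best is None or ll > best[0]):
            best = (ll, model)
    if best is None:
        raise ValidationError("EM failed to converge in any restart")
    ll, model = best
    states = model.predict(z)
    change = np.flatnonzero(np.diff(states)) + 1
    boundaries = tuple(x.t0_s + i / x.rate_hz for i in change)
    return SegmentationResult(
        state_seq=states, boundaries_s=boundaries, n_states=n_states, log_likelihood=ll
    )


def match_states(pred: np.ndarray, truth: np.ndarray) -> float:
    """Best-assignment labelling accuracy (label-permutation invariant).

    Greedy assignment on the confusion matrix; exact for the well-separated
    two-state checks this module is validated with.
    """
    if len(pred) != len(truth):
        raise ValidationError("state sequences must have equal length")
    p_labels, t_labels = np.unique(pred), np.unique(truth)
    conf = np.zeros((len(p_labels), len(t_labels)), dtype=int)
    for i, p in enumerate(p_labels):
        for j, t in enumerate(t_labels):
            conf[i, j] = int(np.sum((pred == p) & (truth == t)))
    total = 0
    conf = conf.astype(float)
    for _ in range(min(conf.shape)):
        i, j = np.unravel_index(np.argmax(conf), conf.shape)
        total += conf[i, j]
        conf[i, :] = -1
        conf[:, j] = -1
    return total / len(pred)
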