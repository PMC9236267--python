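"""Response metrics, smoothing, weight features and the linear classifier.

Per-trial response metrics for the latency paradigm:

* **latency** — time of the first postsynaptic spike minus the reference
  point (the mean of the presynaptic delay distribution); missing (NaN) if
  the trial produced no spike.
* **duration** — interval between first and last postsynaptic spike.
* **intraburst frequency** — ``(n_spikes - 1)/duration`` in Hz, defined for
  trials with at least two spikes.

For the correlated/uncorrelated separation analysis, each input is reduced
to two features — the temporal mean and variance of its weight ``W`` over a
trailing window of the run — and a linear least-squares classifier (labels
coded ±1, prediction by sign) is trained on a stratified half of the inputs
and scored on the other half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TrialMetrics",
    "ClassifierModel",
    "compute_trial_metrics",
    "moving_average",
    "weight_features",
    "fit_classifier",
    "fraction_correct",
]


@dataclass(frozen=True)
class TrialMetrics:
    latency: float          # ms; NaN if no postsynaptic spike
    duration: float         # ms; NaN if no spike
    intraburst_frequency: float  # Hz; NaN unless n_spikes >= 2 and duration > 0
    n_spikes: int


def compute_trial_metrics(post_times: np.ndarray, reference: float) -> TrialMetrics:
    """Latency / duration / intraburst frequency of one trial's response."""
    t = np.asarray(post_times, dtype=float)
    n = int(t.size)
    if n == 0:
        return TrialMetrics(math.nan, math.nan, math.nan, 0)
    latency = float(t[0] - reference)
    duration = float(t[-1] - t[0])
    if n >= 2 and duration > 0:
        freq = (n - 1) / (duration / 1000.0)
    else:
        freq = math.nan
    return TrialMetrics(latency, duration, freq, n)


def moving_average(series, window: int = 3) -> np.ndarray:
    """Centered moving average; the ends use a shrunken window.

    NaN entries (e.g. trials without a response) are ignored within each
    window; a window with no finite values yields NaN.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    x = np.asarray(series, dtype=float)
    half = window // 2
    out = np.empty_like(x)
    for i in range(x.size):
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        seg = x[lo:hi]
        finite = seg[np.isfinite(seg)]
        out[i] = finite.mean() if finite.size else math.nan
    return out


def weight_features(W_trajectory: np.ndarray, window: float = 0.5) -> np.ndarray:
    """Per-synapse (mean, variance) of W over the trailing ``window`` fraction.

    ``W_trajectory`` has shape (n_samples, n_synapses); the default window is
    the final half of the run (steady behaviour).  Population variance.
    """
    W = np.asarray(W_trajectory, dtype=float)
    if W.ndim != 2 or W.shape[0] == 0:
        raise ValueError("W_trajectory must be a non-empty 2-D array")
    if not (0.0 < window <= 1.0):
        raise ValueError("window must lie in (0, 1]")
    start = W.shape[0] - max(1, int(round(window * W.shape[0])))
    tail = W[start:]
    return np.column_stack([tail.mean(axis=0), tail.var(axis=0)])


@dataclass
class ClassifierModel:
    """Linear least-squares separator on (mean, variance) features."""

    coef: np.ndarray            # [intercept, w_mean, w_var]
    train_idx: np.ndarray
    test_idx: np.ndarray
    fallback_label: int | None = None   # majority label if design was singular

    def predict(self, features: np.ndarray) -> np.ndarray:
        if self.fallback_label is not None:
            return np.full(features.shape[0], self.fallback_label)
        X = np.column_stack([np.ones(features.shape[0]), features])
        return np.where(X @ self.coef >= 0, 1, -1)


def _stratified_half_split(labels: np.ndarray, rng: np.random.Generator):
    train, test = [], []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        idx = rng.permutation(idx)
        half = idx.size // 2
        train.extend(idx[:half])
        test.extend(idx[half:])
    return np.sort(np.asarray(train)), np.sort(np.asarray(test))


def fit_classifier(features: np.ndarray, labels: np.ndarray,
                   split_seed=0) -> ClassifierModel:
    """Least-squares fit of ±1-coded labels on a stratified half of inputs.

    ``labels`` may be ±1 integers or string tags (the lexicographically
    larger tag is coded +1).  A singular design (identical features
    everywhere) falls back to the training majority label.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "US":
        classes = np.unique(labels)
        if classes.size != 2:
            raise ValueError("exactly two classes required")
        y = np.where(labels == classes[-1], 1, -1)
    else:
        y = labels.astype(int)
    rng = np.random.default_rng(split_seed)
    train_idx, test_idx = _stratified_half_split(y, rng)
    if min(np.sum(y[train_idx] == 1), np.sum(y[train_idx] == -1)) < 2:
        raise ValueError("need at least 2 training inputs per class")
    X = np.column_stack([np.ones(train_idx.size), features[train_idx]])
    if np.allclose(features[train_idx].var(axis=0), 0.0):
        maj = 1 if np.sum(y[train_idx] == 1) >= np.sum(y[train_idx] == -1) else -1
        return ClassifierModel(np.zeros(X.shape[1]), train_idx, test_idx,
                               fallback_label=maj)
    coef, *_ = np.linalg.lstsq(X, y[train_idx].astype(float), rcond=None)
    return ClassifierModel(coef, train_idx, test_idx)


def fraction_correct(model: ClassifierModel, features: np.ndarray,
                     labels: np.ndarray) -> float:
    """Proportion of the held-out inputs whose predicted sign matches."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "US":
        classes = np.unique(labels)
        y = np.where(labels == classes[-1], 1, -1)
    else:
        y = labels.astype(int)
    pred = model.predict(features[model.test_idx])
    return float(np.mean(pred == y[model.test_idx]))
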