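"""Time-resolved multiclass decoding with a shrinkage LDA classifier.

At each timepoint of the 100 Hz grid (one sample == one 10 ms bin) the 64
channel voltages form the feature vector of a 4-class linear discriminant
analysis.  The pooled within-class covariance is ridge-shrunk as
``S + lambda * mean(diag(S)) * I`` (toolbox-style regularization, default
``lambda = 0.01``), which guarantees invertibility with 64 features and a
few hundred trials.  Prediction is the Gaussian equal-covariance rule with
empirical priors; ties break to the first class in canonical label order
(happiness, pleasure, fear, sadness).

Three training/testing schemes are supported: ``all_all`` (every non-average
trial, leave-one-trial-out cross-validation) and the two cross-morph
generalizations ``full_to_f0`` / ``full_to_timbre`` (train once on all
full-morph trials, test on every F0 / timbre trial — train and test sets are
disjoint by construction, so no fold structure is needed).  Emotion-average
trials are excluded from every scheme.

Leave-one-trial-out does not refit from scratch: class sums and the pooled
scatter are downdated in O(d^2) per held-out trial, which is exact and keeps
a 600-trial x 100-timepoint decode tractable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import AVERAGE, EMOTIONS
from .simulate import EpochedEEG

DEFAULT_SHRINKAGE = 0.01
CHANCE = 0.25


@dataclass(frozen=True)
class LDAModel:
    """Fitted shrinkage-LDA: per-class means, shrunk pooled covariance,
    empirical priors, and the class-label order used for tie-breaking."""

    class_labels: tuple[str, ...]
    class_means: np.ndarray          # classes x features
    pooled_covariance: np.ndarray    # features x features, after shrinkage
    shrinkage: float
    priors: np.ndarray               # classes, sums to 1


@dataclass(frozen=True)
class DecodingScheme:
    name: str
    train_morphs: tuple[str, ...] | None   # None: all non-average morphs
    test_morphs: tuple[str, ...] | None
    cv: str                                # leave_one_trial_out | disjoint_train_test
    n_classes: int = 4

    @property
    def chance(self) -> float:
        return 1.0 / self.n_classes


SCHEMES: dict[str, DecodingScheme] = {
    "all_all": DecodingScheme("all_all", None, None, "leave_one_trial_out"),
    "full_to_f0": DecodingScheme(
        "full_to_f0", ("full",), ("f0",), "disjoint_train_test"),
    "full_to_timbre": DecodingScheme(
        "full_to_timbre", ("full",), ("timbre",), "disjoint_train_test"),
}


@dataclass
class AccuracyTimecourse:
    """Per-subject decoding accuracy on the post-stimulus time grid."""

    subject_id: str
    group: str
    scheme: str
    times: np.ndarray
    accuracy: np.ndarray
    n_test_trials: np.ndarray
    smoothed: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject_id,
                "group": self.group,
                "scheme": self.scheme,
                "time_ms": self.times,
                "accuracy": self.accuracy,
                "n_test_trials": self.n_test_trials,
                "smoothed": self.smoothed,
            }
        )


def _shrink(scatter: np.ndarray, dof: int, lam: float) -> np.ndarray:
    """Pooled covariance ``scatter / dof`` ridge-shrunk by
    ``lam * mean(diag) * I``; falls back to ``lam * I`` when the scatter is
    identically zero so degenerate (duplicated-trial) problems stay solvable."""
    cov = scatter / max(dof, 1)
    mean_diag = float(np.trace(cov)) / cov.shape[0]
    ridge = lam * mean_diag if mean_diag > 0 else lam
    return cov + ridge * np.eye(cov.shape[0])


def train_lda(X: np.ndarray, y: np.ndarray,
              shrinkage: float = DEFAULT_SHRINKAGE,
              class_labels: tuple[str, ...] | None = None) -> LDAModel:
    """Fit shrinkage LDA on trials x features data.

    ``class_labels`` fixes the class order (and thus tie-breaking); by
    default the canonical emotion order is used for emotion labels, else
    first-appearance order.  Every class must contribute at least 2 trials.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be trials x features, y one label per trial")
    if class_labels is None:
        present = list(dict.fromkeys(y.tolist()))
        if set(present) <= set(EMOTIONS):
            class_labels = tuple(e for e in EMOTIONS if e in present)
        else:
            class_labels = tuple(present)
    k = len(class_labels)
    if k < 2:
        raise ValueError("need at least 2 classes")

    n, d = X.shape
    means = np.empty((k, d))
    priors = np.empty(k)
    scatter = np.zeros((d, d))
    for i, lab in enumerate(class_labels):
        rows = X[y == lab]
        if len(rows) < 2:
            raise ValueError(f"class {lab!r} has {len(rows)} trial(s); need >= 2")
        means[i] = rows.mean(axis=0)
        priors[i] = len(rows) / n
        centered = rows - means[i]
        scatter += centered.T @ centered

    cov = _shrink(scatter, n - k, shrinkage)
    return LDAModel(tuple(class_labels), means, cov, shrinkage, priors)


def _discriminants(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Linear discriminant scores: log prior - 1/2 Mahalanobis^2 + const."""
    w = np.linalg.solve(model.pooled_covariance, model.class_means.T)  # d x k
    bias = np.log(model.priors) - 0.5 * np.einsum(
        "kd,dk->k", model.class_means, w)
    return X @ w + bias


def predict_lda(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Predict one label per row; ties break to the first class in
    ``model.class_labels`` order (argmax keeps the first maximum)."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.class_means.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({model.class_means.shape[1]})"
        )
    scores = _discriminants(model, X)
    idx = np.argmax(scores, axis=1)
    return np.asarray(model.class_labels, dtype=object)[idx]


def _class_order(y: np.ndarray) -> tuple[str, ...]:
    present = list(dict.fromkeys(y.tolist()))
    if set(present) <= set(EMOTIONS):
        return tuple(e for e in EMOTIONS if e in present)
    return tuple(present)


def _loto_accuracy(X: np.ndarray, y: np.ndarray, lam: float) -> float:
    """Exact leave-one-trial-out accuracy via O(d^2) downdates.

    For each held-out trial the class mean and pooled scatter are downdated
    (rank-1) rather than refit; predictions are identical to refitting from
    scratch, which tests assert.
    """
    labels = _class_order(y)
    k = len(labels)
    n, d = X.shape
    codes = np.array([labels.index(lab) for lab in y])
    counts = np.bincount(codes, minlength=k).astype(float)
    if (counts < 2).any():
        bad = labels[int(np.argmin(counts))]
        raise ValueError(f"class {bad!r} has fewer than 2 trials")

    sums = np.zeros((k, d))
    np.add.at(sums, codes, X)
    means = sums / counts[:, None]
    scatter = np.zeros((d, d))
    for i in range(k):
        centered = X[codes == i] - means[i]
        scatter += centered.T @ centered

    correct = 0
    eye = np.eye(d)
    for i in range(n):
        c = codes[i]
        x = X[i]
        n_c = counts[c]
        if n_c - 1 < 1:
            raise ValueError("held-out class would be empty")
        mu_c = (sums[c] - x) / (n_c - 1)
        diff = x - means[c]
        scat_i = scatter - (n_c / (n_c - 1)) * np.outer(diff, diff)

        means_i = means.copy()
        means_i[c] = mu_c
        counts_i = counts.copy()
        counts_i[c] -= 1
        dof = (n - 1) - k
        cov = scat_i / max(dof, 1)
        mean_diag = float(np.trace(cov)) / d
        ridge = lam * mean_diag if mean_diag > 0 else lam
        w = np.linalg.solve(cov + ridge * eye, means_i.T)
        bias = np.log(counts_i / (n - 1)) - 0.5 * np.einsum(
            "kd,dk->k", means_i, w)
        pred = int(np.argmax(x @ w + bias))
        correct += pred == c
    return correct / n


def scheme_trials(meta: pd.DataFrame, scheme: DecodingScheme
                  ) -> tuple[np.ndarray, np.ndarray]:
    """(train_rows, test_rows) row indices for a scheme; average trials are
    never eligible."""
    eligible = (meta["emotion"] != AVERAGE).to_numpy()
    morphs = meta["morph"].to_numpy()
    if scheme.train_morphs is None:
        train = eligible
    else:
        train = eligible & np.isin(morphs, scheme.train_morphs)
    if scheme.test_morphs is None:
        test = eligible
    else:
        test = eligible & np.isin(morphs, scheme.test_morphs)
    return np.flatnonzero(train), np.flatnonzero(test)


def decode_timepoint(eeg: EpochedEEG, timepoint_index: int,
                     scheme: DecodingScheme | str,
                     shrinkage: float = DEFAULT_SHRINKAGE) -> float:
    """Decoding accuracy at a single timepoint (one 10 ms bin).

    ``all_all`` runs n leave-one-trial-out folds and averages the 0/1 fold
    outcomes; the cross-morph schemes train once on the train set and score
    every test trial.
    """
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    train_rows, test_rows = scheme_trials(eeg.trial_meta, scheme)
    if len(test_rows) == 0:
        raise ValueError(f"scheme {scheme.name!r} has no eligible test trials")
    y = eeg.trial_meta["emotion"].to_numpy()

    if scheme.cv == "leave_one_trial_out":
        X = eeg.data[train_rows, :, timepoint_index]
        return _loto_accuracy(X, y[train_rows], shrinkage)

    X_train = eeg.data[train_rows, :, timepoint_index]
    X_test = eeg.data[test_rows, :, timepoint_index]
    model = train_lda(X_train, y[train_rows], shrinkage)
    pred = predict_lda(model, X_test)
    return float(np.mean(pred == y[test_rows]))


def time_resolved_decode(eeg: EpochedEEG, scheme: DecodingScheme | str,
                         shrinkage: float = DEFAULT_SHRINKAGE,
                         include_baseline: bool = False
                         ) -> AccuracyTimecourse:
    """Apply :func:`decode_timepoint` to every post-onset timepoint
    (optionally also the baseline interval, for diagnostics).  Returns the
    unsmoothed accuracy timecourse."""
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    mask = np.ones_like(eeg.times, dtype=bool) if include_baseline \
        else eeg.times >= 0
    idx = np.flatnonzero(mask)
    _, test_rows = scheme_trials(eeg.trial_meta, scheme)
    acc = np.array([decode_timepoint(eeg, i, scheme, shrinkage) for i in idx])
    return AccuracyTimecourse(
        subject_id=eeg.subject_id,
        group=eeg.group,
        scheme=scheme.name,
        times=eeg.times[idx].copy(),
        accuracy=acc,
        n_test_trials=np.full(len(idx), len(test_rows)),
        smoothed=False,
    )


def smooth_timecourse(tc: AccuracyTimecourse,
                      window: int = 5) -> AccuracyTimecourse:
    """Centered rolling mean over ``window`` timepoints, truncated at the
    epoch edges (an edge value averages only the samples that exist)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    half = window // 2
    n = len(tc.accuracy)
    smoothed = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        smoothed[i] = tc.accuracy[lo:hi].mean()
    return AccuracyTimecourse(
        subject_id=tc.subject_id, group=tc.group, scheme=tc.scheme,
        times=tc.times.copy(), accuracy=smoothed,
        n_test_trials=tc.n_test_trials.copy(), smoothed=True,
    )
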