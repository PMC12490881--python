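"""Downstream gesture classification and the evaluation battery.

The decoder's 16-dimensional joint-angle output feeds an extremely
randomized trees (extra-trees) classifier over the 14-gesture vocabulary.
Evaluation covers: per-joint errors normalized by anatomical range of
motion, confusion matrices / accuracy / per-gesture F1, Pearson
correlation of per-subject accuracy vectors between settings, paired
t-tests on setting accuracies, inter-onset-interval (IOI) timing
statistics against the ideal 8 s gesture cycle, and the classical sEMG
signal features (zero crossings, slope sign changes, spectral central
frequency).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion

from .session_io import DEFAULT_JOINT_RANGES_DEG, JOINT_NAMES, N_JOINTS

__all__ = [
    "AnatomicalRanges",
    "GestureClassifier",
    "ClassificationReport",
    "IoiResult",
    "SignalFeatures",
    "PairedTTestResult",
    "EvaluationReport",
    "fit_classifier",
    "normalized_joint_error",
    "mean_absolute_error_deg",
    "classification_report",
    "majority_vote_by_event",
    "setting_correlation",
    "paired_t_test",
    "ioi_analysis",
    "signal_features",
]


@dataclass(frozen=True)
class AnatomicalRanges:
    """Per-joint normal range of motion in degrees, for error normalization.

    Shipped defaults are round goniometry figures; they are configuration,
    and analyses that depend on them should inject explicit values.
    """

    ranges: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_JOINT_RANGES_DEG)
    )

    def __post_init__(self) -> None:
        missing = [j for j in JOINT_NAMES if j not in self.ranges]
        if missing:
            raise ValueError(f"ranges missing joints: {missing}")
        if any(self.ranges[j] <= 0 for j in JOINT_NAMES):
            raise ValueError("all ranges must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.ranges[j] for j in JOINT_NAMES])


@dataclass
class GestureClassifier:
    """Trained extra-trees ensemble over decoder joint-angle outputs."""

    estimator: ExtraTreesClassifier
    classes: list[str]
    n_trees: int
    seed: int

    def predict(self, vectors: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(vectors))


def fit_classifier(
    vectors: np.ndarray,
    labels: np.ndarray,
    n_trees: int = 100,
    seed: int = 0,
) -> GestureClassifier:
    """Fit extremely randomized trees on ``[n x 16]`` joint-angle vectors.

    Single-class input is allowed (the classifier degenerates to a
    constant predictor) but flagged with a warning.
    """
    vectors = np.asarray(vectors, dtype=float)
    labels = np.asarray(labels)
    if vectors.ndim != 2 or vectors.shape[1] != N_JOINTS:
        raise ValueError(f"vectors must be [n x {N_JOINTS}], got {vectors.shape}")
    if len(vectors) != len(labels):
        raise ValueError("vectors and labels length mismatch")
    classes = sorted(set(labels.tolist()))
    if len(classes) == 1:
        warnings.warn(
            f"training labels contain a single class {classes[0]!r}; "
            "the classifier will always predict it",
            RuntimeWarning,
            stacklevel=2,
        )
    est = ExtraTreesClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    est.fit(vectors, labels)
    return GestureClassifier(estimator=est, classes=classes, n_trees=n_trees, seed=seed)


def normalized_joint_error(
    pred: np.ndarray, truth: np.ndarray, ranges: AnatomicalRanges = AnatomicalRanges()
) -> np.ndarray:
    """Per-sample, per-joint ``|pred - truth| / range`` (dimensionless)."""
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if pred.shape != truth.shape or pred.shape[-1] != N_JOINTS:
        raise ValueError(f"pred/truth must share shape [n x {N_JOINTS}]")
    return np.abs(pred - truth) / ranges.as_array()


def mean_absolute_error_deg(pred: np.ndarray, truth: np.ndarray) -> float:
    """Plain mean absolute error in degrees over all samples and joints."""
    return float(np.abs(np.asarray(pred) - np.asarray(truth)).mean())


@dataclass
class ClassificationReport:
    """Confusion matrix (rows = truth), accuracy, and one-vs-rest F1."""

    vocabulary: list[str]
    confusion: np.ndarray
    accuracy: float
    f1_per_class: dict[str, float]

    @property
    def macro_f1(self) -> float:
        return float(np.mean(list(self.f1_per_class.values())))


def classification_report(
    predictions: np.ndarray, truths: np.ndarray, vocabulary: list[str]
) -> ClassificationReport:
    """Confusion matrix, accuracy = trace/total, and per-gesture F1."""
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    vocab = list(vocabulary)
    outside = set(predictions.tolist()) | set(truths.tolist())
    outside -= set(vocab)
    if outside:
        raise ValueError(f"labels outside the vocabulary: {sorted(outside)}")
    cm = _sk_confusion(truths, predictions, labels=vocab)
    total = cm.sum()
    accuracy = float(np.trace(cm) / total) if total else float("nan")
    f1: dict[str, float] = {}
    for i, g in enumerate(vocab):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        denom = 2 * tp + fp + fn
        f1[g] = float(2 * tp / denom) if denom else 0.0
    return ClassificationReport(
        vocabulary=vocab, confusion=cm, accuracy=accuracy, f1_per_class=f1
    )


def majority_vote_by_event(
    window_predictions: np.ndarray, event_index: np.ndarray
) -> dict[int, str]:
    """Aggregate window-level labels to one label per gesture event.

    Ties break toward the lexicographically smallest label (deterministic).
    Windows with ``event_index < 0`` (rest) are ignored.
    """
    out: dict[int, str] = {}
    window_predictions = np.asarray(window_predictions)
    event_index = np.asarray(event_index)
    for ev in np.unique(event_index):
        if ev < 0:
            continue
        votes = window_predictions[event_index == ev]
        labels, counts = np.unique(votes, return_counts=True)
        out[int(ev)] = str(labels[np.argmax(counts)])
    return out


def setting_correlation(per_subject_accuracy: np.ndarray) -> np.ndarray:
    """Pearson correlation between settings' per-subject accuracy vectors.

    Input is ``[subjects x settings]``; output is the symmetric
    ``[settings x settings]`` correlation matrix with unit diagonal.
    """
    acc = np.asarray(per_subject_accuracy, dtype=float)
    if acc.ndim != 2:
        raise ValueError("expected a [subjects x settings] matrix")
    if acc.shape[0] < 3:
        raise ValueError(
            f"need at least 3 subjects for a meaningful correlation, got {acc.shape[0]}"
        )
    r = np.clip(np.corrcoef(acc, rowvar=False), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    # exact duplicates correlate exactly, unpolluted by rounding
    for i in range(acc.shape[1]):
        for j in range(i + 1, acc.shape[1]):
            if np.array_equal(acc[:, i], acc[:, j]):
                r[i, j] = r[j, i] = 1.0
    return r


@dataclass(frozen=True)
class PairedTTestResult:
    t: float
    p: float
    degenerate: bool = False


def paired_t_test(acc_a: np.ndarray, acc_b: np.ndarray) -> PairedTTestResult:
    """Two-sided paired t-test on per-subject accuracy differences.

    Zero-variance differences are degenerate for the t statistic; the
    result is flagged rather than raising or returning an unguarded
    infinity (t = 0, p = 1 when the vectors are identical).
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return PairedTTestResult(t=0.0, p=1.0, degenerate=True)
        return PairedTTestResult(
            t=float(np.sign(d.mean()) * np.inf), p=0.0, degenerate=True
        )
    t, p = stats.ttest_rel(a, b)
    return PairedTTestResult(t=float(t), p=float(p))


@dataclass
class IoiResult:
    """Inter-onset-interval timing statistics for one session."""

    iois: np.ndarray
    ideal_cycle: float
    mean_abs_deviation: float
    cdf_x: np.ndarray
    cdf_y: np.ndarray


def ioi_analysis(onsets: np.ndarray, ideal_cycle: float = 8.0) -> IoiResult:
    """Inter-onset intervals vs the ideal cycle (5 s hold + 3 s pause).

    Returns the empirical CDF of the IOIs and the mean absolute deviation
    from ``ideal_cycle`` seconds.
    """
    onsets = np.sort(np.asarray(onsets, dtype=float))
    if onsets.size < 2:
        raise ValueError("need at least 2 onsets for inter-onset intervals")
    iois = np.diff(onsets)
    x = np.sort(iois)
    y = np.arange(1, x.size + 1) / x.size
    return IoiResult(
        iois=iois,
        ideal_cycle=ideal_cycle,
        mean_abs_deviation=float(np.abs(iois - ideal_cycle).mean()),
        cdf_x=x,
        cdf_y=y,
    )


@dataclass(frozen=True)
class SignalFeatures:
    zero_crossings: int
    slope_sign_changes: int
    central_frequency: float


def _sign_changes(x: np.ndarray, dead_band: float) -> int:
    """Count strict sign changes between consecutive above-dead-band samples."""
    s = np.where(x > dead_band, 1, np.where(x < -dead_band, -1, 0))
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.sum(s[:-1] != s[1:]))


def signal_features(
    segment: np.ndarray,
    fs: float,
    dead_band: float = 0.01,
    band: tuple[float, float] = (20.0, 450.0),
) -> SignalFeatures:
    """Classical sEMG features of one single-channel segment.

    Zero crossings: sign changes of the signal; slope sign changes: sign
    changes of its first difference — both with an amplitude dead band
    (default 0.01 on z-scored signals) to suppress counting of numerical
    noise.  Central frequency: power-spectral centroid of a Hann-tapered
    periodogram restricted to ``band``.
    """
    x = np.asarray(segment, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("segment must contain at least 2 samples")
    zc = _sign_changes(x, dead_band)
    ssc = _sign_changes(np.diff(x), dead_band)
    freqs, pxx = sps.periodogram(x, fs=fs, window="hann")
    lo, hi = band
    hi = min(hi, fs / 2)
    sel = (freqs >= lo) & (freqs <= hi)
    if not np.any(sel) or pxx[sel].sum() == 0:
        centroid = float("nan")
    else:
        centroid = float(np.sum(freqs[sel] * pxx[sel]) / np.sum(pxx[sel]))
    return SignalFeatures(zero_crossings=zc, slope_sign_changes=ssc, central_frequency=centroid)


def central_frequency_variance(
    windows: np.ndarray, fs: float, band: tuple[float, float] = (20.0, 450.0)
) -> float:
    """Variance of the spectral centroid across a recording's windows."""
    cents = [
        signal_features(w, fs, band=band).central_frequency for w in np.atleast_2d(windows)
    ]
    return float(np.var(cents))


@dataclass
class EvaluationReport:
    """Bundle of all evaluation outputs for one decoding run."""

    normalized_errors: np.ndarray  # [n x 16]
    mae_deg: float
    classification: ClassificationReport
    event_classification: ClassificationReport | None = None
    ioi: IoiResult | None = None
    features: list[SignalFeatures] | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "mae_deg": self.mae_deg,
            "normalized_error_mean_per_joint": dict(
                zip(JOINT_NAMES, self.normalized_errors.mean(axis=0).tolist())
            ),
            "window_accuracy": self.classification.accuracy,
            "window_f1": self.classification.f1_per_class,
            "confusion": self.classification.confusion.tolist(),
            "vocabulary": self.classification.vocabulary,
        }
        if self.event_classification is not None:
            d["event_accuracy"] = self.event_classification.accuracy
            d["event_confusion"] = self.event_classification.confusion.tolist()
        if self.ioi is not None:
            d["ioi_mean_abs_deviation_s"] = self.ioi.mean_abs_deviation
        if self.features is not None:
            d["signal_features"] = [
                {
                    "zero_crossings": f.zero_crossings,
                    "slope_sign_changes": f.slope_sign_changes,
                    "central_frequency_hz": f.central_frequency,
                }
                for f in self.features
            ]
        d.update(self.extras)
        return d
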