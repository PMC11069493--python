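"""Motor-imagery classification from electrode- or source-space epochs.

Pipeline: channel subset -> common average reference (CAR, computed within
the subset so the discarded channels cannot leak into the reference) ->
zero-phase FIR band-pass in the mu band (8-12 Hz) -> common spatial patterns
(CSP) log-variance features -> RF / SVM / LDA, evaluated with repeated
stratified 70/30 splits.  CSP and the feature scaler are fit on the training
split only.

CSP solves the generalized eigenproblem of the two class-mean covariance
matrices; the extreme eigenvectors maximize the variance ratio between
classes, and the selected filters W jointly whiten the composite covariance,
W (C_A + C_B) W^T = I.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .headmodel import LeadField
from .inverse import make_sloreta
from .simulate import EpochSet

__all__ = [
    "PreprocConfig",
    "FeatureSpec",
    "CvReport",
    "FoldResult",
    "Metrics",
    "preprocess",
    "source_features",
    "CspFilters",
    "csp_fit",
    "cross_validate",
    "metrics_from_confusion",
]


@dataclass(frozen=True)
class PreprocConfig:
    notch_freqs: tuple[float, ...] = (50.0, 100.0)
    highpass: float | None = 0.1
    bandpass: tuple[float, float] = (8.0, 12.0)
    epoch_window: tuple[float, float] = (-1.0, 3.0)
    reference: str = "CAR"
    transition_bandwidth: float = 2.0  # Hz, FIR design target

    def __post_init__(self):
        if self.bandpass[0] >= self.bandpass[1]:
            raise ValueError("bandpass low cutoff must be below high cutoff")
        if self.epoch_window[0] >= self.epoch_window[1]:
            raise ValueError("epoch window start must precede end")


@dataclass(frozen=True)
class FeatureSpec:
    space: str = "electrode"  # 'electrode' | 'source'
    n_csp_components: int = 6
    roi_indices: np.ndarray | None = None
    lambda2: float = 0.0

    def __post_init__(self):
        if self.space not in ("electrode", "source"):
            raise ValueError("space must be 'electrode' or 'source'")
        if self.n_csp_components % 2:
            raise ValueError("n_csp_components must be even")


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    undefined: tuple[str, ...] = ()

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.accuracy, self.precision, self.recall, self.f1)


@dataclass(frozen=True)
class FoldResult:
    confusion: tuple[int, int, int, int]  # TN, FP, FN, TP
    metrics: Metrics


@dataclass(frozen=True)
class CvReport:
    folds: tuple[FoldResult, ...]
    classifier: str
    space: str

    def _stack(self) -> np.ndarray:
        return np.array([f.metrics.as_tuple() for f in self.folds])

    @property
    def mean(self) -> Metrics:
        return Metrics(*self._stack().mean(axis=0))

    @property
    def std(self) -> Metrics:
        return Metrics(*self._stack().std(axis=0, ddof=1))

    def to_dict(self) -> dict:
        names = ("accuracy", "precision", "recall", "f1")
        return {
            "classifier": self.classifier,
            "space": self.space,
            "n_folds": len(self.folds),
            "mean": dict(zip(names, np.round(self._stack().mean(axis=0), 6))),
            "std": dict(zip(names, np.round(self._stack().std(axis=0, ddof=1), 6))),
            "confusions": [list(f.confusion) for f in self.folds],
        }


def _fir_bandpass(low, high, sfreq, transition):
    numtaps = int(np.ceil(3.3 * sfreq / transition))
    numtaps += 1 - numtaps % 2  # odd for a type-I linear-phase filter
    return signal.firwin(numtaps, [low, high], pass_zero=False, fs=sfreq, window="hamming")


def _filtfilt(taps, data):
    padlen = min(3 * len(taps), data.shape[-1] - 1)
    return signal.filtfilt(taps, [1.0], data, axis=-1, padlen=padlen)


def preprocess(epochs: EpochSet, cfg: PreprocConfig = PreprocConfig(), mask=None) -> EpochSet:
    """Channel subset -> notch -> high-pass -> CAR -> mu band-pass.

    The subset is taken before the CAR so the reference is computed from the
    retained channels only.  Notch filters above the Nyquist frequency are
    skipped (the synthetic data is band-limited anyway); the high-pass is
    skipped when the epochs are too short to support its FIR length.
    """
    data = epochs.data
    if mask is not None:
        bits = np.asarray(getattr(mask, "bits", mask))
        idx = np.flatnonzero(bits) if bits.dtype == bool else np.asarray(bits, int)
        if idx.size < 2:
            raise ValueError("CAR requires at least two channels")
        data = data[:, idx, :]
    sfreq, nyq = epochs.sfreq, epochs.sfreq / 2.0
    if cfg.bandpass[1] >= nyq:
        raise ValueError("bandpass upper cutoff must be below Nyquist")

    for f0 in cfg.notch_freqs:
        if f0 >= nyq:
            continue
        w = min(2.0, 0.5 * (nyq - f0))
        taps = signal.firwin(
            int(np.ceil(3.3 * sfreq / w)) | 1,
            [f0 - w / 2, f0 + w / 2],
            fs=sfreq,
            window="hamming",
        )  # band-stop (pass_zero default True)
        data = _filtfilt(taps, data)
    if cfg.highpass is not None:
        hp_taps_needed = int(np.ceil(3.3 * sfreq / (2 * cfg.highpass))) | 1
        if hp_taps_needed < data.shape[-1]:
            taps = signal.firwin(hp_taps_needed, cfg.highpass, pass_zero=False, fs=sfreq)
            data = _filtfilt(taps, data)
    if cfg.reference == "CAR":
        data = data - data.mean(axis=1, keepdims=True)
    taps = _fir_bandpass(*cfg.bandpass, sfreq, cfg.transition_bandwidth)
    data = _filtfilt(taps, data)
    return EpochSet(data, sfreq, epochs.truth.copy(), epochs.snr_db, dict(epochs.meta))


def source_features(
    epochs: EpochSet, lf: LeadField, roi_indices, lambda2: float = 0.0, mask=None
) -> EpochSet:
    """Epochs mapped to the source space, restricted to the ROI time courses.

    sLORETA reconstructs all sources from the (optionally masked) channels and
    the rows of the hand-knob ROI are extracted, giving trials x n_roi x
    samples.  The transform is linear and label-free, so it cannot leak class
    information across cross-validation splits.
    """
    roi_indices = np.asarray(roi_indices, int)
    if roi_indices.size and (roi_indices.min() < 0 or roi_indices.max() >= lf.n_sources):
        raise IndexError("ROI index out of range for the lead field")
    op = make_sloreta(lf, lambda2, mask)
    kernel = op.kernel[roi_indices]  # restrict before applying: cheaper
    sub = op.channel_subset
    data = epochs.data if epochs.n_channels == len(sub) else epochs.data[:, sub, :]
    out = np.einsum("rc,tcs->trs", kernel, data)
    meta = dict(epochs.meta, space="source", n_roi=int(roi_indices.size))
    return EpochSet(out, epochs.sfreq, epochs.truth.copy(), epochs.snr_db, meta)


@dataclass(frozen=True)
class CspFilters:
    filters: np.ndarray  # (n_components, n_channels)
    eigenvalues: np.ndarray  # class-A variance ratio of every solution, ascending

    def transform(self, data: np.ndarray) -> np.ndarray:
        """Log-variance features, trials x n_components."""
        projected = np.einsum("kc,tcs->tks", self.filters, data)
        return np.log(np.einsum("tks,tks->tk", projected, projected) / data.shape[-1])


def _class_covariances(data: np.ndarray, labels: np.ndarray):
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("CSP requires exactly two classes")
    if any(np.sum(labels == c) < 2 for c in classes):
        raise ValueError("CSP requires at least two trials per class")
    covs = []
    for c in classes:
        trials = data[labels == c]
        per_trial = np.matmul(trials, trials.transpose(0, 2, 1))
        traces = np.trace(per_trial, axis1=1, axis2=2)
        covs.append(np.mean(per_trial / traces[:, None, None], axis=0))
    return covs[0], covs[1]


def csp_fit(data, labels, n_components: int = 6) -> CspFilters:
    """Common spatial patterns from the two class-mean covariances.

    Solves C_A v = lambda (C_A + C_B) v and keeps n_components/2 eigenvectors
    from each spectral extreme.  A rank-deficient composite covariance is
    ridge-regularized (1e-10 of the mean eigenvalue scale) with a warning.
    """
    data = np.asarray(getattr(data, "data", data), float)
    labels = np.asarray(labels)
    if n_components > data.shape[1]:
        raise ValueError("n_components exceeds the channel dimension")
    ca, cb = _class_covariances(data, labels)
    comp = ca + cb
    scale = np.trace(comp) / comp.shape[0]
    if np.linalg.matrix_rank(comp, tol=1e-10 * scale * comp.shape[0]) < comp.shape[0]:
        warnings.warn("rank-deficient covariance; applying trace-scaled ridge")
        comp = comp + 1e-8 * scale * np.eye(comp.shape[0])
        ca = ca + 0.5e-8 * scale * np.eye(comp.shape[0])
    evals, evecs = linalg.eigh(ca, comp)  # ascending; evecs are B-orthonormal
    half = n_components // 2
    sel = np.r_[0:half, evals.size - half : evals.size]
    return CspFilters(evecs[:, sel].T, evals)


def metrics_from_confusion(tn: int, fp: int, fn: int, tp: int) -> Metrics:
    """Accuracy, precision, recall and F1 from one binary confusion matrix.

    Undefined quotients (0/0) are reported as 0 and flagged in ``undefined``.
    """
    for v in (tn, fp, fn, tp):
        if v < 0 or v != int(v):
            raise ValueError("confusion counts must be non-negative integers")
    total = tn + fp + fn + tp
    if total == 0:
        raise ValueError("confusion matrix must contain at least one sample")
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = (tn + tp) / total
    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    f1 = ratio(2 * tp, 2 * tp + fp + fn, "f1")
    return Metrics(accuracy, precision, recall, f1, tuple(undefined))


def _make_classifier(tag: str, seed: int):
    tag = tag.lower()
    if tag == "rf":
        return RandomForestClassifier(random_state=seed)
    if tag == "svm":
        return SVC(kernel="rbf", random_state=seed)
    if tag == "lda":
        return LinearDiscriminantAnalysis()
    raise ValueError(f"unknown classifier tag {tag!r}")


def cross_validate(
    epochs: EpochSet,
    labels=None,
    feature_spec: FeatureSpec = FeatureSpec(),
    classifier: str = "lda",
    n_repeats: int = 10,
    test_frac: float = 0.3,
    seed: int = 0,
    lf: LeadField | None = None,
    mask=None,
    preproc: PreprocConfig | None = None,
) -> CvReport:
    """Repeated stratified 70/30 evaluation of CSP features.

    Per repeat: stratified shuffle split, CSP fit on the training trials only,
    per-feature standardization fit on the training features only, classifier
    training, and a confusion matrix on the held-out trials.  The class with
    the higher label is treated as "positive".  Deterministic for fixed seed.
    """
    labels = np.asarray(epochs.truth if labels is None else labels)
    if preproc is not None:
        # the mask is applied here; it is kept for the source transform so the
        # imaging kernel is built on the same channel subset
        epochs = preprocess(epochs, preproc, mask)
    if feature_spec.space == "source":
        if lf is None or feature_spec.roi_indices is None:
            raise ValueError("source space requires a lead field and ROI indices")
        epochs = source_features(
            epochs, lf, feature_spec.roi_indices, feature_spec.lambda2, mask
        )
    data = epochs.data
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("binary classification requires exactly two classes")

    splitter = StratifiedShuffleSplit(
        n_splits=n_repeats, test_size=test_frac, random_state=seed
    )
    folds = []
    for k, (train, test) in enumerate(splitter.split(data, labels)):
        csp = csp_fit(data[train], labels[train], feature_spec.n_csp_components)
        scaler = StandardScaler().fit(csp.transform(data[train]))
        x_train = scaler.transform(csp.transform(data[train]))
        x_test = scaler.transform(csp.transform(data[test]))
        clf = _make_classifier(classifier, seed + k)
        clf.fit(x_train, labels[train])
        pred = clf.predict(x_test)
        true = labels[test]
        pos, neg = classes[1], classes[0]
        tp = int(np.sum((true == pos) & (pred == pos)))
        tn = int(np.sum((true == neg) & (pred == neg)))
        fp = int(np.sum((true == neg) & (pred == pos)))
        fn = int(np.sum((true == pos) & (pred == neg)))
        folds.append(FoldResult((tn, fp, fn, tp), metrics_from_confusion(tn, fp, fn, tp)))
    return CvReport(tuple(folds), classifier.lower(), feature_spec.space)
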