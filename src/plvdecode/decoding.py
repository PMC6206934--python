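"""SVM decoding: static LOOCV, time-indexed banks, lagged ensembles and the
self-paced switch.

Direction decoding ("left" vs "right") uses maximum-margin linear SVMs over
selected-coupling PLV features, with a sigmoid-calibrated signed confidence
in [-1, 1] (+ right / - left).  In the static scenario feature selection is
re-run inside every leave-one-out fold; in the time-indexed scenario one
"instantaneous" SVM is trained per stepping-window latency on a fixed
(bootstrap-selected) feature set.  Latencies where the accuracy curve peaks
— separated by at least one window width and defining genuinely different
hyperplanes — populate an ensemble whose members are read out at their own
lags and averaged into a streaming classification index

    z_ensemble(t) = (1/M) sum_i z^i(t + tau_sel_i).

A radial-basis-kernel SVM (the "switch") then labels 0.5-s segments of that
index trace as MI event vs baseline, which makes trigger-free (self-paced)
detection possible; performance is summarized as Monte-Carlo false-positive
and false-negative rates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .screening import bootstrap_select, select_static_features

#: label convention for the direction decoders
LABEL_SIGNS = {"left": -1, "right": +1}


def _as_signed(y) -> np.ndarray:
    out = []
    for v in y:
        if isinstance(v, str):
            out.append(LABEL_SIGNS[v])
        else:
            out.append(int(np.sign(v)))
    y = np.asarray(out)
    if np.any(y == 0):
        raise ValueError("labels must be nonzero (+1 right / -1 left)")
    return y


class ConfidenceClassifier:
    """A maximum-margin classifier with a signed-confidence readout.

    The margin distance is mapped through a sigmoid fitted on the training
    decision values (Platt-style), giving P(class=+1); the reported
    confidence is 2*P(+1) - 1, a real number in [-1, 1] whose sign is the
    predicted class and whose magnitude reflects certainty.  Features are
    standardized with training statistics; C is fixed at 1 (no tuning).
    """

    def __init__(self, C: float = 1.0, kernel: str = "linear",
                 gamma: str | float = "scale"):
        self.C = C
        self.kernel = kernel
        self.gamma = gamma
        self._scaler: StandardScaler | None = None
        self._svc: SVC | None = None
        self._platt: LogisticRegression | None = None

    def fit(self, X: np.ndarray, y) -> "ConfidenceClassifier":
        X = np.asarray(X, dtype=float)
        y = _as_signed(y)
        if np.unique(y).size < 2:
            raise ValueError("training data contains a single class")
        self._scaler = StandardScaler().fit(X)
        Xs = self._scaler.transform(X)
        self._svc = SVC(C=self.C, kernel=self.kernel, gamma=self.gamma).fit(Xs, y)
        d = self._svc.decision_function(Xs).reshape(-1, 1)
        # moderate regularization keeps the sigmoid graded on separable
        # training sets, so confidence magnitude stays informative
        self._platt = LogisticRegression(C=1.0, max_iter=2000).fit(d, y)
        return self

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self._svc.decision_function(self._scaler.transform(np.asarray(X, float)))

    def proba(self, X: np.ndarray) -> np.ndarray:
        """P(class = +1)."""
        d = self.decision(X).reshape(-1, 1)
        pos = list(self._platt.classes_).index(1)
        return self._platt.predict_proba(d)[:, pos]

    def confidence(self, X: np.ndarray) -> np.ndarray:
        """Signed confidence 2*P(+1) - 1 in [-1, 1]."""
        return 2.0 * self.proba(X) - 1.0

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._svc.predict(self._scaler.transform(np.asarray(X, float)))

    @property
    def normal_(self) -> np.ndarray:
        """Hyperplane normal in standardized feature space (linear kernel)."""
        if self.kernel != "linear":
            raise AttributeError("hyperplane normal requires a linear kernel")
        return self._svc.coef_.ravel()


def fit_confidence_classifier(X: np.ndarray, y, C: float = 1.0) -> ConfidenceClassifier:
    """Fit the linear direction decoder on selected-coupling patterns."""
    return ConfidenceClassifier(C=C).fit(X, y)


@dataclass
class StaticDecodingResult:
    accuracy: float
    n_folds: int
    predictions: np.ndarray
    truth: np.ndarray
    train_sizes: list[int]
    fold_features: list[np.ndarray]


def loocv_static_accuracy(left: np.ndarray, right: np.ndarray,
                          k: int = 10) -> StaticDecodingResult:
    """Leave-one-out accuracy of the static decoder, selection inside folds.

    Each of the 2*N trials is held out once; the top-k coupling selection is
    re-run on the remaining trials only (no leakage), a linear SVM is fitted
    on them and the held-out trial is predicted.
    """
    left = np.asarray(left, float)
    right = np.asarray(right, float)
    X = np.vstack([left, right])
    y = np.concatenate([-np.ones(len(left)), np.ones(len(right))]).astype(int)
    n = len(y)
    if n < 4:
        raise ValueError("LOOCV needs at least 4 trials")
    preds = np.empty(n, dtype=int)
    train_sizes, fold_features = [], []
    for i in range(n):
        train = np.delete(np.arange(n), i)
        feats = select_static_features(X[train][y[train] == -1],
                                       X[train][y[train] == 1], k=k)
        clf = ConfidenceClassifier().fit(X[train][:, feats], y[train])
        preds[i] = clf.predict(X[i:i + 1, feats])[0]
        train_sizes.append(train.size)
        fold_features.append(feats)
    return StaticDecodingResult(accuracy=float(np.mean(preds == y)), n_folds=n,
                                predictions=preds, truth=y,
                                train_sizes=train_sizes,
                                fold_features=fold_features)


@dataclass
class TimeResolvedResult:
    accuracy: np.ndarray
    bank: list[ConfidenceClassifier]
    selected: np.ndarray


def time_resolved_svms(left_seqs: np.ndarray, right_seqs: np.ndarray,
                       selected: np.ndarray) -> TimeResolvedResult:
    """One "instantaneous" SVM per latency on the fixed feature set.

    Per latency tau: LOOCV accuracy on vec(W[tau]) restricted to the
    selected couplings (selection happened outside this loop), plus a final
    classifier trained on all trials for ensemble use.
    """
    selected = np.asarray(selected, dtype=int)
    if selected.size == 0:
        raise ValueError("empty feature set")
    L = np.asarray(left_seqs, float)[:, selected, :]
    R = np.asarray(right_seqs, float)[:, selected, :]
    n_tau = L.shape[2]
    X_all = np.concatenate([L, R], axis=0)
    y = np.concatenate([-np.ones(L.shape[0]), np.ones(R.shape[0])]).astype(int)
    n = len(y)
    acc = np.empty(n_tau)
    bank = []
    for tau in range(n_tau):
        X = X_all[:, :, tau]
        preds = np.empty(n, dtype=int)
        for i in range(n):
            train = np.delete(np.arange(n), i)
            clf = ConfidenceClassifier().fit(X[train], y[train])
            preds[i] = clf.predict(X[i:i + 1])[0]
        acc[tau] = np.mean(preds == y)
        bank.append(ConfidenceClassifier().fit(X, y))
    return TimeResolvedResult(accuracy=acc, bank=bank, selected=selected)


@dataclass
class EnsembleModel:
    """A bank of latency-specific linear SVMs sharing one feature set.

    lags are strictly increasing stepping-window indices tau_sel_i; members
    are pairwise non-colliding (lag separation >= one window width) and
    define distinct hyperplanes.
    """

    members: list[ConfidenceClassifier]
    lags: np.ndarray
    selected: np.ndarray
    step: float

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=int)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("ensemble lags must be strictly increasing")

    @property
    def n_members(self) -> int:
        return len(self.members)


def build_ensemble(accuracy: np.ndarray, bank: list[ConfidenceClassifier],
                   selected: np.ndarray, step: float,
                   min_separation: int, min_accuracy_frac: float = 0.9,
                   similarity_max: float = 0.95,
                   max_lag: int | None = None) -> EnsembleModel:
    """Pick consecutive but non-colliding high-accuracy latencies as members.

    Every latency within ``min_accuracy_frac`` of the curve maximum is a
    candidate (a noisy curve contributes its local peaks, a saturated one
    its whole plateau); candidates are kept greedily in accuracy order
    (earlier latency on ties) subject to a pairwise lag separation of at
    least ``min_separation`` steps and to a hyperplane-normal cosine
    similarity below ``similarity_max`` (duplicated decision boundaries are
    dropped).  The global argmax always qualifies, so a monotone curve
    still yields one member.
    """
    accuracy = np.asarray(accuracy, float)
    floor = min_accuracy_frac * accuracy.max()
    peaks = set(int(p) for p in np.flatnonzero(accuracy >= floor))
    peaks.add(int(np.argmax(accuracy)))
    if max_lag is not None:
        peaks = {p for p in peaks if p <= max_lag} or {min(peaks)}
    candidates = sorted(peaks, key=lambda p: (-accuracy[p], p))
    if not candidates:
        raise ValueError("no qualifying accuracy peak for the ensemble")

    kept: list[int] = []
    for p in candidates:
        if accuracy[p] < floor:
            continue
        if any(abs(p - q) < min_separation for q in kept):
            continue
        normal = bank[p].normal_
        dup = False
        for q in kept:
            other = bank[q].normal_
            cos = abs(normal @ other) / (np.linalg.norm(normal)
                                         * np.linalg.norm(other) + 1e-30)
            if cos >= similarity_max:
                dup = True
                break
        if not dup:
            kept.append(p)
    if not kept:
        raise ValueError("no qualifying accuracy peak for the ensemble")
    kept = sorted(kept)
    return EnsembleModel(members=[bank[p] for p in kept], lags=np.array(kept),
                         selected=np.asarray(selected, int), step=step)


def ensemble_readout(vecs: np.ndarray, ensemble: EnsembleModel,
                     restrict: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Member confidences Z(tau) and the lag-aligned classification index.

    ``vecs`` is one trial's (n_pairs, n_tau) sequence (or already restricted
    to the ensemble's features if ``restrict`` is False).  All members are
    evaluated at every latency (the parallel-bank contract); the index

        z_ensemble(t) = mean_i Z[i, t + lag_i]

    is defined while every member's lag stays inside the stream, so the
    trace has n_tau - max(lag) points; a stream shorter than the largest lag
    yields an empty trace and a warning.
    """
    vecs = np.asarray(vecs, float)
    X = vecs[ensemble.selected].T if restrict else vecs.T
    Z = np.stack([m.confidence(X) for m in ensemble.members])
    n_tau = Z.shape[1]
    horizon = n_tau - int(ensemble.lags.max())
    if horizon <= 0:
        warnings.warn("stream shorter than the largest ensemble lag; "
                      "empty readout", RuntimeWarning, stacklevel=2)
        return Z, np.empty(0)
    z_ens = np.mean([Z[i, lag:lag + horizon]
                     for i, lag in enumerate(ensemble.lags)], axis=0)
    return Z, z_ens


@dataclass
class SwitchModel:
    """RBF-kernel classifier labelling readout segments MI-event vs baseline."""

    classifier: ConfidenceClassifier
    segment_len: int
    step: float
    threshold: float = 0.5


def _extract_segments(trace: np.ndarray, starts: np.ndarray, seg_len: int) -> np.ndarray:
    return np.stack([trace[s:s + seg_len] for s in starts])


def train_switch(mi_traces: list[np.ndarray], rest_traces: list[np.ndarray],
                 step: float, segment_width: float = 0.5,
                 mi_interval: tuple[float, float] = (0.2, 2.0),
                 segments_per_trial: int = 5,
                 rng: np.random.Generator | None = None) -> SwitchModel:
    """Fit the MI-event vs baseline switch on classification-index segments.

    From each MI trace, ``segments_per_trial`` evenly spaced segments of
    ``segment_width`` s are drawn inside ``mi_interval`` (s, re trace start =
    event onset) — 20 training trials x 5 = 100 MI-event segments at the
    study design.  An equal number of baseline segments is drawn at random
    positions anywhere in the rest traces.
    """
    rng = np.random.default_rng(rng)
    seg_len = int(round(segment_width / step))
    if seg_len < 2:
        raise ValueError("segment too short for the trace step")

    mi_segments = []
    for trace in mi_traces:
        lo = int(round(mi_interval[0] / step))
        hi = min(int(round(mi_interval[1] / step)), trace.size - seg_len)
        if hi < lo:
            raise ValueError(
                f"MI interval {mi_interval} s cannot hold a "
                f"{segment_width} s segment in a {trace.size * step:.2f} s trace")
        starts = np.unique(np.linspace(lo, hi, segments_per_trial).round().astype(int))
        mi_segments.append(_extract_segments(trace, starts, seg_len))
    mi_segments = np.concatenate(mi_segments)

    n_baseline = len(mi_segments)
    rest_segments = []
    for _ in range(n_baseline):
        trace = rest_traces[rng.integers(len(rest_traces))]
        s = rng.integers(0, trace.size - seg_len + 1)
        rest_segments.append(trace[s:s + seg_len])
    rest_segments = np.stack(rest_segments)

    X = np.vstack([mi_segments, rest_segments])
    y = np.concatenate([np.ones(len(mi_segments)), -np.ones(n_baseline)]).astype(int)
    clf = ConfidenceClassifier(kernel="rbf").fit(X, y)
    return SwitchModel(classifier=clf, segment_len=seg_len, step=step)


@dataclass(frozen=True)
class Detection:
    time: float
    direction: int
    confidence: float


def stream_decode(trace: np.ndarray, switch: SwitchModel,
                  threshold: float | None = None) -> list[Detection]:
    """Flag MI events in a streaming classification-index trace.

    Consecutive 0.5-s segments are scored by the switch; runs of
    supra-threshold confidence are merged into single detections, each
    stamped with the run-start time and the direction given by the sign of
    the classification index at the flag.
    """
    if threshold is None:
        threshold = switch.threshold
    trace = np.asarray(trace, float)
    n = trace.size - switch.segment_len + 1
    if n <= 0:
        return []
    starts = np.arange(n)
    segments = _extract_segments(trace, starts, switch.segment_len)
    conf = switch.classifier.proba(segments)
    above = conf > threshold
    detections = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            flag = i + switch.segment_len // 2
            direction = int(np.sign(trace[min(flag, trace.size - 1)])) or 1
            detections.append(Detection(time=i * switch.step, direction=direction,
                                        confidence=float(conf[i:j + 1].max())))
            i = j + 1
        else:
            i += 1
    return detections


@dataclass
class SelfPacedResult:
    """Monte-Carlo evaluation of the two-stage self-paced decoder."""

    fp_rate: float
    fn_rate: float
    fp_per_split: list[float]
    fn_per_split: list[float]
    n_splits: int
    details: dict = field(default_factory=dict)


def monte_carlo_selfpaced_eval(left_seqs: np.ndarray, right_seqs: np.ndarray,
                               rest_seqs: np.ndarray, step: float,
                               t_window: float, n_splits: int = 100,
                               n_train: int = 10, n_boot: int = 30,
                               n_rand: int = 100,
                               segment_width: float = 0.5,
                               mi_interval: tuple[float, float] = (0.2, 2.0),
                               threshold: float = 0.5,
                               min_accuracy_frac: float = 0.9,
                               seed: int | np.random.Generator = 0) -> SelfPacedResult:
    """FP/FN rates of the full self-paced pipeline over randomized splits.

    Per split: ``n_train`` trials per class train the two-stage decoder
    (bootstrap feature selection -> time-resolved SVM bank -> lagged
    ensemble -> RBF switch), and detections are counted on the held-out
    trials: a detection in a rest trial is a false positive, an MI trial
    with no detection a false negative; both counts are referenced to the
    total number of test trials.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    left_seqs, right_seqs, rest_seqs = (np.asarray(a, float) for a in
                                        (left_seqs, right_seqs, rest_seqs))
    n_l, n_r, n_rest = (a.shape[0] for a in (left_seqs, right_seqs, rest_seqs))
    if min(n_l, n_r, n_rest) < n_train + 1:
        raise ValueError("each class needs more trials than n_train")
    min_sep = int(np.ceil(t_window / step))
    n_tau = left_seqs.shape[2]
    # keep the largest lag small enough for the switch-training interval
    max_lag = n_tau - int(np.ceil((mi_interval[1] + segment_width) / step)) - 1
    if max_lag < 0:
        max_lag = None

    fp_per_split, fn_per_split = [], []
    for _ in range(n_splits):
        perm_l = rng.permutation(n_l)
        perm_r = rng.permutation(n_r)
        perm_b = rng.permutation(n_rest)
        trL, teL = left_seqs[perm_l[:n_train]], left_seqs[perm_l[n_train:]]
        trR, teR = right_seqs[perm_r[:n_train]], right_seqs[perm_r[n_train:]]
        trB, teB = rest_seqs[perm_b[:n_train]], rest_seqs[perm_b[n_train:]]

        # stage 1: selection, bank, ensemble — MI trials only
        sel = bootstrap_select(trL, trR, step=step, n_boot=n_boot,
                               n_rand=n_rand, rng=rng)
        tr = time_resolved_svms(trL, trR, sel.selected)
        ensemble = build_ensemble(tr.accuracy, tr.bank, sel.selected, step,
                                  min_separation=min_sep,
                                  min_accuracy_frac=min_accuracy_frac,
                                  max_lag=max_lag)

        # stage 2: switch on training readout traces
        mi_traces = [ensemble_readout(v, ensemble)[1] for v in trL] + \
                    [ensemble_readout(v, ensemble)[1] for v in trR]
        rest_traces = [ensemble_readout(v, ensemble)[1] for v in trB]
        switch = train_switch(mi_traces, rest_traces, step=step,
                              segment_width=segment_width,
                              mi_interval=mi_interval, rng=rng)

        fp = fn = 0
        n_test = len(teL) + len(teR) + len(teB)
        for v in np.concatenate([teL, teR]):
            dets = stream_decode(ensemble_readout(v, ensemble)[1], switch,
                                 threshold=threshold)
            if not dets:
                fn += 1
        for v in teB:
            dets = stream_decode(ensemble_readout(v, ensemble)[1], switch,
                                 threshold=threshold)
            fp += len(dets)
        fp_per_split.append(fp / n_test)
        fn_per_split.append(fn / n_test)

    return SelfPacedResult(fp_rate=float(np.mean(fp_per_split)),
                           fn_rate=float(np.mean(fn_per_split)),
                           fp_per_split=fp_per_split, fn_per_split=fn_per_split,
                           n_splits=n_splits)
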