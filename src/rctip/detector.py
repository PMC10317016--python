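"""Supervised tipping-point detector on readout-weight features.

Training runs with a known change time ``t_p`` yield one positive example
anchored exactly at ``t_p`` — the flattened readout difference ``dW_out``
whose two windows straddle the change — plus negative examples anchored at
times whose full ``[t - T_w, t + T_w)`` span is change-free.  A standard
learner (Random Forest for the classification task, Ridge regression for
the intensity task) maps the feature to a change score.  Scanning a test
series slides the 2*T_w feature span along the data; the resulting score
curve is unimodal around a true change, so its peak locates the tipping
point (and, for regression, the signed peak height estimates the
intensity change).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import Ridge, RidgeCV

from .readout import RidgeSpec, sliding_weights, weight_deltas
from .reservoir import Reservoir, evolve
from .systems import LabeledRun, MultivariateSeries

__all__ = [
    "Scaler",
    "fit_scaler",
    "FeatureSet",
    "DetectorModel",
    "IndexCurve",
    "Detection",
    "build_training_set",
    "build_data_features",
    "train_detector",
    "scan",
    "locate_tipping",
    "ensemble_mean_scan",
]

Task = Literal["classification", "regression"]


@dataclass(frozen=True)
class Scaler:
    """Per-channel standardisation fitted on the training runs.

    The reservoir nonlinearity works in an O(1) regime; observed series
    are shifted/scaled channel-wise by training-set statistics before
    driving the reservoir (the same transform is stored with the model
    and applied at scan time).
    """

    mean: np.ndarray
    std: np.ndarray

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.std

    def narrow(self, sl: slice) -> "Scaler":
        return Scaler(mean=self.mean[sl], std=self.std[sl])


def fit_scaler(runs: Sequence[LabeledRun]) -> Scaler:
    """Channel-wise mean/std over all samples of all runs."""
    stacked = np.concatenate([r.series.values for r in runs], axis=0)
    std = stacked.std(axis=0)
    std[std == 0] = 1.0
    return Scaler(mean=stacked.mean(axis=0), std=std)


@dataclass(frozen=True)
class FeatureSet:
    """Feature matrix with one label per row.

    Classification labels are {0, 1}; regression labels are the signed
    intensity change (0 for change-free anchors).
    """

    features: np.ndarray  # (examples, d)
    labels: np.ndarray  # (examples,)
    task: Task

    def __post_init__(self) -> None:
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("one label per feature row required")
        if self.task == "classification" and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("classification labels must be 0/1")


@dataclass
class DetectorModel:
    """The fitted mapping f from a feature vector to a change score."""

    task: Task
    estimator: object
    family: str
    seed: int
    feature_kind: str = "weight_delta"  # weight_delta | raw_window
    T_w: int = 0
    scaler: Scaler | None = None

    def score(self, features: np.ndarray) -> np.ndarray:
        """Class-1 probability (classification) or predicted intensity."""
        F = np.atleast_2d(np.asarray(features, float))
        if self.task == "classification":
            idx = list(self.estimator.classes_).index(1)
            return self.estimator.predict_proba(F)[:, idx]
        return self.estimator.predict(F)


@dataclass(frozen=True)
class IndexCurve:
    """Detector scores along strictly increasing scan anchors."""

    anchors: np.ndarray
    scores: np.ndarray
    task: Task

    def __post_init__(self) -> None:
        if self.anchors.shape != self.scores.shape:
            raise ValueError("anchors and scores must align")
        if len(self.anchors) and not (np.diff(self.anchors) > 0).all():
            raise ValueError("anchors must be strictly increasing")


@dataclass(frozen=True)
class Detection:
    """A located tipping point with its (regression) intensity estimate."""

    t_hat_p: int
    peak_score: float
    delta_h_hat: float | None = None
    detected: bool = True


# ---------------------------------------------------------------------------
# Training-set construction


def _negative_anchors(
    T: int, t_p: int | None, T_w: int, washout: int, count: int,
    rng: np.random.Generator,
) -> list[int]:
    """Anchors whose whole [t - T_w, t + T_w) span is change-free and clean."""
    lo, hi = washout + T_w, T - T_w  # anchor grid where both windows exist
    candidates = np.arange(lo, hi + 1)
    if t_p is not None:
        ok = (candidates + T_w <= t_p) | (candidates - T_w >= t_p)
        candidates = candidates[ok]
    if candidates.size == 0:
        return []
    k = min(count, candidates.size)
    return sorted(int(a) for a in rng.choice(candidates, size=k, replace=False))


def _delta_at(values: np.ndarray, res: Reservoir, anchor: int, T_w: int,
              spec: RidgeSpec, states: np.ndarray | None = None) -> np.ndarray:
    """Flattened dW_out at one anchor: readouts on [a-T_w, a) and [a, a+T_w)."""
    from .readout import fit_window_readout

    if states is None:
        states = evolve(res, values).states
    X = values
    W1 = fit_window_readout(states[anchor - T_w:anchor], X[anchor - T_w:anchor], spec)
    W2 = fit_window_readout(states[anchor:anchor + T_w], X[anchor:anchor + T_w], spec)
    return (W2 - W1).ravel(order="C")


def build_training_set(
    runs: Sequence[LabeledRun],
    res: Reservoir,
    T_w: int,
    spec: RidgeSpec = RidgeSpec(),
    task: Task = "classification",
    negatives_per_run: int = 3,
    seed: int = 0,
    channel_slice: slice | None = None,
    scaler: Scaler | None = None,
) -> FeatureSet:
    """Assemble labeled ``dW_out`` features from runs with known change times.

    Each changed run contributes one positive example anchored at its
    ``t_p`` (label 1, or the signed intensity change for regression) and up
    to ``negatives_per_run`` negatives at seeded random change-free anchors
    (label 0).  Change-free runs contribute only negatives.
    ``channel_slice`` restricts the observed channels (used by the
    per-subsystem ensemble on networked systems); ``scaler`` — fitted on
    the full channel set — standardises the series before the reservoir.
    """
    rng = np.random.default_rng(seed)
    feats: list[np.ndarray] = []
    labels: list[float] = []
    for run in runs:
        values = run.series.values
        if scaler is not None:
            values = scaler.transform(values)
        if channel_slice is not None:
            values = values[:, channel_slice]
        T = values.shape[0]
        if T < 2 * T_w + res.washout:
            raise ValueError(
                f"run of length {T} too short for T_w={T_w} and washout")
        states = evolve(res, values).states
        if run.t_p is not None:
            a = run.t_p
            if not res.washout + T_w <= a <= T - T_w:
                raise ValueError(
                    f"t_p={a} outside the admissible training band "
                    f"[{res.washout + T_w}, {T - T_w}]")
            feats.append(_delta_at(values, res, a, T_w, spec, states))
            labels.append(1.0 if task == "classification" else run.delta_h)
        for a in _negative_anchors(T, run.t_p, T_w, res.washout,
                                   negatives_per_run, rng):
            feats.append(_delta_at(values, res, a, T_w, spec, states))
            labels.append(0.0)
    if not feats:
        raise ValueError("no admissible anchors in any run")
    return FeatureSet(features=np.vstack(feats), labels=np.asarray(labels), task=task)


def build_data_features(
    runs: Sequence[LabeledRun],
    T_w: int,
    task: Task = "classification",
    negatives_per_run: int = 3,
    seed: int = 0,
    washout: int = 50,
    scaler: Scaler | None = None,
) -> FeatureSet:
    """Baseline features: the flattened raw data window around each anchor.

    Identical labeling scheme to :func:`build_training_set`, but the
    feature at anchor ``t`` is the raw slice ``x[t - T_w] ... x[t + T_w]``
    flattened to length ``(2 T_w + 1) q``.  Plugs into the same
    train/scan/locate chain (the DATA-R / DATA-C baselines).
    """
    rng = np.random.default_rng(seed)
    feats: list[np.ndarray] = []
    labels: list[float] = []
    for run in runs:
        X = run.series.values
        if scaler is not None:
            X = scaler.transform(X)
        T = X.shape[0]
        if run.t_p is not None and run.t_p + T_w < T:
            a = run.t_p
            feats.append(X[a - T_w:a + T_w + 1].ravel(order="C"))
            labels.append(1.0 if task == "classification" else run.delta_h)
        # the inclusive (2 T_w + 1)-sample window needs one extra trailing sample
        for a in _negative_anchors(T - 1, run.t_p, T_w, washout,
                                   negatives_per_run, rng):
            feats.append(X[a - T_w:a + T_w + 1].ravel(order="C"))
            labels.append(0.0)
    if not feats:
        raise ValueError("no admissible anchors in any run")
    return FeatureSet(features=np.vstack(feats), labels=np.asarray(labels), task=task)


# ---------------------------------------------------------------------------
# Model fitting and scanning


def train_detector(
    fs: FeatureSet,
    family: str | None = None,
    seed: int = 0,
    feature_kind: str = "weight_delta",
    T_w: int = 0,
    scaler: Scaler | None = None,
    **hyper,
) -> DetectorModel:
    """Fit the detection function f on a labeled feature set.

    Defaults per task: Random Forest (200 trees) for classification,
    Ridge regression with a leave-one-out cross-validated penalty for the
    intensity task (pass ``alpha`` to pin the penalty instead); both
    seeded and overridable via ``family`` and keyword hyperparameters.
    """
    if fs.task == "classification":
        if len(np.unique(fs.labels)) < 2:
            raise ValueError("classification training set must contain both classes")
        family = family or "random_forest"
        if family == "random_forest":
            est = RandomForestClassifier(
                n_estimators=hyper.pop("n_estimators", 200),
                max_features=hyper.pop("max_features", None),
                class_weight=hyper.pop("class_weight", "balanced"),
                random_state=seed, n_jobs=1, **hyper)
        else:
            raise ValueError(f"unknown classification family {family!r}")
    else:
        family = family or "ridge"
        if family == "ridge":
            if "alpha" in hyper:
                est = Ridge(alpha=hyper.pop("alpha"), **hyper)
            else:
                est = RidgeCV(alphas=hyper.pop("alphas", np.logspace(-4, 4, 17)),
                              **hyper)
        else:
            raise ValueError(f"unknown regression family {family!r}")
    est.fit(fs.features, fs.labels.astype(int) if fs.task == "classification"
            else fs.labels)
    return DetectorModel(task=fs.task, estimator=est, family=family, seed=seed,
                         feature_kind=feature_kind, T_w=T_w, scaler=scaler)


def scan(
    test: MultivariateSeries,
    res: Reservoir,
    model: DetectorModel,
    T_w: int,
    stride: int,
    spec: RidgeSpec = RidgeSpec(),
    method: str = "ridge",
) -> IndexCurve:
    """Slide the 2*T_w feature span along a test series and score each anchor.

    Readouts are fitted on every trailing window of the anchor grid
    (spacing ``stride``, which must divide ``T_w``); their differences give
    one ``dW_out`` per admissible anchor, each scored by the trained model.
    For a raw-window baseline model the features are data slices instead.
    """
    T = test.T
    if T < 2 * T_w + res.washout:
        raise ValueError(
            f"test series of length {T} shorter than 2*T_w + washout")
    values = test.values
    if model.scaler is not None:
        values = model.scaler.transform(values)
    if model.feature_kind == "raw_window":
        anchors = np.arange(res.washout + T_w, T - T_w, stride)
        F = np.stack([values[a - T_w:a + T_w + 1].ravel(order="C")
                      for a in anchors])
    else:
        states = evolve(res, values)
        ws = sliding_weights(states, values, T_w, stride, spec, method=method)
        deltas = weight_deltas(ws, T_w)
        anchors = np.array([d.anchor for d in deltas])
        F = np.stack([d.vector for d in deltas])
    scores = model.score(F)
    return IndexCurve(anchors=anchors, scores=scores, task=model.task)


def locate_tipping(
    curve: IndexCurve,
    task: Task | None = None,
    threshold: float | None = None,
    smooth: int = 1,
    bump_span: int | None = None,
    refine_width: int | None = None,
) -> Detection:
    """Locate the tipping point at the peak of the index curve.

    Classification: anchor of the maximum class-1 probability.  Regression:
    anchor of the maximum absolute score; the signed score there is the
    intensity estimate.  Ties break to the earliest anchor.  If a
    ``threshold`` is given and the peak magnitude stays below it, the
    detection is flagged ``detected=False`` (change-free series).

    Two optional robustness layers exploit the known geometry of a true
    detection — a bump spanning about ``2 T_w / stride`` consecutive
    anchors, whereas fitting artefacts spike on one or two:

    * ``smooth`` (odd) takes a running median of that width before the
      peak search.
    * ``bump_span`` (anchors) first finds the bump region by moving-average
      (matched-filter) scanning at that width, then refines the peak on the
      3-point-median curve within ``refine_width`` samples (default a
      quarter of the matched span) of the region centre.

    With neither option set this is the plain argmax of the curve.
    """
    if len(curve.anchors) == 0:
        raise ValueError("cannot locate a tipping point on an empty curve")
    task = task or curve.task
    scores = curve.scores
    if smooth > 1:
        from scipy.signal import medfilt

        scores = medfilt(scores, kernel_size=smooth | 1)
    key = np.abs(scores) if task == "regression" else scores
    if bump_span is not None and bump_span > 1 and len(scores) > 2:
        from scipy.signal import medfilt

        w = min(bump_span | 1, len(key))
        regional = np.convolve(key, np.ones(w) / w, mode="same")
        a0 = curve.anchors[int(np.argmax(regional))]
        stride = int(np.min(np.diff(curve.anchors))) if len(curve.anchors) > 1 else 1
        half = refine_width if refine_width is not None else (bump_span * stride) // 4
        idx = np.where(np.abs(curve.anchors - a0) <= half)[0]
        local = medfilt(scores, kernel_size=3)
        local_key = np.abs(local) if task == "regression" else local
        i = int(idx[np.argmax(local_key[idx])])
    else:
        i = int(np.argmax(key))  # first maximum: earliest anchor
    peak = float(scores[i])
    detected = True if threshold is None else bool(key[i] >= threshold)
    return Detection(
        t_hat_p=int(curve.anchors[i]),
        peak_score=peak,
        delta_h_hat=peak if task == "regression" else None,
        detected=detected,
    )


def ensemble_mean_scan(curves: Sequence[IndexCurve]) -> IndexCurve:
    """Pointwise mean of per-subsystem index curves sharing one anchor grid."""
    if not curves:
        raise ValueError("need at least one curve")
    anchors = curves[0].anchors
    for c in curves[1:]:
        if not np.array_equal(c.anchors, anchors):
            raise ValueError("curves must share identical anchors")
    scores = np.mean([c.scores for c in curves], axis=0)
    return IndexCurve(anchors=anchors, scores=scores, task=curves[0].task)
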