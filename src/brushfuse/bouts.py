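"""Bout detection: gaps, event features, boundary classification, assembly.

A *bout* is a contiguous run of brush rotation events used continuously by
the same cow(s).  Its first event is a *boundary event*: a transition
between different users, or an event occurring after more than ten seconds
of brush inactivity.  Boundaries are learned from three per-event features
— the inactivity gap preceding the event, the event duration, and the
rotation direction — optionally extended with the same features of
neighbouring events.  At inference a hybrid rule layer can overrule the
classifier where the label is already decided by definition (gap > 10 s ⇒
boundary) or where the classifier never saw training data (gap ≤ 1 s, which
is excluded from the training set).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .records import SENTINEL_FIRST

__all__ = [
    "BoundaryModelSpec",
    "BoundaryModel",
    "compute_gaps",
    "annotate_boundaries",
    "build_features",
    "filter_training_set",
    "train_boundary_classifier",
    "predict_boundaries",
    "assemble_bouts",
]

#: Strict thresholds, read literally: boundaries occur after *more than*
#: ten seconds of inactivity; training keeps only gaps *exceeding* one second.
BOUNDARY_GAP_S = 10.0
TRAIN_GAP_S = 1.0

_DIRECTION_CODE = {"cw": 1.0, "ccw": -1.0}

_DEFAULT_GRIDS = {
    "logistic_regression": {"clf__C": [0.01, 0.1, 1.0, 10.0]},
    "random_forest": {"clf__n_estimators": [100, 300]},
    "svm": {"clf__kernel": ["linear", "rbf"], "clf__C": [0.1, 1.0, 10.0]},
}


def compute_gaps(events: pd.DataFrame) -> pd.DataFrame:
    """Populate ``gap_s``: brush inactivity preceding each event.

    ``gap_s[i] = start[i] − (start[i−1] + duration[i−1])``; the first event
    of the stream gets :data:`~brushfuse.records.SENTINEL_FIRST` (one day),
    which keeps the feature numeric and pushes it firmly to the boundary
    side.  Raises on a negative gap (overlapping input is corrupt).
    """
    out = events.copy()
    n = len(out)
    gaps = np.full(n, SENTINEL_FIRST)
    if n > 1:
        starts = out["start_s"].to_numpy(dtype=float)
        ends = starts + out["duration_s"].to_numpy(dtype=float)
        g = starts[1:] - ends[:-1]
        if np.any(g < -1e-6):
            k = int(np.argmax(g < -1e-6)) + 1
            raise ValueError(
                f"negative gap at event index {k}: events overlap (corrupt input)"
            )
        gaps[1:] = np.maximum(g, 0.0)
    out["gap_s"] = gaps
    return out


def annotate_boundaries(events: pd.DataFrame, event_true_users) -> np.ndarray:
    """Ground-truth boundary labels from per-event true user sets.

    ``flag[i]`` is true iff the user set changed from event ``i−1`` or the
    preceding inactivity gap strictly exceeds 10 s; the first event is
    always a boundary.  Requires ``gap_s`` populated.
    """
    if "gap_s" not in events.columns:
        raise ValueError("gap_s not computed; call compute_gaps first")
    n = len(events)
    if len(event_true_users) != n:
        raise ValueError("one true user set required per event")
    for i, u in enumerate(event_true_users):
        if u is None:
            raise ValueError(f"missing user set for event index {i}")
    flags = np.zeros(n, dtype=bool)
    if n == 0:
        return flags
    flags[0] = True
    gaps = events["gap_s"].to_numpy(dtype=float)
    for i in range(1, n):
        flags[i] = (
            frozenset(event_true_users[i]) != frozenset(event_true_users[i - 1])
            or gaps[i] > BOUNDARY_GAP_S
        )
    return flags


def build_features(events: pd.DataFrame, context_k: int = 0) -> np.ndarray:
    """Per-event feature matrix.

    With ``context_k=0`` each row is ``(gap_s, duration_s, direction_code)``.
    With ``context_k=k`` the same triple of each of the ``k`` preceding and
    ``k`` following events is appended (order: offsets −k..−1, 0, +1..+k),
    followed by ``2k`` validity flags (1 if the neighbour exists, else the
    triple is zero-filled).
    """
    if "gap_s" not in events.columns:
        raise ValueError("gap_s not computed; call compute_gaps first")
    n = len(events)
    base = np.column_stack(
        [
            events["gap_s"].to_numpy(dtype=float),
            events["duration_s"].to_numpy(dtype=float),
            np.array([_DIRECTION_CODE[d] for d in events["direction"]], dtype=float)
            if n
            else np.zeros(0),
        ]
    )
    if context_k == 0:
        return base
    blocks, flags = [], []
    for off in range(-context_k, context_k + 1):
        if off == 0:
            blocks.append(base)
            continue
        shifted = np.zeros_like(base)
        valid = np.zeros(n)
        if off < 0:
            shifted[-off:] = base[:off]
            valid[-off:] = 1.0
        else:
            shifted[:-off] = base[off:]
            valid[:-off] = 1.0
        blocks.append(shifted)
        flags.append(valid)
    return np.column_stack(blocks + flags)


def filter_training_set(
    features: np.ndarray, labels: np.ndarray, gaps: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Keep only rows whose own gap strictly exceeds 1 s.

    Events produced back-to-back (gap ≤ 1 s) are overwhelmingly
    continuations; dropping them rebalances the training classes.  ``gaps``
    defaults to the first feature column (the event's own gap).  Returns the
    subset plus a count report ``{"n_boundary", "n_non_boundary"}``.
    """
    labels = np.asarray(labels, dtype=bool)
    if len(features) != len(labels):
        raise ValueError("features and labels must align")
    if gaps is None:
        gaps = np.asarray(features)[:, 0]
    mask = np.asarray(gaps, dtype=float) > TRAIN_GAP_S
    kept_x, kept_y = np.asarray(features)[mask], labels[mask]
    report = {
        "n_boundary": int(kept_y.sum()),
        "n_non_boundary": int((~kept_y).sum()),
    }
    if len(kept_y) == 0:
        import warnings

        warnings.warn("training filter removed every event (all gaps <= 1 s)")
    return kept_x, kept_y, report


@dataclass
class BoundaryModelSpec:
    """Classifier family + search space for boundary detection."""

    model_kind: str = "logistic_regression"
    grid: dict = field(default_factory=dict)
    cv_folds: int = 5
    seed: int = 0
    class_weighting: str = "balanced"
    context_k: int = 1

    def __post_init__(self):
        if self.model_kind not in _DEFAULT_GRIDS:
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not self.grid:
            self.grid = dict(_DEFAULT_GRIDS[self.model_kind])


@dataclass
class BoundaryModel:
    """A fitted boundary classifier bundled with its feature convention."""

    estimator: object
    spec: BoundaryModelSpec
    cv_report: pd.DataFrame


def _make_estimator(spec: BoundaryModelSpec):
    weight = None if spec.class_weighting == "none" else "balanced"
    if spec.model_kind == "logistic_regression":
        clf = LogisticRegression(class_weight=weight, max_iter=2000)
    elif spec.model_kind == "random_forest":
        clf = RandomForestClassifier(
            class_weight=weight, random_state=spec.seed, n_jobs=1
        )
    else:
        clf = SVC(class_weight=weight, random_state=spec.seed)
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def train_boundary_classifier(
    features: np.ndarray, labels: np.ndarray, spec: BoundaryModelSpec
) -> BoundaryModel:
    """Cross-validated grid search maximizing F1 on the boundary class."""
    labels = np.asarray(labels, dtype=bool)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training set contains a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 examples of each class")
    cv = StratifiedKFold(
        n_splits=min(spec.cv_folds, int(counts.min())),
        shuffle=True,
        random_state=spec.seed,
    )
    search = GridSearchCV(
        _make_estimator(spec),
        spec.grid,
        scoring=["f1", "precision", "recall"],
        refit="f1",
        cv=cv,
        n_jobs=1,
    )
    search.fit(np.asarray(features, dtype=float), labels.astype(int))
    res = search.cv_results_
    cv_report = pd.DataFrame(
        {
            "params": res["params"],
            "mean_f1": res["mean_test_f1"],
            "mean_precision": res["mean_test_precision"],
            "mean_recall": res["mean_test_recall"],
        }
    )
    return BoundaryModel(estimator=search.best_estimator_, spec=spec, cv_report=cv_report)


def predict_boundaries(
    model: BoundaryModel, events: pd.DataFrame, rule_layer: str = "hybrid"
) -> np.ndarray:
    """Predict boundary flags for an event stream (gaps must be computed).

    ``hybrid``: gaps ≤ 1 s are forced non-boundary (the classifier never
    trained there), gaps > 10 s forced boundary (true by definition), the
    classifier decides in between.  ``classifier_only``: the classifier
    decides everywhere.  The first event is a boundary in both modes.
    """
    if rule_layer not in ("hybrid", "classifier_only"):
        raise ValueError(f"unknown rule_layer {rule_layer!r}")
    x = build_features(events, context_k=model.spec.context_k)
    n = len(events)
    flags = np.zeros(n, dtype=bool)
    if n == 0:
        return flags
    flags[:] = model.estimator.predict(x).astype(bool)
    if rule_layer == "hybrid":
        gaps = events["gap_s"].to_numpy(dtype=float)
        flags[gaps <= TRAIN_GAP_S] = False
        flags[gaps > BOUNDARY_GAP_S] = True
    flags[0] = True
    return flags


def assemble_bouts(
    events: pd.DataFrame,
    boundary_flags: np.ndarray,
    duration_convention: str = "rotation",
) -> pd.DataFrame:
    """Group events between consecutive boundaries into bouts.

    ``duration_convention='rotation'`` (default) sums member event durations
    (rotation time ≈ contact time); ``'span'`` uses last end − first start.
    Returns columns ``bout_id, start_s, end_s, midpoint_s, duration_s,
    member_event_ids`` (list of event ids); bouts partition the stream.
    """
    if duration_convention not in ("rotation", "span"):
        raise ValueError(f"unknown duration convention {duration_convention!r}")
    flags = np.asarray(boundary_flags, dtype=bool)
    n = len(events)
    if len(flags) != n:
        raise ValueError("one flag required per event")
    if n == 0:
        return pd.DataFrame(
            columns=["bout_id", "start_s", "end_s", "midpoint_s", "duration_s", "member_event_ids"]
        )
    if not flags[0]:
        raise ValueError("the first event must be a boundary")
    starts = events["start_s"].to_numpy(dtype=float)
    durs = events["duration_s"].to_numpy(dtype=float)
    ids = events["event_id"].to_numpy()
    bound_idx = np.flatnonzero(flags)
    rows = []
    for b, (lo, hi) in enumerate(zip(bound_idx, list(bound_idx[1:]) + [n])):
        start = starts[lo]
        end = starts[hi - 1] + durs[hi - 1]
        dur = durs[lo:hi].sum() if duration_convention == "rotation" else end - start
        rows.append((b, start, end, (start + end) / 2.0, dur, list(ids[lo:hi])))
    return pd.DataFrame(
        rows,
        columns=["bout_id", "start_s", "end_s", "midpoint_s", "duration_s", "member_event_ids"],
    )
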