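"""User attribution: who was using the brush during each event or bout.

Two strategies, applied to either detection stream:

* *proximity* — the animal whose detection lies temporally closest to the
  unit is the (single) user;
* *multilabel ML* — the four temporally nearest animals are candidates;
  their four signed intervals to the unit midpoint (negative before, zero
  during, positive after) feed four per-slot binary classifiers, so a unit
  may receive zero, one or several users.

Both strategies consume the same candidate table, which keeps them directly
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "SENTINEL_FAR",
    "N_SLOTS",
    "AttributionModelSpec",
    "AttributionModel",
    "build_candidates",
    "attribute_proximity",
    "train_attribution_model",
    "attribute_ml",
    "candidate_features",
]

#: Interval imputed for an empty candidate slot (one day, in seconds).
SENTINEL_FAR = 86400.0

#: A unit considers at most this many temporally nearest animals: the brush
#: area cannot hold more than four cows at once or in rapid succession.
N_SLOTS = 4

#: Animal-id placeholder for an empty slot.
MISSING = ""

_DEFAULT_GRIDS = {
    "mlp": {"clf__alpha": [1e-4, 1e-2]},
    "gradient_boosting": {"clf__learning_rate": [0.1, 0.3]},
    "random_forest": {"clf__n_estimators": [100, 300]},
}


def build_candidates(
    units: pd.DataFrame, detections: pd.DataFrame, window_s: float = 120.0
) -> pd.DataFrame:
    """Per unit, the 4 animals detected nearest in time, with signed intervals.

    ``units`` needs columns ``start_s``, ``end_s``, ``midpoint_s`` and an id
    column (``event_id`` or ``bout_id``).  For every animal the single
    detection minimising ``|t − midpoint|`` within ``±window_s`` is
    considered; a detection inside ``[start_s, end_s]`` counts as interval 0
    ("during"), beating any non-zero interval.  Slots are ordered by
    ascending ``|interval|``; ties are broken in favour of detections at or
    before the unit, then lexicographically by animal id.  Units with fewer
    than 4 nearby animals get empty slots with interval ``+SENTINEL_FAR``.

    Returns one row per unit: ``unit_id``, then ``animal_1..4`` and
    ``interval_1..4``.
    """
    id_col = "event_id" if "event_id" in units.columns else "bout_id"
    n_units = len(units)
    mids = units["midpoint_s"].to_numpy(dtype=float)
    starts = units["start_s"].to_numpy(dtype=float)
    ends = units["end_s"].to_numpy(dtype=float)

    animals = sorted(detections["animal_id"].unique()) if len(detections) else []
    n_animals = len(animals)
    iv = np.full((n_units, n_animals), np.inf)
    for j, animal in enumerate(animals):
        t = np.sort(
            detections.loc[detections["animal_id"] == animal, "time_s"].to_numpy(
                dtype=float
            )
        )
        if len(t) == 0:
            continue
        pos = np.searchsorted(t, mids)
        best = np.full(n_units, np.inf)
        left_ok = pos > 0
        best[left_ok] = t[pos[left_ok] - 1] - mids[left_ok]
        right_ok = pos < len(t)
        right_iv = t[pos[right_ok]] - mids[right_ok]
        closer = np.abs(right_iv) < np.abs(best[right_ok])
        tmp = best[right_ok]
        tmp[closer] = right_iv[closer]
        best[right_ok] = tmp
        # any detection inside the unit span → interval 0
        lo = np.searchsorted(t, starts, side="left")
        hi = np.searchsorted(t, ends, side="right")
        best[hi > lo] = 0.0
        best[np.abs(best) > window_s] = np.inf
        iv[:, j] = best

    # rank per unit: |interval| asc, then before/during beats after, then id
    out = {
        "unit_id": units[id_col].to_numpy(),
    }
    slot_animals = np.full((n_units, N_SLOTS), MISSING, dtype=object)
    slot_iv = np.full((n_units, N_SLOTS), SENTINEL_FAR)
    if n_animals:
        after = (iv > 0).astype(float)
        absiv = np.abs(iv)
        aid = np.broadcast_to(np.arange(n_animals, dtype=float), iv.shape)
        order = np.lexsort((aid, after, absiv), axis=1)
        for s in range(min(N_SLOTS, n_animals)):
            j = order[:, s]
            vals = iv[np.arange(n_units), j]
            ok = np.isfinite(vals)
            slot_animals[ok, s] = np.asarray(animals, dtype=object)[j[ok]]
            slot_iv[ok, s] = vals[ok]
    for s in range(N_SLOTS):
        out[f"animal_{s + 1}"] = slot_animals[:, s]
        out[f"interval_{s + 1}"] = slot_iv[:, s]
    return pd.DataFrame(out)


def candidate_features(candidates: pd.DataFrame) -> np.ndarray:
    """The 4 signed intervals, the multilabel model's input matrix."""
    return candidates[[f"interval_{s + 1}" for s in range(N_SLOTS)]].to_numpy(
        dtype=float
    )


def attribute_proximity(candidates: pd.DataFrame, source: str = "") -> pd.DataFrame:
    """Assign the temporally closest detected animal (slot 1) as the user.

    Units with no candidate within the window stay unattributed (empty set).
    Returns ``unit_id``, ``predicted_users`` (frozenset), ``method``,
    ``source``.
    """
    preds = [
        frozenset([a]) if a != MISSING else frozenset()
        for a in candidates["animal_1"]
    ]
    return pd.DataFrame(
        {
            "unit_id": candidates["unit_id"],
            "predicted_users": preds,
            "method": "proximity",
            "source": source,
        }
    )


@dataclass
class AttributionModelSpec:
    """Classifier family + search space for the 4-slot multilabel model."""

    model_kind: str = "random_forest"
    grid: dict = field(default_factory=dict)
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.model_kind not in _DEFAULT_GRIDS:
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not self.grid:
            self.grid = dict(_DEFAULT_GRIDS[self.model_kind])


@dataclass
class AttributionModel:
    """Four fitted per-slot binary classifiers (one-classifier-per-target)."""

    slot_estimators: list
    spec: AttributionModelSpec
    cv_report: pd.DataFrame


def _make_estimator(spec: AttributionModelSpec):
    if spec.model_kind == "mlp":
        clf = MLPClassifier(
            hidden_layer_sizes=(16,),
            max_iter=300,
            random_state=spec.seed,
        )
    elif spec.model_kind == "gradient_boosting":
        clf = HistGradientBoostingClassifier(random_state=spec.seed)
    else:
        clf = RandomForestClassifier(random_state=spec.seed, n_jobs=1)
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def slot_targets(candidates: pd.DataFrame, true_user_sets) -> np.ndarray:
    """Positional binary targets: y[i, j] = slot-j animal ∈ true_users[i]."""
    n = len(candidates)
    if len(true_user_sets) != n:
        raise ValueError("one true user set required per unit")
    y = np.zeros((n, N_SLOTS), dtype=int)
    for s in range(N_SLOTS):
        col = candidates[f"animal_{s + 1}"].to_numpy()
        for i, truth in enumerate(true_user_sets):
            if col[i] != MISSING and col[i] in truth:
                y[i, s] = 1
    return y


def train_attribution_model(
    candidates: pd.DataFrame, true_user_sets, spec: AttributionModelSpec
) -> AttributionModel:
    """Fit one cross-validated classifier per candidate slot.

    Each slot's classifier is grid-searched with F1 on that slot's binary
    target.  A slot whose training target is single-class (e.g. slot 4 is
    never a user) falls back to a constant predictor with a warning.
    """
    x = candidate_features(candidates)
    y = slot_targets(candidates, true_user_sets)
    estimators, report_rows = [], []
    for s in range(N_SLOTS):
        ys = y[:, s]
        classes, counts = np.unique(ys, return_counts=True)
        if len(classes) < 2 or counts.min() < 2:
            warnings.warn(
                f"slot {s + 1} target is (nearly) single-class; using a constant predictor"
            )
            est = DummyClassifier(strategy="most_frequent").fit(x, ys)
            estimators.append(est)
            report_rows.append({"slot": s + 1, "params": None, "mean_f1": np.nan})
            continue
        cv = StratifiedKFold(
            n_splits=min(spec.cv_folds, int(counts.min())),
            shuffle=True,
            random_state=spec.seed,
        )
        search = GridSearchCV(
            _make_estimator(spec), spec.grid, scoring="f1", cv=cv, n_jobs=1
        )
        search.fit(x, ys)
        estimators.append(search.best_estimator_)
        report_rows.append(
            {
                "slot": s + 1,
                "params": search.best_params_,
                "mean_f1": float(search.best_score_),
            }
        )
    return AttributionModel(
        slot_estimators=estimators, spec=spec, cv_report=pd.DataFrame(report_rows)
    )


def attribute_ml(
    model: AttributionModel, candidates: pd.DataFrame, source: str = ""
) -> pd.DataFrame:
    """Predict user sets with the 4-slot model; multiple users allowed.

    A positive prediction on an empty slot is suppressed (no animal to
    name); an all-negative unit stays unattributed.
    """
    x = candidate_features(candidates)
    n = len(candidates)
    preds = [set() for _ in range(n)]
    if n:
        for s in range(N_SLOTS):
            pos = np.asarray(model.slot_estimators[s].predict(x)).astype(bool)
            col = candidates[f"animal_{s + 1}"].to_numpy()
            for i in np.flatnonzero(pos):
                if col[i] != MISSING:
                    preds[i].add(col[i])
    return pd.DataFrame(
        {
            "unit_id": candidates["unit_id"],
            "predicted_users": [frozenset(p) for p in preds],
            "method": "ml",
            "source": source,
        }
    )
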