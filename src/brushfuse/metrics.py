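"""Evaluation and aggregation: daily totals, classification metrics,
multilabel Jaccard, and Pearson validation against ground truth.

Undefined ratios (for instance precision when nothing was predicted
positive) are reported as ``nan``, never silently zeroed: comparing
attribution methods on rates that were quietly clamped would be misleading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .attribution import MISSING, N_SLOTS
from .records import SECONDS_PER_DAY

__all__ = [
    "MetricsReport",
    "aggregate_daily_use",
    "boundary_metrics",
    "average_jaccard",
    "multilabel_pr",
    "pearson_daily",
]


@dataclass
class MetricsReport:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    precision: float = np.nan
    recall: float = np.nan
    f1: float = np.nan

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def aggregate_daily_use(
    units: pd.DataFrame, assignments: pd.DataFrame, credit: str = "full"
) -> pd.DataFrame:
    """Sum attributed unit durations into an animal × day table.

    ``credit='full'`` (default) credits each predicted user with the whole
    unit duration — ground truth measures each animal's own use, including
    simultaneous co-use.  ``credit='split'`` divides the duration equally
    among predicted users, which conserves total seconds.  Unattributed
    units (empty prediction) contribute to no animal.
    """
    if credit not in ("full", "split"):
        raise ValueError(f"unknown credit mode {credit!r}")
    id_col = "event_id" if "event_id" in units.columns else "bout_id"
    lut = units.set_index(id_col)
    rows: dict[tuple[str, int], float] = {}
    for rec in assignments.itertuples():
        users = rec.predicted_users
        if not users:
            continue
        unit = lut.loc[rec.unit_id]
        day = int(unit["start_s"] // SECONDS_PER_DAY)
        dur = float(unit["duration_s"])
        share = dur if credit == "full" else dur / len(users)
        for cow in users:
            key = (cow, day)
            rows[key] = rows.get(key, 0.0) + share
    return pd.DataFrame(
        [(c, d, s) for (c, d), s in sorted(rows.items())],
        columns=["cow_id", "day", "seconds"],
    )


def boundary_metrics(pred_flags, true_flags) -> MetricsReport:
    """Event-level confusion counts and precision/recall/F1.

    ``precision = TP/(TP+FP)``, ``recall = TP/(TP+FN)``,
    ``F1 = 2·P·R/(P+R)``; each is ``nan`` where its denominator is zero.
    """
    pred = np.asarray(pred_flags, dtype=bool)
    true = np.asarray(true_flags, dtype=bool)
    if pred.shape != true.shape:
        raise ValueError("flag vectors must have equal length")
    tp = int(np.sum(pred & true))
    tn = int(np.sum(~pred & ~true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    precision = tp / (tp + fp) if tp + fp else np.nan
    recall = tp / (tp + fn) if tp + fn else np.nan
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = np.nan
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return MetricsReport(tp, tn, fp, fn, precision, recall, f1)


def average_jaccard(pred_sets, true_sets) -> float:
    """Mean over units of ``|P ∩ L| / |P ∪ L|``.

    A unit where both sets are empty scores 1: predicting "no user" when
    there was none is a correct prediction (the raw ratio is 0/0 there).
    """
    if len(pred_sets) != len(true_sets):
        raise ValueError("prediction and truth lists must align")
    if len(pred_sets) == 0:
        raise ValueError("average_jaccard of an empty list is undefined")
    total = 0.0
    for p, t in zip(pred_sets, true_sets):
        p, t = set(p), set(t)
        union = len(p | t)
        total += 1.0 if union == 0 else len(p & t) / union
    return total / len(pred_sets)


def multilabel_pr(pred_sets, true_sets, candidates: pd.DataFrame) -> dict:
    """Per-slot precision/recall of "the slot-j animal is a user".

    For each of the four candidate slots, the slot's animal induces a binary
    prediction (animal ∈ predicted set) and truth (animal ∈ true set);
    empty slots count as negative on both sides.  Returns per-slot vectors
    plus macro averages over the slots where the ratio is defined (a slot
    with no positive truth has undefined recall and is excluded with a
    warning).
    """
    n = len(candidates)
    if len(pred_sets) != n or len(true_sets) != n:
        raise ValueError("prediction/truth lists must align with candidates")
    precisions, recalls = [], []
    for s in range(N_SLOTS):
        col = candidates[f"animal_{s + 1}"].to_numpy()
        yp = np.array(
            [a != MISSING and a in p for a, p in zip(col, pred_sets)], dtype=bool
        )
        yt = np.array(
            [a != MISSING and a in t for a, t in zip(col, true_sets)], dtype=bool
        )
        tp = int(np.sum(yp & yt))
        fp = int(np.sum(yp & ~yt))
        fn = int(np.sum(~yp & yt))
        precisions.append(tp / (tp + fp) if tp + fp else np.nan)
        recalls.append(tp / (tp + fn) if tp + fn else np.nan)
    if any(np.isnan(r) for r in recalls):
        import warnings

        warnings.warn("slot(s) with no positive truth excluded from macro recall")
    return {
        "per_slot_precision": precisions,
        "per_slot_recall": recalls,
        "macro_precision": float(np.nanmean(precisions))
        if not all(np.isnan(p) for p in precisions)
        else np.nan,
        "macro_recall": float(np.nanmean(recalls))
        if not all(np.isnan(r) for r in recalls)
        else np.nan,
    }


def pearson_daily(est: pd.DataFrame, truth: pd.DataFrame) -> float:
    """Pearson r between estimated and true daily per-animal totals.

    Tables are outer-joined on ``(cow_id, day)``; an animal-day absent from
    one table counts as 0 s there.  Returns ``nan`` (with no exception) for
    fewer than 3 pairs or zero variance.
    """
    merged = pd.merge(
        truth, est, on=["cow_id", "day"], how="outer", suffixes=("_true", "_est")
    ).fillna(0.0)
    x = merged["seconds_true"].to_numpy(dtype=float)
    y = merged["seconds_est"].to_numpy(dtype=float)
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)
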