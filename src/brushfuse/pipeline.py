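"""End-to-end pipeline: simulate → detect bouts → attribute → aggregate →
evaluate, with a YAML config, per-stage sub-seeding and a run manifest.

Every stage writes plain CSV/JSON artifacts into the run directory, so any
stage can also be re-run standalone on the previous stage's files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attribution as at
from . import bouts as bt
from . import harness as hx
from . import metrics as mx
from . import records as rec
from . import simulate as sim

__all__ = ["load_config", "derive_seed", "run_pipeline"]

log = logging.getLogger("brushfuse")

_SIM_KEYS = {f.name for f in dataclasses.fields(sim.SimConfig)}


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (< 2**31) from one global seed."""
    digest = hashlib.blake2b(f"{seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return normalize_config(cfg)


def normalize_config(cfg: dict) -> dict:
    """Fill defaults and validate the pipeline config mapping."""
    out = {
        "seed": int(cfg.get("seed", 0)),
        "sim": dict(cfg.get("sim", {})),
        "bout": {
            "model_kind": "logistic_regression",
            "context_k": 1,
            "rule_layer": "hybrid",
            "duration_convention": "rotation",
            **cfg.get("bout", {}),
        },
        "attribution": {
            "event_model_kind": "random_forest",
            "bout_model_kind": "random_forest",
            "window_s": 120.0,
            "credit": "full",
            **cfg.get("attribution", {}),
        },
        "split": {"train_days": 2, "test_days": 1, **cfg.get("split", {})},
    }
    unknown = set(out["sim"]) - _SIM_KEYS
    if unknown:
        raise ValueError(f"unknown sim config keys: {sorted(unknown)}")
    n_days = out["sim"].get("n_days", 3)
    split = out["split"]
    if split["test_days"] < 1 or split["train_days"] < 1:
        raise ValueError("train_days and test_days must each be >= 1")
    if split["train_days"] + split["test_days"] > n_days:
        raise ValueError("train_days + test_days exceeds simulated days")
    return out


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_simulation(cfg: dict, out_dir: Path) -> dict:
    """Stage 1: simulate a pen and write every stream as CSV."""
    sim_cfg = sim.SimConfig(**cfg["sim"], seed=derive_seed(cfg["seed"], "simulate"))
    data = sim.simulate_all(sim_cfg)
    out_dir.mkdir(parents=True, exist_ok=True)
    rec.write_events(data["events"], out_dir / "events.csv")
    rec.write_detections(data["detections_vision"], out_dir / "detections_vision.csv")
    rec.write_detections(data["detections_rfid"], out_dir / "detections_rfid.csv")
    truth = data["truth"]
    ann = pd.DataFrame(
        {
            "unit_kind": "event",
            "unit_id": data["events"]["event_id"],
            "true_users": truth.event_users,
        }
    )
    rec.write_annotations(ann, out_dir / "annotations_events.csv")
    rec.write_daily_use(truth.daily_use, out_dir / "daily_truth.csv")
    np.savetxt(
        out_dir / "boundaries_true.csv",
        truth.boundary.astype(int),
        fmt="%d",
        header="boundary",
        comments="",
    )
    log.info(
        "simulate: %d visits, %d events, %d vision / %d rfid detections",
        len(data["schedule"]),
        len(data["events"]),
        len(data["detections_vision"]),
        len(data["detections_rfid"]),
    )
    return data


def run_pipeline(cfg: dict, out_dir) -> dict:
    """Run every stage; returns the report dict written to report.json."""
    out_dir = Path(out_dir)
    data = write_simulation(cfg, out_dir)
    events = data["events"]
    truth = data["truth"]

    n_days = data["schedule"]["day"].nunique()
    split = cfg["split"]
    train_days = tuple(range(split["train_days"]))
    test_day = split["train_days"]  # first held-out day

    seed = derive_seed(cfg["seed"], "models")
    b = cfg["bout"]
    a = cfg["attribution"]
    table, extras = hx.run_comparison_harness(
        events,
        {"vision": data["detections_vision"], "rfid": data["detections_rfid"]},
        truth,
        boundary_spec=bt.BoundaryModelSpec(
            model_kind=b["model_kind"], context_k=b["context_k"], seed=seed
        ),
        event_spec=at.AttributionModelSpec(model_kind=a["event_model_kind"], seed=seed),
        bout_spec=at.AttributionModelSpec(model_kind=a["bout_model_kind"], seed=seed),
        train_days=train_days,
        test_day=test_day,
        window_s=a["window_s"],
        rule_layer=b["rule_layer"],
        credit=a["credit"],
        duration_convention=b["duration_convention"],
        seed=seed,
    )
    table.to_csv(out_dir / "comparison.csv", index=False)
    extras["bouts_test"].assign(
        member_event_ids=[
            ";".join(str(i) for i in m) for m in extras["bouts_test"]["member_event_ids"]
        ]
    ).to_csv(out_dir / "bouts_test.csv", index=False)

    report = {
        "config_hash": config_hash(cfg),
        "seed": cfg["seed"],
        "n_days": int(n_days),
        "test_day": int(test_day),
        "boundary": {
            k: (None if isinstance(v, float) and np.isnan(v) else v)
            for k, v in extras["boundary"].as_dict().items()
        },
        "comparison": [
            {k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in row.items()}
            for row in table.to_dict(orient="records")
        ],
        "manifest": {
            "n_visits": int(len(data["schedule"])),
            "n_events": int(len(events)),
            "n_detections_vision": int(len(data["detections_vision"])),
            "n_detections_rfid": int(len(data["detections_rfid"])),
            "n_bouts_test": int(len(extras["bouts_test"])),
        },
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
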