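import warnings

import numpy as np
import pandas as pd
import pytest

import brushfuse as bf
from brushfuse import attribution as at
from brushfuse import bouts as bt

# single-class candidate slots are routine in clean simulations
warnings.filterwarnings(
    "ignore", message="slot .* target is .*single-class", category=UserWarning
)


def make_events(starts, durations, directions=None):
    """Build an in-memory event frame from explicit times (seconds)."""
    n = len(starts)
    if directions is None:
        directions = ["cw" if i % 2 == 0 else "ccw" for i in range(n)]
    return pd.DataFrame(
        {
            "event_id": np.arange(n),
            "start_s": np.asarray(starts, dtype=float),
            "duration_s": np.asarray(durations, dtype=float),
            "direction": directions,
        }
    )


def make_detections(times, animals, source="vision"):
    return pd.DataFrame(
        {
            "time_s": np.asarray(times, dtype=float),
            "animal_id": list(animals),
            "source": source,
        }
    )


@pytest.fixture(scope="session")
def small_sim():
    """One simulated day of a small pen with default noise, shared across tests."""
    cfg = bf.SimConfig(n_cows=8, n_days=1, seed=42)
    return cfg, bf.simulate_all(cfg)


@pytest.fixture(scope="session")
def noiseless_sim():
    """A noiseless 3-day default-size pen (deterministic structure)."""
    cfg = bf.SimConfig.noiseless(seed=7)
    return cfg, bf.simulate_all(cfg)


def fast_boundary_spec(seed=0, **kw):
    return bt.BoundaryModelSpec(
        model_kind="logistic_regression", grid={"clf__C": [0.1, 1.0]},
        cv_folds=3, seed=seed, **kw,
    )


def fast_attribution_spec(seed=0, model_kind="random_forest"):
    grids = {
        "random_forest": {"clf__n_estimators": [100]},
        "mlp": {"clf__alpha": [1e-3]},
        "gradient_boosting": {"clf__learning_rate": [0.1]},
    }
    return at.AttributionModelSpec(
        model_kind=model_kind, grid=grids[model_kind], cv_folds=3, seed=seed
    )
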