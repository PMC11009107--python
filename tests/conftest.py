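"""Shared fixtures: synthetic event tables built through the real pipeline."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cupore.classify import FEATURE_COLUMNS
from cupore.params import DEFAULT_PARAMS
from cupore.signals import FEATURE_NAMES, detect_events, events_to_frame
from cupore.simulate import TraceConfig, simulate_trace


def make_labeled_events(
    classes: list[str],
    n_experiments: int = 2,
    duration: float = 60.0,
    rate_per_min: float = 360.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Labeled event table from simulated single-class recordings.

    Each class is recorded in ``n_experiments`` independent traces at a
    concentration chosen to give ``rate_per_min`` arrivals per minute; the
    traces run through the full detection chain, state-1 events only.
    """
    frames = []
    s = seed
    for cls in classes:
        p = DEFAULT_PARAMS[cls]
        conc = rate_per_min / p.capture_rate
        for e in range(n_experiments):
            cfg = TraceConfig.fast(duration=duration, seed=s)
            s += 1
            trace, _ = simulate_trace([(p, conc)], cfg)
            events, _, _ = detect_events(trace, experiment_id=f"{cls}-{e}")
            df = events_to_frame(events, trace.sampling_rate, label=cls)
            df = df[df["n_sublevels"] == 1]
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def toy_feature_frame(
    blockade: np.ndarray,
    dwell_ms: np.ndarray | float = 5.0,
    level_sd: np.ndarray | float = 1.0,
    peak_width: float = 0.01,
) -> pd.DataFrame:
    """Minimal event table with the full 1,003-column feature schema.

    Density features are a Gaussian bump at ``1 - blockade`` (the
    standardized event level), mimicking what the detector would produce.
    """
    blockade = np.atleast_1d(np.asarray(blockade, dtype=float))
    n = blockade.size
    grid = np.arange(1, 1001) * 0.001
    X = np.exp(
        -0.5 * ((grid[None, :] - (1.0 - blockade)[:, None]) / peak_width) ** 2
    ) / (peak_width * np.sqrt(2 * np.pi))
    df = pd.DataFrame(
        {
            "blockade": blockade,
            "dwell_ms": np.broadcast_to(np.asarray(dwell_ms, dtype=float), (n,)).copy(),
            "level_sd": np.broadcast_to(np.asarray(level_sd, dtype=float), (n,)).copy(),
        }
    )
    df = pd.concat([df, pd.DataFrame(X, columns=FEATURE_NAMES)], axis=1)
    return df[FEATURE_COLUMNS]


@pytest.fixture(scope="session")
def labeled_events_4class() -> pd.DataFrame:
    """Events of the four calibrated classes (S, K, Ac-K, P-S), 2 experiments each."""
    return make_labeled_events(["S", "K", "Ac-K", "P-S"], seed=42)
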