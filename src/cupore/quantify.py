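"""Signal frequencies, concentration calibration and limit-of-detection.

Event counts per minute scale linearly with analyte concentration, so an
ordinary least-squares fit of frequency on concentration yields a per-class
calibration that can be inverted to estimate unknown concentrations.  The
limit-of-detection criterion is count-based: a class is detectable when
some continuous 10-minute stretch of the recording contains more than five
confident calls of that class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "signal_frequency",
    "CalibrationResult",
    "calibrate",
    "estimate_concentration",
    "lod_assess",
]


def signal_frequency(
    events: pd.DataFrame | int,
    duration_min: float,
    label: str | None = None,
) -> float:
    """Events per minute, optionally restricted to one class label."""
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    if isinstance(events, (int, np.integer)):
        count = int(events)
        if label is not None:
            raise ValueError("label filter needs an event table, not a count")
    else:
        if label is not None:
            col = "call" if "call" in events.columns else "label"
            count = int((events[col] == label).sum())
        else:
            count = len(events)
    return count / duration_min


@dataclass(frozen=True)
class CalibrationResult:
    """OLS calibration of signal frequency (min^-1) on concentration (µM)."""

    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    r_squared: float
    adj_r_squared: float
    se_slope: float
    se_intercept: float
    cov_slope_intercept: float
    n: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def calibrate(
    frequencies: np.ndarray, concentrations: np.ndarray
) -> CalibrationResult:
    """Fit frequency = slope * concentration + intercept by OLS."""
    f = np.asarray(frequencies, dtype=np.float64)
    c = np.asarray(concentrations, dtype=np.float64)
    if f.shape != c.shape or f.ndim != 1:
        raise ValueError("frequencies and concentrations must be 1-D and aligned")
    if np.unique(c).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if np.ptp(f) == 0:
        raise ValueError("constant frequencies: correlation undefined")
    X = sm.add_constant(c)
    res = sm.OLS(f, X).fit()
    r = float(np.corrcoef(c, f)[0, 1])
    cov = res.cov_params()
    return CalibrationResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        pearson_r=r,
        p_value=float(res.pvalues[1]),
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        se_slope=float(res.bse[1]),
        se_intercept=float(res.bse[0]),
        cov_slope_intercept=float(np.asarray(cov)[0, 1]),
        n=int(f.size),
    )


def estimate_concentration(
    frequency: float, calibration: CalibrationResult
) -> tuple[float, float]:
    """Invert a calibration: concentration (µM) with delta-method s.e.

    The estimate is ``(f - intercept) / slope``; its standard error
    propagates the joint uncertainty of slope and intercept.
    """
    a, b = calibration.slope, calibration.intercept
    if a <= 0:
        raise ValueError("calibration slope must be positive to invert")
    conc = (frequency - b) / a
    # gradient of g(a, b) = (f - b)/a
    ga, gb = -conc / a, -1.0 / a
    var = (
        ga * ga * calibration.se_slope**2
        + gb * gb * calibration.se_intercept**2
        + 2 * ga * gb * calibration.cov_slope_intercept
    )
    return float(conc), float(np.sqrt(max(var, 0.0)))


def lod_assess(
    call_times_s: np.ndarray,
    recording_duration_min: float,
    window_min: float = 10.0,
    step_s: float = 1.0,
    min_count: int = 6,
) -> tuple[bool, dict]:
    """Count-based detectability: > 5 calls in some continuous 10-min window.

    ``call_times_s`` are onset timestamps (seconds) of the confident calls
    of one class.  The window slides over the recording at ``step_s``
    resolution; detectability requires at least ``min_count`` (= strictly
    more than five) calls inside a single window.
    """
    if recording_duration_min < window_min:
        raise ValueError(
            f"recording must span at least {window_min} min for the LOD criterion"
        )
    t = np.sort(np.asarray(call_times_s, dtype=np.float64))
    win_s = window_min * 60.0
    total_s = recording_duration_min * 60.0
    best = 0
    best_start = 0.0
    starts = np.arange(0.0, max(total_s - win_s, 0.0) + step_s / 2, step_s)
    for s in starts:
        cnt = int(np.searchsorted(t, s + win_s, side="right") - np.searchsorted(t, s))
        if cnt > best:
            best, best_start = cnt, float(s)
    detectable = best >= min_count
    return detectable, {
        "max_window_count": best,
        "window_start_s": best_start,
        "min_count": min_count,
        "n_calls_total": int(t.size),
    }
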