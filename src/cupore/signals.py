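"""Event extraction from raw current traces.

The pipeline mirrors standard single-channel blockade analysis: the raw
trace is segmented at its optimal change points (penalized Gaussian
mean+variance cost), polished to the per-segment means, the state-0
baseline I0 is estimated as the duration-weighted mode of segment levels,
and maximal runs of segments at least ``min_blockade`` below I0 become
candidate translocation events.  Each event is summarised by its blockade
(I0 - I1)/I0, dwell time, level s.d. and a 1,000-point density feature
vector (the kernel density of the I0-standardized in-event samples on the
grid 0.001 ... 1.000).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._pelt import pelt_gaussian

__all__ = [
    "CurrentTrace",
    "SegmentedTrace",
    "BaselineEstimate",
    "Event",
    "DENSITY_GRID",
    "FEATURE_NAMES",
    "detect_change_points",
    "polish_trace",
    "estimate_baseline",
    "extract_events",
    "compute_density_features",
    "characterize_dwell",
    "fit_blockade_distribution",
    "detect_events",
    "events_to_frame",
]

LN2 = float(np.log(2.0))

#: Fixed evaluation grid of the density features: 0.001, 0.002, ..., 1.000.
DENSITY_GRID = np.round(np.arange(1, 1001) * 0.001, 3)

#: Column names X0001 ... X1000 of the density features.
FEATURE_NAMES = [f"X{i:04d}" for i in range(1, 1001)]


@dataclass
class CurrentTrace:
    """A uniformly sampled single-channel current recording."""

    samples: np.ndarray  # pA
    sampling_rate: float  # Hz
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.size / self.sampling_rate


@dataclass
class SegmentedTrace:
    """A trace partitioned at change points into piecewise-constant segments."""

    change_points: np.ndarray  # internal break indices, strictly increasing
    segment_means: np.ndarray  # pA, one per segment
    segment_lengths: np.ndarray  # samples, one per segment
    n_samples: int
    sampling_rate: float

    @property
    def bounds(self) -> np.ndarray:
        """Segment boundaries [0, cp_1, ..., cp_k, n]."""
        return np.concatenate(([0], self.change_points, [self.n_samples]))

    def polished(self) -> np.ndarray:
        """Piecewise-constant series: each sample replaced by its segment mean."""
        return np.repeat(self.segment_means, self.segment_lengths)


@dataclass
class BaselineEstimate:
    """State-0 baseline level I0 with per-window estimates for drift tracking."""

    I0: float  # pA
    window_I0: np.ndarray  # per-window estimates
    window_s: float  # window length used
    coverage: float  # duration fraction of the modal cluster

    def __post_init__(self) -> None:
        if self.I0 <= 0:
            raise ValueError("I0 must be positive")


@dataclass
class Event:
    """One candidate amino-acid binding event (half-open sample interval)."""

    start: int
    end: int
    dwell_ms: float
    mean_level: float  # I1, pA (duration-weighted over sub-segments)
    blockade: float  # (I0 - I1)/I0
    level_sd: float  # pA, s.d. of raw in-event samples
    n_sublevels: int = 1
    density_features: np.ndarray | None = None
    experiment_id: str = ""


def detect_change_points(
    trace: CurrentTrace,
    penalty: float | None = None,
    min_size: int = 5,
    chunk_size: int = 200_000,
) -> np.ndarray:
    """Optimal change points of the raw current (mean and variance cost).

    ``penalty`` defaults to ``5 * log(n)``, a BIC-like choice that admits
    genuine level changes a few noise s.d. deep while ignoring fluctuation
    in homogeneous stretches.  Traces longer than ``chunk_size`` are
    segmented chunk by chunk (chunk boundaries are reported as breaks; the
    downstream event extractor merges segments across them, so only the
    segmentation bookkeeping — not the event set — is affected).
    """
    x = trace.samples
    n = x.size
    if penalty is None:
        penalty = 5.0 * np.log(n)
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    if n <= chunk_size:
        return pelt_gaussian(x, penalty, min_size=min_size)
    breaks: list[np.ndarray] = []
    for a in range(0, n, chunk_size):
        b = min(a + chunk_size, n)
        if b - a < 2 * min_size:
            breaks.append(np.array([a], dtype=np.int64))
            continue
        cps = pelt_gaussian(x[a:b], penalty, min_size=min_size) + a
        if a > 0:
            cps = np.concatenate(([a], cps))
        breaks.append(cps)
    return np.concatenate(breaks).astype(np.int64)


def polish_trace(trace: CurrentTrace, change_points: Sequence[int]) -> SegmentedTrace:
    """Replace each inter-change-point segment by its arithmetic mean."""
    n = trace.samples.size
    cps = np.asarray(change_points, dtype=np.int64)
    if cps.size and (np.any(np.diff(cps) <= 0) or cps[0] <= 0 or cps[-1] >= n):
        raise ValueError("change points must be strictly increasing interior indices")
    bounds = np.concatenate(([0], cps, [n]))
    csum = np.concatenate(([0.0], np.cumsum(trace.samples)))
    lengths = np.diff(bounds)
    means = (csum[bounds[1:]] - csum[bounds[:-1]]) / lengths
    return SegmentedTrace(
        change_points=cps,
        segment_means=means,
        segment_lengths=lengths,
        n_samples=n,
        sampling_rate=trace.sampling_rate,
    )


def estimate_baseline(
    segmented: SegmentedTrace,
    rel_tol: float = 0.02,
    min_coverage: float = 0.2,
    window_s: float = 30.0,
) -> BaselineEstimate:
    """Estimate the state-0 baseline I0 from a segmented trace.

    I0 is the duration-weighted mode of the segment levels: the tightest
    cluster of segment means (relative width ``rel_tol``) carrying the
    most recording time.  Blockade events lie well below it and open-pore
    copper excursions above it, so neither perturbs the mode.  Per-window
    re-estimates track slow drift.  Raises if no cluster covers at least
    ``min_coverage`` of the duration (no stable baseline).
    """

    def weighted_mode(levels: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
        order = np.argsort(levels)
        lv, w = levels[order], weights[order]
        cw = np.concatenate(([0.0], np.cumsum(w)))
        best_w, best_lo, best_hi = -1.0, 0, 0
        j = 0
        for i in range(lv.size):
            while lv[i] - lv[j] > rel_tol * max(lv[i], 1e-12):
                j += 1
            tot = cw[i + 1] - cw[j]
            if tot > best_w:
                best_w, best_lo, best_hi = tot, j, i + 1
        sel = slice(best_lo, best_hi)
        mode = float(np.average(lv[sel], weights=w[sel]))
        return mode, best_w / weights.sum()

    if segmented.segment_means.size == 0:
        raise ValueError("segmented trace has no segments")
    I0, coverage = weighted_mode(segmented.segment_means, segmented.segment_lengths.astype(float))
    if coverage < min_coverage:
        raise ValueError(
            f"no stable baseline: modal cluster covers {coverage:.1%} < {min_coverage:.0%}"
        )

    # per-window estimates (fall back to global where a window has no mode)
    win = max(1, int(round(window_s * segmented.sampling_rate)))
    bounds = segmented.bounds
    centers = (bounds[:-1] + bounds[1:]) / 2
    n_win = max(1, int(np.ceil(segmented.n_samples / win)))
    window_I0 = np.full(n_win, I0)
    idx = np.minimum((centers // win).astype(int), n_win - 1)
    for w_i in range(n_win):
        m = idx == w_i
        if not np.any(m):
            continue
        lv = segmented.segment_means[m]
        wt = segmented.segment_lengths[m].astype(float)
        # drop segments far below the running mode (events), then re-mode
        keep = lv > 0.9 * I0
        if np.any(keep):
            mode_w, cov_w = weighted_mode(lv[keep], wt[keep])
            if cov_w * wt[keep].sum() >= min_coverage * wt.sum():
                window_I0[w_i] = mode_w
    return BaselineEstimate(I0=I0, window_I0=window_I0, window_s=window_s, coverage=coverage)


def extract_events(
    segmented: SegmentedTrace,
    baseline: BaselineEstimate,
    min_blockade: float = 0.1,
    min_dwell_ms: float = 0.5,
    sublevel_tol: float = 0.05,
) -> list[Event]:
    """Group blocked segments into translocation events.

    Maximal runs of consecutive segments whose mean lies at least
    ``min_blockade`` below I0 form one event; I1 is the duration-weighted
    mean over the run.  Sub-segments whose levels differ by more than
    ``sublevel_tol * I0`` are counted as distinct sub-levels (state-2
    events have ``n_sublevels > 1``).  Events shorter than
    ``min_dwell_ms`` are dropped, as are segments above baseline (open-pore
    copper excursions).
    """
    I0 = baseline.I0
    thresh = I0 * (1.0 - min_blockade)
    means = segmented.segment_means
    lengths = segmented.segment_lengths
    bounds = segmented.bounds
    blocked = means <= thresh

    events: list[Event] = []
    i = 0
    n_seg = means.size
    while i < n_seg:
        if not blocked[i]:
            i += 1
            continue
        j = i
        while j + 1 < n_seg and blocked[j + 1]:
            j += 1
        start, end = int(bounds[i]), int(bounds[j + 1])
        run_means = means[i : j + 1]
        run_lens = lengths[i : j + 1].astype(float)
        I1 = float(np.average(run_means, weights=run_lens))
        dwell_ms = (end - start) / segmented.sampling_rate * 1000.0
        if dwell_ms >= min_dwell_ms:
            # count distinct levels among sub-segments
            n_sub = 1
            for a, b in zip(run_means[:-1], run_means[1:]):
                if abs(b - a) > sublevel_tol * I0:
                    n_sub += 1
            events.append(
                Event(
                    start=start,
                    end=end,
                    dwell_ms=dwell_ms,
                    mean_level=I1,
                    blockade=(I0 - I1) / I0,
                    level_sd=0.0,
                    n_sublevels=n_sub,
                )
            )
        i = j + 1
    return events


def compute_density_features(
    event: Event,
    trace: CurrentTrace,
    baseline: BaselineEstimate,
    bandwidth: float | None = None,
) -> np.ndarray:
    """1,000-point density feature vector of an event.

    The raw in-event samples are standardized by I0 and a Gaussian kernel
    density (Silverman bandwidth unless given) is evaluated on the fixed
    grid 0.001 ... 1.000; values are clipped below at zero.  Standardized
    samples outside [-0.5, 1.5] indicate a corrupt event and raise.
    """
    x = trace.samples[event.start : event.end]
    if x.size < 5:
        raise ValueError("event too short for density features (need >= 5 samples)")
    z = x / baseline.I0
    if np.any(z < -0.5) or np.any(z > 1.5):
        raise ValueError("standardized samples outside [-0.5, 1.5]: corrupt event")
    return kde_density_on_grid(z, bandwidth=bandwidth)


def kde_density_on_grid(z: np.ndarray, bandwidth: float | None = None) -> np.ndarray:
    """Gaussian KDE of standardized amplitudes on the fixed 1,000-point grid.

    Silverman's rule sets the bandwidth unless one is given; a
    near-degenerate sample falls back to a narrow fixed bandwidth so the
    density is a sharp peak at the sample value.
    """
    z = np.asarray(z, dtype=np.float64)
    if bandwidth is None:
        sd = float(np.std(z, ddof=1))
        iqr = float(np.subtract(*np.percentile(z, [75, 25])))
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        if spread <= 1e-9:
            bandwidth = 5e-4  # near-degenerate sample: narrow peak at the value
        else:
            bandwidth = 0.9 * spread * z.size ** (-0.2)
    # evaluate in blocks to bound the 1000 x n working set
    dens = np.zeros(DENSITY_GRID.size)
    block = 50_000
    for a in range(0, z.size, block):
        zz = z[a : a + block]
        diff = (DENSITY_GRID[:, None] - zz[None, :]) / bandwidth
        dens += np.exp(-0.5 * diff * diff).sum(axis=1)
    dens /= z.size * bandwidth * np.sqrt(2 * np.pi)
    return np.clip(dens, 0.0, None)


def characterize_dwell(dwells_ms: np.ndarray) -> tuple[float, float]:
    """Half-life (ms) of the exponential dwell-time distribution, with s.e.

    Fits the exponential decay ``S(t) = exp(-t ln2 / t_half)`` to the
    empirical survival function of the dwell times.  Requires at least 30
    events; a degenerate sample (zero spread) raises.
    """
    d = np.sort(np.asarray(dwells_ms, dtype=np.float64))
    if d.size < 30:
        raise ValueError("need >= 30 events to characterize dwell")
    if np.ptp(d) <= 0:
        raise ValueError("degenerate dwell sample: all values equal")
    surv = 1.0 - (np.arange(1, d.size + 1) - 0.5) / d.size

    def model(t, t_half):
        return np.exp(-t * LN2 / t_half)

    p0 = max(float(np.mean(d)) * LN2, 1e-9)
    try:
        popt, pcov = curve_fit(model, d, surv, p0=[p0], maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - defensive
        raise RuntimeError("exponential dwell fit failed") from exc
    t_half = float(popt[0])
    se_fit = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan
    # sampling s.e. of an exponential scale estimate dominates the curve-fit
    # residual s.e.; report the larger of the two
    se = max(se_fit if np.isfinite(se_fit) else 0.0, t_half / np.sqrt(d.size))
    if t_half <= 0 or not np.isfinite(t_half):
        raise RuntimeError("exponential dwell fit failed: non-positive half-life")
    return t_half, se


def fit_blockade_distribution(
    blockades: np.ndarray, bins: int = 50
) -> tuple[float, float, float, dict]:
    """Gaussian fit of the blockade histogram: (mean, sd, se_mean, diagnostics).

    A point mass returns (value, 0, 0); otherwise a Gaussian is fitted to
    the histogram density with the sample moments as the starting point.
    Fit failure raises rather than returning silently wrong numbers.
    """
    b = np.asarray(blockades, dtype=np.float64)
    if b.size < 30:
        raise ValueError("need >= 30 events to fit the blockade distribution")
    m0, s0 = float(np.mean(b)), float(np.std(b, ddof=1))
    if s0 <= 1e-9 * max(abs(m0), 1.0):
        return m0, 0.0, 0.0, {"method": "point_mass", "n": int(b.size)}
    hist, edges = np.histogram(b, bins=bins, density=True)
    centers = (edges[:-1] + edges[1:]) / 2

    def gauss(x, mu, sigma, amp):
        return amp / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

    try:
        popt, pcov = curve_fit(
            gauss, centers, hist, p0=[m0, s0, 1.0], maxfev=10000
        )
    except RuntimeError as exc:
        raise RuntimeError("Gaussian blockade fit failed") from exc
    mu, sigma = float(popt[0]), abs(float(popt[1]))
    if not np.isfinite(mu) or sigma <= 0:
        raise RuntimeError("Gaussian blockade fit failed: degenerate solution")
    se_mean = sigma / np.sqrt(b.size)
    diag = {
        "method": "histogram_gauss",
        "n": int(b.size),
        "amp": float(popt[2]),
        "cov": pcov.tolist(),
        "sample_mean": m0,
        "sample_sd": s0,
    }
    return mu, sigma, se_mean, diag


def detect_events(
    trace: CurrentTrace,
    penalty: float | None = None,
    min_blockade: float = 0.1,
    min_dwell_ms: float = 0.5,
    with_features: bool = True,
    min_size: int = 5,
    experiment_id: str = "",
) -> tuple[list[Event], BaselineEstimate, SegmentedTrace]:
    """Full detection chain: segment, polish, baseline, extract, featurize."""
    cps = detect_change_points(trace, penalty=penalty, min_size=min_size)
    segmented = polish_trace(trace, cps)
    baseline = estimate_baseline(segmented)
    events = extract_events(
        segmented, baseline, min_blockade=min_blockade, min_dwell_ms=min_dwell_ms
    )
    kept: list[Event] = []
    for ev in events:
        ev.experiment_id = experiment_id
        x = trace.samples[ev.start : ev.end]
        ev.level_sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        if with_features:
            if x.size < 5:
                continue  # too short to featurize; drop from the feature table
            try:
                ev.density_features = compute_density_features(ev, trace, baseline)
            except ValueError:
                continue
        kept.append(ev)
    return kept, baseline, segmented


def events_to_frame(
    events: Sequence[Event], sampling_rate: float, label: str | None = None
) -> pd.DataFrame:
    """Tabulate events (one row each) with the X0001...X1000 feature columns."""
    rows = {
        "experiment_id": [e.experiment_id for e in events],
        "start": [e.start for e in events],
        "end": [e.end for e in events],
        "onset_s": [e.start / sampling_rate for e in events],
        "dwell_ms": [e.dwell_ms for e in events],
        "mean_level": [e.mean_level for e in events],
        "blockade": [e.blockade for e in events],
        "level_sd": [e.level_sd for e in events],
        "n_sublevels": [e.n_sublevels for e in events],
    }
    df = pd.DataFrame(rows)
    if label is not None:
        df["label"] = label
    feats = [e.density_features for e in events]
    if events and all(f is not None for f in feats):
        fm = pd.DataFrame(np.vstack(feats), columns=FEATURE_NAMES, index=df.index)
        df = pd.concat([df, fm], axis=1)
    return df
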