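"""Synthetic single-channel trace and experiment generator.

Emulates the statistical structure of copper(II)-MspA amino-acid sensing
recordings: a stable state-0 baseline (copper-bound pore) with Gaussian
noise, reversible excursions to the open-pore level I* whenever a copper
ion dissociates, amino-acid binding events whose depth is a per-class
Gaussian blockade, exponential dwell times, Poisson capture kinetics
proportional to concentration, occasional two-level (state-2) events, and
sparse flat-density artifacts in blank controls.

Every generated trace carries a ground-truth :class:`EventLog` so that the
downstream detector, filter, classifier and quantifier can all be tested
against known truth.  All randomness flows from a single integer seed;
identical configuration and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .params import (
    DEFAULT_PARAMS,
    STOP_RESIDUES_CPA1,
    AminoAcidParams,
    get_params,
    residue_class,
)
from .signals import CurrentTrace

__all__ = [
    "TraceConfig",
    "PeptideSpec",
    "SimulationError",
    "EVENT_LOG_COLUMNS",
    "simulate_trace",
    "simulate_blank",
    "simulate_hydrolysis",
    "simulate_experiment_set",
    "ConcentrationSeriesSpec",
    "MixtureSpec",
    "HydrolysateSpec",
    "Experiment",
]

LN2 = float(np.log(2.0))

#: Schema of the ground-truth event log emitted next to every trace.
EVENT_LOG_COLUMNS = ["label", "onset_s", "dwell_ms", "level_pA", "is_state2"]


class SimulationError(RuntimeError):
    """Raised when a simulation request is physically unrealisable."""


@dataclass(frozen=True)
class TraceConfig:
    """Recording-level configuration of a simulated trace.

    Defaults follow a typical recording setup: 100 kHz digitisation, a
    ~100 pA copper-bound baseline at +50 mV, and a copper occupancy of
    87.8% of the measurement time.  ``fast()`` returns a reduced-rate
    configuration (2 kHz, the analogue-filter bandwidth) for quick runs.
    """

    sampling_rate: float = 100_000.0  # Hz
    baseline_current: float = 100.0  # pA, state-0 level I0
    noise_sd: float = 1.0  # pA
    duration: float = 60.0  # s
    copper_occupancy: float = 0.878  # fraction of time at state 0
    copper_excursion_level: float = 110.0  # pA, open-pore level I*
    excursion_mean_ms: float = 50.0  # mean open-pore residence
    state2_prob: float = 0.05  # chance an event carries a 2nd sub-level
    state2_extra_blockade: float = 0.08
    bessel_smoother: bool = False  # optional moving-average low-pass
    bessel_cutoff_hz: float = 2000.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.copper_occupancy <= 1.0:
            raise ValueError("copper_occupancy must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @classmethod
    def fast(cls, **kwargs) -> "TraceConfig":
        """Reduced-rate configuration for fast tests (2 kHz sampling)."""
        kwargs.setdefault("sampling_rate", 2000.0)
        return cls(**kwargs)

    def with_seed(self, seed: int) -> "TraceConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide plus the exopeptidase digestion applied to it."""

    sequence: str  # one-letter, N -> C
    enzyme: str = "carboxypeptidase_a1"  # or "leucyl_aminopeptidase"
    cleavage_rate: float = 1.0  # min^-1 per exposed terminal residue
    digestion_time: float = 1.0  # minutes
    stop_residues: frozenset[str] | None = None  # None -> enzyme default

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        for r in self.sequence:
            residue_class(r)  # validates alphabet
        if self.enzyme not in ("carboxypeptidase_a1", "leucyl_aminopeptidase"):
            raise ValueError(f"unknown enzyme {self.enzyme!r}")

    @property
    def terminus(self) -> str:
        return "C" if self.enzyme == "carboxypeptidase_a1" else "N"

    def effective_stop_residues(self) -> frozenset[str]:
        if self.stop_residues is not None:
            return self.stop_residues
        if self.enzyme == "carboxypeptidase_a1":
            return STOP_RESIDUES_CPA1
        return frozenset()


def _empty_log() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": pd.Series(dtype=str),
            "onset_s": pd.Series(dtype=float),
            "dwell_ms": pd.Series(dtype=float),
            "level_pA": pd.Series(dtype=float),
            "is_state2": pd.Series(dtype=bool),
        }
    )


def _place_excursions(
    rng: np.random.Generator,
    config: TraceConfig,
    blocked: list[tuple[int, int]],
    n: int,
) -> list[tuple[int, int]]:
    """Alternating two-state copper kinetics, avoiding event intervals.

    Exponential residence times are tuned so that the long-run fraction of
    time at state 0 equals ``copper_occupancy``; excursions that would
    overlap an amino-acid binding event are dropped (events take place at
    the copper-bound baseline by construction).
    """
    c = config.copper_occupancy
    if c >= 1.0:
        return []
    rate = config.sampling_rate
    tau_exc = config.excursion_mean_ms / 1000.0
    tau0 = tau_exc * c / (1.0 - c)
    intervals: list[tuple[int, int]] = []
    t = float(rng.exponential(tau0))
    dur_s = n / rate
    blocked_arr = np.array(blocked, dtype=np.int64).reshape(-1, 2)
    while t < dur_s:
        d = float(rng.exponential(tau_exc))
        a = int(round(t * rate))
        b = min(int(round((t + d) * rate)), n)
        if b > a:
            overlaps = np.any((blocked_arr[:, 0] < b) & (blocked_arr[:, 1] > a))
            if not overlaps:
                intervals.append((a, b))
        t += d + float(rng.exponential(tau0))
    return intervals


def simulate_trace(
    analytes: Sequence[tuple[AminoAcidParams, float]],
    config: TraceConfig,
) -> tuple[CurrentTrace, pd.DataFrame]:
    """Simulate one recording with the given analytes in solution.

    Parameters
    ----------
    analytes:
        ``(params, concentration_uM)`` pairs; an empty sequence gives a
        blank recording (baseline and copper excursions only).
    config:
        Recording configuration; ``config.seed`` fixes all randomness.

    Returns
    -------
    (CurrentTrace, EventLog)
        The sampled trace and the ground-truth log of injected events.

    Notes
    -----
    Event arrivals form a homogeneous Poisson process with per-class rate
    ``capture_rate * concentration`` (per minute).  Arrivals that would
    overlap an already-placed event are rejected and counted; if more than
    half of at least 20 arrivals are rejected the requested rate is judged
    unrealisable and :class:`SimulationError` is raised.
    """
    rng = np.random.default_rng(config.seed)
    rate_hz = config.sampling_rate
    n = int(round(config.duration * rate_hz))
    if n < 2:
        raise ValueError("duration too short for the sampling rate")
    I0 = config.baseline_current

    # --- arrivals ---------------------------------------------------------
    duration_min = config.duration / 60.0
    arrivals: list[tuple[float, str, float, float]] = []  # t, label, dwell_s, blockade
    for p, conc in analytes:
        lam = p.capture_rate * conc * duration_min
        if lam < 0:
            raise ValueError("negative event rate")
        k = rng.poisson(lam)
        ts = rng.uniform(0.0, config.duration, size=k)
        dwell_scale = p.dwell_halflife / LN2 / 1000.0  # s
        dwells = rng.exponential(dwell_scale, size=k)
        blockades = rng.normal(p.blockade_mean, p.blockade_sd, size=k)
        for t, d, b in zip(ts, dwells, blockades):
            arrivals.append((float(t), p.name, float(d), float(b)))
    arrivals.sort(key=lambda a: a[0])

    # --- rejection of overlapping arrivals --------------------------------
    gap = 2  # samples of baseline required between events
    kept: list[tuple[int, int, str, float]] = []  # start, end, label, blockade
    rejected = 0
    prev_end = -gap
    for t, label, d, b in arrivals:
        start = int(round(t * rate_hz))
        end = min(start + max(1, int(round(d * rate_hz))), n)
        if start < prev_end + gap or end >= n or start < 0:
            rejected += 1
            continue
        kept.append((start, end, label, b))
        prev_end = end
    n_arr = len(arrivals)
    if n_arr >= 20 and rejected > 0.5 * n_arr:
        raise SimulationError(
            f"event rate unrealisable: {rejected}/{n_arr} arrivals rejected"
        )

    # --- state-2 sub-levels ----------------------------------------------
    is_state2 = rng.uniform(size=len(kept)) < config.state2_prob

    # --- copper excursions -----------------------------------------------
    blocked = [(s, e) for s, e, _, _ in kept]
    excursions = _place_excursions(rng, config, blocked, n)

    # --- render -----------------------------------------------------------
    if config.noise_sd > 0:
        x = rng.normal(I0, config.noise_sd, size=n)
    else:
        x = np.full(n, I0, dtype=np.float64)
    for a, b in excursions:
        x[a:b] += config.copper_excursion_level - I0
    records = []
    for (start, end, label, blockade), s2 in zip(kept, is_state2):
        level = I0 * (1.0 - blockade)
        x[start:end] += level - I0
        if s2 and end - start >= 9:
            third = (end - start) // 3
            a2, b2 = start + third, start + 2 * third
            deeper = I0 * (1.0 - blockade - config.state2_extra_blockade)
            x[a2:b2] += deeper - level
        records.append(
            {
                "label": label,
                "onset_s": start / rate_hz,
                "dwell_ms": (end - start) / rate_hz * 1000.0,
                "level_pA": level,
                "is_state2": bool(s2),
            }
        )

    if config.bessel_smoother:
        width = max(1, int(round(rate_hz / (2.0 * config.bessel_cutoff_hz))))
        if width > 1:
            kernel = np.ones(width) / width
            x = np.convolve(x, kernel, mode="same")

    meta = {
        "kind": "simulated",
        "seed": config.seed,
        "duration_s": config.duration,
        "baseline_current": I0,
        "n_rejected_arrivals": rejected,
        "analytes": {p.name: conc for p, conc in analytes},
    }
    trace = CurrentTrace(samples=x, sampling_rate=rate_hz, metadata=meta)
    log = pd.DataFrame(records, columns=EVENT_LOG_COLUMNS) if records else _empty_log()
    return trace, log


def simulate_blank(
    config: TraceConfig, artifact_rate: float = 0.0
) -> tuple[CurrentTrace, pd.DataFrame]:
    """Simulate a blank-control recording with sparse background artifacts.

    Artifacts arrive as a Poisson process at ``artifact_rate`` per minute.
    Each artifact is a burst of samples drawn uniformly over a wide
    blockade band (5-35% below baseline), i.e. a broad *flat* amplitude
    density, deliberately unlike the sharply peaked density of a true
    binding event.  Artifacts are logged with label ``"noise"``.
    """
    if artifact_rate < 0:
        raise ValueError("artifact_rate must be >= 0")
    rng = np.random.default_rng(config.seed)
    trace, _ = simulate_trace([], replace(config, seed=config.seed))
    x = trace.samples
    n = x.size
    rate_hz = config.sampling_rate
    I0 = config.baseline_current

    # use an independent stream for artifacts so the baseline matches the
    # analyte-free trace exactly under the same seed
    art_rng = np.random.default_rng(
        None if config.seed is None else (int(config.seed) * 2654435761) % (2**31)
    )
    k = art_rng.poisson(artifact_rate * config.duration / 60.0)
    starts = np.sort(art_rng.uniform(0.0, config.duration, size=k))
    records = []
    for t in starts:
        dur_s = float(art_rng.exponential(5e-3))  # ~5 ms bursts
        a = int(round(t * rate_hz))
        b = min(a + max(2, int(round(dur_s * rate_hz))), n)
        if b <= a:
            continue
        lo, hi = I0 * (1 - 0.35), I0 * (1 - 0.05)
        burst = art_rng.uniform(lo, hi, size=b - a)
        x[a:b] = burst + art_rng.normal(0.0, config.noise_sd, size=b - a)
        records.append(
            {
                "label": "noise",
                "onset_s": a / rate_hz,
                "dwell_ms": (b - a) / rate_hz * 1000.0,
                "level_pA": float(burst.mean()),
                "is_state2": False,
            }
        )
    trace.metadata["kind"] = "blank"
    trace.metadata["artifact_rate"] = artifact_rate
    log = pd.DataFrame(records, columns=EVENT_LOG_COLUMNS) if records else _empty_log()
    return trace, log


def simulate_hydrolysis(peptide: PeptideSpec) -> dict[int, float]:
    """Released fraction of each residue under sequential exopeptidase cleavage.

    Residues are removed one at a time from the enzyme's terminus.  With
    cleavage events Poisson at ``cleavage_rate`` per minute, the m-th
    residue from the start terminus is released in a given molecule iff at
    least m cleavages occurred, so its released fraction is
    ``P(N >= m)`` with ``N ~ Poisson(rate * time)`` — truncated at the
    first stop residue (for carboxypeptidase A1: R, K or P), beyond which
    nothing is ever released.

    Returns
    -------
    dict mapping 0-based position in the (N->C) sequence to released fraction.
    """
    seq = peptide.sequence
    m_total = len(seq)
    stops = peptide.effective_stop_residues()
    # order of exposure, as positions in the written sequence
    if peptide.terminus == "C":
        order = list(range(m_total - 1, -1, -1))
    else:
        order = list(range(m_total))
    mu = peptide.cleavage_rate * peptide.digestion_time
    out: dict[int, float] = {}
    stopped = False
    for m, pos in enumerate(order, start=1):
        if stopped or seq[pos] in stops:
            stopped = True
            out[pos] = 0.0
        else:
            out[pos] = float(stats.poisson.sf(m - 1, mu))  # P(N >= m)
    return out


# ---------------------------------------------------------------------------
# experiment sets


@dataclass(frozen=True)
class ConcentrationSeriesSpec:
    """One class measured at several concentrations (µM)."""

    class_name: str
    concentrations: tuple[float, ...]


@dataclass(frozen=True)
class MixtureSpec:
    """Several classes in one chamber; ``concentrations`` maps name -> µM."""

    concentrations: Mapping[str, float]


@dataclass(frozen=True)
class HydrolysateSpec:
    """A digested peptide added to the chamber at ``peptide_concentration`` µM.

    Per-class rates are proportional to the released amount of each residue
    (from :func:`simulate_hydrolysis`) times that class's capture rate.
    """

    peptide: PeptideSpec
    peptide_concentration: float = 20.0


@dataclass
class Experiment:
    trace: CurrentTrace
    events: pd.DataFrame  # ground-truth EventLog
    metadata: dict = field(default_factory=dict)


def hydrolysate_concentrations(spec: HydrolysateSpec) -> dict[str, float]:
    """Effective free amino-acid concentrations (µM) of a digested peptide."""
    released = simulate_hydrolysis(spec.peptide)
    conc: dict[str, float] = {}
    for pos, frac in released.items():
        cls = residue_class(spec.peptide.sequence[pos])
        conc[cls] = conc.get(cls, 0.0) + frac * spec.peptide_concentration
    return {k: v for k, v in conc.items() if v > 0}


def _child_seeds(seed: int | None, count: int) -> list[int | None]:
    if seed is None:
        return [None] * count
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(count)]


def simulate_experiment_set(
    spec: ConcentrationSeriesSpec | MixtureSpec | HydrolysateSpec,
    config: TraceConfig,
    params_table: Mapping[str, AminoAcidParams] | None = None,
    replicates: int = 1,
) -> list[Experiment]:
    """Simulate a reproducible collection of traces described by ``spec``."""
    table = DEFAULT_PARAMS if params_table is None else params_table

    def analytes_for(conc_map: Mapping[str, float]):
        return [(get_params(name, table), c) for name, c in conc_map.items()]

    runs: list[tuple[dict[str, float], dict]] = []
    if isinstance(spec, ConcentrationSeriesSpec):
        get_params(spec.class_name, table)  # raise early on unknown class
        for c in spec.concentrations:
            runs.append(
                ({spec.class_name: c} if c > 0 else {}, {"concentration_uM": c})
            )
    elif isinstance(spec, MixtureSpec):
        runs.append((dict(spec.concentrations), {"mixture": dict(spec.concentrations)}))
    elif isinstance(spec, HydrolysateSpec):
        conc = hydrolysate_concentrations(spec)
        runs.append(
            (
                conc,
                {
                    "peptide": spec.peptide.sequence,
                    "enzyme": spec.peptide.enzyme,
                    "class_concentrations_uM": conc,
                },
            )
        )
    else:
        raise TypeError(f"unsupported spec {type(spec).__name__}")

    seeds = _child_seeds(config.seed, len(runs) * replicates)
    out: list[Experiment] = []
    i = 0
    for conc_map, meta in runs:
        for rep in range(replicates):
            cfg = replace(config, seed=seeds[i])
            i += 1
            trace, log = simulate_trace(analytes_for(conc_map), cfg)
            m = dict(meta)
            m["replicate"] = rep
            m["seed"] = cfg.seed
            trace.metadata.update(m)
            out.append(Experiment(trace=trace, events=log, metadata=m))
    return out
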