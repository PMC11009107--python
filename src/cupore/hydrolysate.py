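"""Peptide-hydrolysate interpretation from classified events.

Confident calls (max class probability strictly above 0.95 by default) are
counted per amino acid, normalized by each class's capture rate to convert
counts into molar abundances, and correlated against residue position to
recover the hallmark of sequential exopeptidase digestion: residues closer
to the cleavage terminus are released earlier and are therefore more
abundant in a partial hydrolysate.  Pooled amplitude-density profiles of
whole peptides feed a Euclidean distance matrix and classical MDS for
unsupervised peptide comparison.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .params import AminoAcidParams, residue_class
from .signals import BaselineEstimate, CurrentTrace, Event, kde_density_on_grid

__all__ = [
    "AbundanceProfile",
    "PeptideProfile",
    "confident_calls",
    "normalize_abundance",
    "positional_trend",
    "peptide_profile",
    "peptide_distance_matrix",
    "classical_mds",
]


@dataclass
class AbundanceProfile:
    """Capture-rate-normalized composition of a hydrolysate (percent)."""

    percent: dict[str, float]
    counts: dict[str, int]
    capture_rates: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.percent.values())
        if self.percent and abs(total - 100.0) > 1e-6:
            raise ValueError(f"abundances must sum to 100, got {total}")


@dataclass
class PeptideProfile:
    """Pooled 1,000-point amplitude-density profile of one peptide."""

    peptide_id: str
    density: np.ndarray
    n_events: int

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=np.float64)
        if self.density.shape != (1000,):
            raise ValueError("profile density must have exactly 1,000 entries")
        if np.any(self.density < 0):
            raise ValueError("profile density must be non-negative")


def confident_calls(predictions: pd.DataFrame, p_min: float = 0.95) -> pd.Series:
    """Per-class counts of calls whose max probability strictly exceeds p_min."""
    if "p_max" not in predictions.columns or "call" not in predictions.columns:
        raise ValueError("predictions need 'call' and 'p_max' columns")
    keep = predictions["p_max"] > p_min
    return predictions.loc[keep, "call"].value_counts().sort_index()


def normalize_abundance(
    counts: Mapping[str, int] | pd.Series,
    params_table: Mapping[str, AminoAcidParams],
) -> AbundanceProfile:
    """Convert per-class call counts into molar abundance percentages.

    Each count is divided by its class's capture rate (events per minute
    per µM) and the quotients are standardized to percentages:
    ``abundance_i = (count_i / rate_i) / sum_j (count_j / rate_j) * 100``.
    """
    counts = dict(counts)
    if not counts:
        raise ValueError("no counts to normalize")
    rates = {}
    weighted = {}
    for cls, cnt in counts.items():
        p = params_table.get(cls)
        if p is None:
            raise KeyError(f"no parameters for class {cls!r}")
        if p.capture_rate <= 0:
            raise ValueError(f"class {cls!r} has non-positive capture rate")
        rates[cls] = p.capture_rate
        weighted[cls] = cnt / p.capture_rate
    total = sum(weighted.values())
    if total <= 0:
        raise ValueError("all counts are zero")
    percent = {cls: w / total * 100.0 for cls, w in weighted.items()}
    return AbundanceProfile(
        percent=percent, counts={k: int(v) for k, v in counts.items()}, capture_rates=rates
    )


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value of Spearman's rho (small n)."""
    n = x.size
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = stats.spearmanr(x, y[list(perm)]).statistic
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def positional_trend(
    sequence: str,
    terminus: str,
    profile: AbundanceProfile,
    exclude_stop_residues: frozenset[str] | None = None,
) -> tuple[float, float]:
    """Spearman correlation of abundance with proximity to the cleavage terminus.

    Positive rho means residues nearer the ``terminus`` ("C" or "N") are
    more abundant — the signature of a partial digestion that started
    there.  The reference ``sequence`` supplies the positional axis and
    need not be the digested peptide itself, which allows two hydrolysates
    of the same composition to be compared on a common axis.  Repeated
    residues share their class abundance at every occurrence; stop
    residues (default R/K/P for the C terminus) are excluded from the
    axis.  The p-value is an exact permutation test for up to 8 positions
    and the asymptotic approximation beyond.
    """
    if terminus not in ("C", "N"):
        raise ValueError("terminus must be 'C' or 'N'")
    if exclude_stop_residues is None:
        exclude_stop_residues = frozenset({"R", "K", "P"}) if terminus == "C" else frozenset()
    n = len(sequence)
    proximity: list[float] = []
    abundance: list[float] = []
    for pos, res in enumerate(sequence):
        if res in exclude_stop_residues:
            continue
        cls = residue_class(res)
        if cls not in profile.percent:
            continue
        dist = (n - pos) if terminus == "C" else (pos + 1)
        proximity.append(-float(dist))  # larger = nearer the terminus
        abundance.append(profile.percent[cls])
    if len(proximity) < 3:
        raise ValueError("need at least 3 mapped positions for a trend")
    x = np.asarray(proximity)
    y = np.asarray(abundance)
    if np.ptp(y) == 0:
        raise ValueError("constant abundances: rank correlation undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    if x.size <= 8:
        p = _exact_spearman_p(x, y, rho)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def peptide_profile(
    events: Sequence[Event],
    trace: CurrentTrace,
    baseline: BaselineEstimate,
    peptide_id: str = "",
) -> PeptideProfile:
    """Pooled density profile of all of one peptide's signals.

    All raw in-event samples, standardized by I0, are pooled and smoothed
    into one density on the fixed 1,000-point grid.  Requires >= 30 events.
    """
    if len(events) < 30:
        raise ValueError("need >= 30 events for a peptide profile")
    z = np.concatenate(
        [trace.samples[e.start : e.end] for e in events]
    ) / baseline.I0
    dens = kde_density_on_grid(z)
    return PeptideProfile(peptide_id=peptide_id, density=dens, n_events=len(events))


def peptide_distance_matrix(profiles: Sequence[PeptideProfile]) -> pd.DataFrame:
    """Pairwise Euclidean distances between peptide density profiles."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    X = np.vstack([p.density for p in profiles])
    ids = [p.peptide_id for p in profiles]
    D = squareform(pdist(X, metric="euclidean"))
    return pd.DataFrame(D, index=ids, columns=ids)


def classical_mds(distances: pd.DataFrame | np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centers the squared distances into a Gram matrix, takes its top
    ``dims`` positive eigenpairs and returns coordinates whose pairwise
    distances reproduce the input exactly whenever the matrix is
    Euclidean-embeddable in at most ``dims`` dimensions.  Warns when the
    negative part of the spectrum exceeds 5% of its total mass (the input
    is then far from Euclidean).
    """
    D = np.asarray(distances, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10) or np.any(np.diag(D) > 1e-10):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    neg_mass = float(np.abs(evals[evals < 0]).sum())
    tot_mass = float(np.abs(evals).sum())
    if tot_mass > 0 and neg_mass / tot_mass > 0.05:
        warnings.warn(
            f"negative eigenvalue mass {neg_mass / tot_mass:.1%} > 5%: "
            "distances are far from Euclidean",
            stacklevel=2,
        )
    coords = np.zeros((n, dims))
    for d in range(min(dims, n)):
        if evals[d] > 0:
            coords[:, d] = evecs[:, d] * np.sqrt(evals[d])
    return coords
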