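"""Background-noise rejection by k-nearest-neighbour comparison with blanks.

Candidate events that resemble the artifacts of a blank-control recording
are removed: signals are pooled with an equally sized random subsample of
blank events, Euclidean distances are computed on the z-scored feature
vector (1,000 density features + blockade + dwell + s.d.), and any signal
with at least one blank among its k nearest pool neighbours is discarded.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .signals import FEATURE_NAMES

__all__ = ["knn_background_filter", "KNN_FEATURES"]

#: Feature columns entering the distance computation.
KNN_FEATURES = ["blockade", "dwell_ms", "level_sd", *FEATURE_NAMES]


def knn_background_filter(
    signals: pd.DataFrame,
    blanks: pd.DataFrame,
    k: int = 10,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Remove signals whose k nearest neighbours include a blank event.

    Parameters
    ----------
    signals, blanks:
        Event tables with the full feature columns (see
        :data:`KNN_FEATURES`).  ``blanks`` must be non-empty.
    k:
        Neighbourhood size; a signal is removed when any of its ``k``
        nearest pool neighbours (itself excluded; ties broken by pool
        index) is a blank.
    seed:
        Seeds the random blank subsample, which has size ``len(signals)``
        (drawn with replacement, with a warning, when fewer blanks exist).

    Returns
    -------
    (retained, report)
        The surviving rows of ``signals`` and a report with counts, the
        blank subsample indices and each signal's nearest-blank distance.
    """
    if len(signals) == 0:
        raise ValueError("signals table is empty")
    if len(blanks) == 0:
        raise ValueError("blanks table is empty — need a blank control")
    if k < 1:
        raise ValueError("k must be >= 1")
    missing = [c for c in KNN_FEATURES if c not in signals.columns]
    if missing:
        raise ValueError(f"signals table lacks feature columns: {missing[:3]}...")

    rng = np.random.default_rng(seed)
    n_sig = len(signals)
    replace = len(blanks) < n_sig
    if replace:
        warnings.warn(
            f"only {len(blanks)} blanks for {n_sig} signals; sampling with replacement",
            stacklevel=2,
        )
    pick = rng.choice(len(blanks), size=n_sig, replace=replace)
    blank_sub = blanks.iloc[pick]

    sig_f = signals[KNN_FEATURES].to_numpy(dtype=np.float64)
    bl_f = blank_sub[KNN_FEATURES].to_numpy(dtype=np.float64)
    pool = np.vstack([sig_f, bl_f])

    mu = pool.mean(axis=0)
    sd = pool.std(axis=0)
    sd[sd == 0] = 1.0  # constant features carry no distance information
    pool_z = (pool - mu) / sd
    sig_z = pool_z[:n_sig]

    # pairwise squared distances signal x pool; ties resolved by pool index
    d2 = (
        (sig_z * sig_z).sum(axis=1)[:, None]
        - 2.0 * sig_z @ pool_z.T
        + (pool_z * pool_z).sum(axis=1)[None, :]
    )
    np.fill_diagonal(d2[:, :n_sig], np.inf)  # self is never a neighbour
    kk = min(k, pool_z.shape[0] - 1)
    order = np.argsort(d2, axis=1, kind="stable")[:, :kk]
    has_blank = (order >= n_sig).any(axis=1)

    blank_d2 = d2[:, n_sig:]
    nearest_blank = np.sqrt(np.maximum(blank_d2.min(axis=1), 0.0))
    retained = signals.loc[~has_blank]
    report = {
        "n_signals": int(n_sig),
        "n_removed": int(has_blank.sum()),
        "n_retained": int(len(retained)),
        "k": int(k),
        "seed": seed,
        "blank_subsample": pick.tolist(),
        "upsampled_blanks": bool(replace),
        "nearest_blank_distance": nearest_blank.tolist(),
    }
    return retained, report
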