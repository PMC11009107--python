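"""Text-first readers and writers for traces, event tables and parameters.

Traces are two-column delimited text (``time_s``, ``current_pA``) with a
JSON sidecar holding the sampling rate and free-form metadata; a
single-column variant (current only) is accepted when the sidecar states
the rate.  Event tables and ground-truth logs are TSV with headers, and
parameter tables are JSON.  Gzip compression is transparent via the
``.gz`` suffix.  Numeric round-trips are lossless (floats are written with
``repr`` precision).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .params import AminoAcidParams
from .signals import CurrentTrace

__all__ = [
    "write_trace",
    "read_trace",
    "iter_trace_chunks",
    "write_events",
    "read_events",
    "write_params",
    "read_params",
    "sidecar_path",
]


def sidecar_path(path) -> Path:
    """JSON sidecar next to a trace file (``trace.tsv`` -> ``trace.json``)."""
    p = Path(path)
    name = p.name
    for suf in (".gz",):
        if name.endswith(suf):
            name = name[: -len(suf)]
    stem = name.rsplit(".", 1)[0] if "." in name else name
    return p.with_name(stem + ".json")


def write_trace(trace: CurrentTrace, path, include_time: bool = True) -> None:
    path = Path(path)
    t = np.arange(trace.samples.size) / trace.sampling_rate
    if include_time:
        df = pd.DataFrame({"time_s": t, "current_pA": trace.samples})
    else:
        df = pd.DataFrame({"current_pA": trace.samples})
    df.to_csv(path, sep="\t", index=False)
    meta = {
        "sampling_rate": trace.sampling_rate,
        "n_samples": int(trace.samples.size),
        "columns": list(df.columns),
        "metadata": _jsonable(trace.metadata),
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2))


def iter_trace_chunks(path, chunksize: int = 1_000_000) -> Iterator[np.ndarray]:
    """Stream current samples in bounded chunks (never the whole text at once)."""
    path = Path(path)
    for chunk in pd.read_csv(
        path, sep="\t", chunksize=chunksize, float_precision="round_trip"
    ):
        if "current_pA" not in chunk.columns:
            raise ValueError("trace file lacks required column 'current_pA'")
        vals = pd.to_numeric(chunk["current_pA"], errors="coerce").to_numpy()
        if np.any(~np.isfinite(vals)):
            raise ValueError("non-numeric or missing current samples in trace file")
        yield vals


def read_trace(path, chunksize: int = 1_000_000) -> CurrentTrace:
    path = Path(path)
    sp = sidecar_path(path)
    if not sp.exists():
        raise FileNotFoundError(f"missing trace sidecar {sp}")
    meta = json.loads(sp.read_text())
    rate = float(meta["sampling_rate"])
    parts = list(iter_trace_chunks(path, chunksize=chunksize))
    samples = np.concatenate(parts) if parts else np.empty(0)
    n_expected = meta.get("n_samples")
    if n_expected is not None and samples.size != int(n_expected):
        raise ValueError(
            f"trace length {samples.size} != sidecar n_samples {n_expected}"
        )
    return CurrentTrace(
        samples=samples, sampling_rate=rate, metadata=meta.get("metadata", {})
    )


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(Path(path), sep="\t", index=False)


def read_events(path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t", float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"event table lacks required columns: {missing}")
    return df


def write_params(table: Mapping[str, AminoAcidParams], path) -> None:
    payload = {name: p.to_dict() for name, p in table.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_params(path) -> dict[str, AminoAcidParams]:
    payload = json.loads(Path(path).read_text())
    out = {}
    for name, d in payload.items():
        d = dict(d)
        d.pop("name", None)
        out[name] = AminoAcidParams(name=name, **d)
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
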