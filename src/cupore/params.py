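"""Per-class generative parameters for amino-acid binding events.

Each sensed class (an amino acid, a PTM variant such as phosphoserine, or a
distinct binding mode such as the long-lived His1 population of histidine)
is summarised by four numbers: the mean and standard deviation of its
fractional current blockade, the half-life of its exponentially distributed
dwell time, and its capture rate per unit concentration.  These parameters
drive the trace simulator and are also the normaliser used when converting
event counts into molar abundances of a hydrolysate.

Only a handful of entries in the packaged default table are calibrated
against published single-channel measurements (serine, phosphoserine,
lysine, acetyl-lysine blockades and the His1 dwell half-life); every other
entry is a synthetic placeholder spread over the empirically plausible
blockade range (~0.10-0.36) and is flagged as such via ``calibrated=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Mapping

__all__ = [
    "AminoAcidParams",
    "DEFAULT_PARAMS",
    "get_params",
    "residue_class",
    "STOP_RESIDUES_CPA1",
]


@dataclass(frozen=True)
class AminoAcidParams:
    """Generative parameters for one sensed class.

    Parameters
    ----------
    name:
        One-letter residue code or tag (``"S"``, ``"P-S"``, ``"His1"``).
    blockade_mean:
        Mean fractional blockade (I0 - I1)/I0, dimensionless, in (0, 1).
    blockade_sd:
        Between-event standard deviation of the blockade.
    dwell_halflife:
        Half-life of the exponential dwell-time distribution, milliseconds.
    capture_rate:
        Events per minute per micromolar of analyte.
    calibrated:
        True when the value derives from a published measurement; False for
        synthetic placeholder values.
    """

    name: str
    blockade_mean: float
    blockade_sd: float
    dwell_halflife: float
    capture_rate: float
    calibrated: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.blockade_mean < 1.0:
            raise ValueError(f"{self.name}: blockade_mean must lie in (0, 1)")
        if self.blockade_sd <= 0:
            raise ValueError(f"{self.name}: blockade_sd must be positive")
        if self.dwell_halflife <= 0:
            raise ValueError(f"{self.name}: dwell_halflife must be positive")
        if self.capture_rate < 0:
            raise ValueError(f"{self.name}: capture_rate must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def _table(rows: Iterable[tuple]) -> dict[str, AminoAcidParams]:
    out = {}
    for name, bmean, bsd, hl, rate, calib in rows:
        out[name] = AminoAcidParams(name, bmean, bsd, hl, rate, calib)
    return out


# name, blockade_mean, blockade_sd, dwell_halflife_ms, capture_rate, calibrated
# Calibrated rows: S, P-S, K, Ac-K blockades and the His1 dwell half-life.
# All other numbers are synthetic, spaced over the plausible blockade range;
# capture rates loosely follow the observation that polar side chains are
# captured more often than non-polar ones and proline is rarest.
DEFAULT_PARAMS: dict[str, AminoAcidParams] = _table(
    [
        ("G", 0.104, 0.0045, 2.0, 1.20, False),
        ("A", 0.115, 0.0042, 2.5, 0.90, False),
        ("S", 0.132, 0.0033, 3.5, 1.00, True),
        ("C", 0.143, 0.0048, 2.2, 0.50, False),
        ("T", 0.153, 0.0045, 3.0, 0.80, False),
        ("V", 0.163, 0.0050, 2.8, 0.55, False),
        ("K", 0.171, 0.0026, 4.0, 0.70, True),
        ("D", 0.181, 0.0047, 3.2, 1.10, False),
        ("N", 0.192, 0.0052, 3.6, 0.95, False),
        ("L", 0.203, 0.0048, 4.2, 0.85, False),
        ("P", 0.214, 0.0055, 1.5, 0.05, False),
        ("I", 0.224, 0.0055, 3.8, 0.60, False),
        ("Ac-K", 0.233, 0.0071, 4.5, 0.55, True),
        ("Q", 0.243, 0.0050, 4.0, 0.75, False),
        ("E", 0.253, 0.0053, 4.4, 1.05, False),
        ("M", 0.263, 0.0058, 5.0, 0.60, False),
        ("Y", 0.274, 0.0060, 5.4, 0.65, False),
        ("CMC", 0.285, 0.0068, 4.8, 0.50, False),
        ("P-S", 0.295, 0.0093, 5.5, 0.45, True),
        ("His1", 0.306, 0.0060, 42.7, 0.40, True),
        ("F", 0.316, 0.0062, 5.2, 0.70, False),
        ("His2", 0.326, 0.0065, 8.0, 0.15, False),
        ("R", 0.336, 0.0057, 6.0, 0.35, False),
        ("W", 0.347, 0.0065, 6.5, 0.50, False),
    ]
)

#: Residues that carboxypeptidase A1 cannot release; hydrolysis halts
#: permanently once one of them becomes C-terminal.
STOP_RESIDUES_CPA1 = frozenset({"R", "K", "P"})


def residue_class(residue: str) -> str:
    """Map a one-letter residue code to its default sensed class.

    Histidine is represented by its dominant long-lived binding population
    (``His1``); all other residues map to themselves.
    """
    if len(residue) != 1 or residue not in "ACDEFGHIKLMNPQRSTVWY":
        raise ValueError(f"unknown residue {residue!r}")
    return "His1" if residue == "H" else residue


def get_params(
    name: str, table: Mapping[str, AminoAcidParams] | None = None
) -> AminoAcidParams:
    """Look up one class in a parameter table (default: packaged table)."""
    table = DEFAULT_PARAMS if table is None else table
    try:
        return table[name]
    except KeyError:
        raise KeyError(f"no parameters for class {name!r}") from None
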