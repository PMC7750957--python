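"""Flexibility, SWI, GRAVY and solubility-probability scoring.

The Solubility-Weighted Index (SWI) of a sequence is the arithmetic mean of
per-residue weights W_i,

    SWI = <W_i>,

a purely composition-based score.  Structural flexibility is modeled from
normalized crystallographic B-factors B_i, either through the classical
9-residue sliding window

    f_i = [B_i + 0.8125 (B_{i-1}+B_{i+1}) + 0.625 (B_{i-2}+B_{i+2})
               + 0.4375 (B_{i-3}+B_{i+3}) + 0.25 (B_{i-4}+B_{i+4})] / 5.25

with global flexibility F = <f_i>, or through the simplified form
F' = <B_i> (the plain mean; the window coefficients sum to the divisor, so
each f_i is a convex combination of B values and F' tracks F closely).

Probability of solubility maps SWI through a logistic calibration
p = 1 / (1 + exp(-(a·SWI + b))); the published calibration fitted on
12 216 E. coli expression outcomes is a = 81.05812, b = -62.7775.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.special import expit

from .scales import ResidueScale, get_scale
from .seqio import SequenceRecord

#: Sliding-window half-width: profiles cover positions 5 .. L-4 (1-based).
WINDOW_SIZE = 9
#: Symmetric window coefficients for offsets -4 .. +4; they sum to 5.25,
#: which is also the divisor.
WINDOW_COEFFS = np.array(
    [0.25, 0.4375, 0.625, 0.8125, 1.0, 0.8125, 0.625, 0.4375, 0.25]
)
WINDOW_DIVISOR = 5.25


@dataclass(frozen=True)
class LogisticCalibration:
    """Slope/intercept of the SWI -> probability logistic link."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise ValueError("calibration parameters must be finite")

    @property
    def midpoint(self) -> float:
        """The SWI value at which the probability is exactly 0.5."""
        return -self.b / self.a


#: Calibration fitted on the PSI:Biology binary solubility outcomes.
PUBLISHED_CALIBRATION = LogisticCalibration(a=81.05812, b=-62.7775)


@dataclass(frozen=True)
class FlexibilityProfile:
    """Per-position windowed flexibility values f_i.

    ``start_position`` is the 1-based index of the first scored residue
    (5 for any sequence long enough to score).
    """

    sequence_id: str
    start_position: int
    values: tuple[float, ...]


@dataclass(frozen=True)
class SolubilityReport:
    """Scores for a sequence or a region of it (1-based inclusive)."""

    sequence_id: str
    start: int
    end: int
    swi: float
    probability: float
    global_flexibility: float  # windowed F; NaN when the region is < 9 residues
    simplified_flexibility: float  # F' = mean B
    gravy: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _values(residues: str, scale: ResidueScale) -> np.ndarray:
    try:
        return np.array([scale.values[aa] for aa in residues])
    except KeyError as exc:
        raise KeyError(
            f"residue {exc.args[0]!r} is not covered by scale {scale.name!r}"
        ) from None


def _mean(values: Sequence[float]) -> float:
    # fsum keeps long-sequence means exactly rounded, independent of order
    return math.fsum(values) / len(values)


def local_flexibility_profile(
    residues: str | SequenceRecord, scale: ResidueScale
) -> FlexibilityProfile:
    """Windowed flexibility profile f_i for positions with 4 flanking residues.

    Only fully covered windows are scored (positions 5 .. L-4, 1-based);
    no mirrored or truncated edge windows.
    """
    seq_id, residues = _as_pair(residues)
    if len(residues) < WINDOW_SIZE:
        raise ValueError(
            f"sequence must have at least {WINDOW_SIZE} residues for a "
            f"windowed flexibility profile (got {len(residues)})"
        )
    b = _values(residues, scale)
    prof = np.convolve(b, WINDOW_COEFFS, mode="valid") / WINDOW_DIVISOR
    return FlexibilityProfile(seq_id, start_position=5, values=tuple(prof.tolist()))


def global_flexibility(
    residues: str | SequenceRecord,
    scale: ResidueScale,
    method: Literal["window", "mean"] = "window",
) -> float:
    """Global flexibility: F = <f_i> ("window") or F' = <B_i> ("mean")."""
    _, seq = _as_pair(residues)
    if method == "window":
        return _mean(local_flexibility_profile(residues, scale).values)
    if method == "mean":
        if not seq:
            raise ValueError("empty sequence")
        return _mean(_values(seq, scale).tolist())
    raise ValueError(f"unknown method {method!r}; expected 'window' or 'mean'")


def swi(residues: str | SequenceRecord, weights: ResidueScale) -> float:
    """Solubility-Weighted Index: the mean residue weight of the sequence."""
    _, seq = _as_pair(residues)
    if not seq:
        raise ValueError("empty sequence")
    return _mean(_values(seq, weights).tolist())


def gravy(residues: str | SequenceRecord) -> float:
    """Grand Average of Hydropathy (mean Kyte–Doolittle value)."""
    return swi(residues, get_scale("kyte_doolittle"))


def probability_of_solubility(
    swi_value: float, calibration: LogisticCalibration = PUBLISHED_CALIBRATION
) -> float:
    """Logistic probability 1 / (1 + exp(-(a·x + b))).

    Numerically stable: saturates to 0 or 1 instead of overflowing.
    """
    return float(expit(calibration.a * swi_value + calibration.b))


def score_sequence(
    record: SequenceRecord | str,
    weights: ResidueScale | None = None,
    calibration: LogisticCalibration = PUBLISHED_CALIBRATION,
    flexibility_scale: ResidueScale | None = None,
) -> SolubilityReport:
    """Full solubility report for a whole sequence.

    ``weights`` defaults to the final SWI weights; ``flexibility_scale``
    (for F and F') defaults to the Vihinen et al. normalized B-factors used
    by the standard sliding-window flexibility implementation.
    """
    seq_id, seq = _as_pair(record)
    weights = weights or get_scale("swi_final")
    flex = flexibility_scale or get_scale("vihinen1994")
    x = swi(seq, weights)
    return SolubilityReport(
        sequence_id=seq_id,
        start=1,
        end=len(seq),
        swi=x,
        probability=probability_of_solubility(x, calibration),
        global_flexibility=(
            global_flexibility(seq, flex, "window") if len(seq) >= WINDOW_SIZE else math.nan
        ),
        simplified_flexibility=global_flexibility(seq, flex, "mean"),
        gravy=gravy(seq),
    )


def _as_pair(record: SequenceRecord | str) -> tuple[str, str]:
    if isinstance(record, SequenceRecord):
        return record.id, record.residues
    return "seq", record
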