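"""Region-level solubility analysis and construct design.

Scores arbitrary sub-sequences, searches for boundary extensions of a seed
region that maximize the probability of solubility (simulated annealing,
with a small exhaustive-search oracle for short sequences), and predicts
the effect of fusing a solubility tag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

from .scales import ResidueScale, get_scale
from .scoring import (
    PUBLISHED_CALIBRATION,
    LogisticCalibration,
    SolubilityReport,
    score_sequence,
)
from .seqio import SequenceRecord


@dataclass(frozen=True)
class Region:
    """A scored sub-sequence; ``start``/``end`` are 1-based inclusive."""

    start: int
    end: int
    report: SolubilityReport

    @property
    def probability(self) -> float:
        return self.report.probability

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AnnealConfig:
    """Simulated-annealing schedule for region boundary search.

    Geometric cooling from ``t_initial`` by ``cooling`` per temperature
    level, ``steps_per_temp`` proposals per level, stopping below
    ``t_min``; each move displaces a boundary by at most
    ``max_displacement`` residues.
    """

    t_initial: float = 1.0
    cooling: float = 0.95
    steps_per_temp: int = 50
    t_min: float = 1e-4
    max_displacement: int = 3
    seed: int = 0
    allow_shrink: bool = False  # extension beyond the default extension-only moves

    def __post_init__(self) -> None:
        if not (0 < self.cooling < 1):
            raise ValueError("cooling factor must be in (0, 1)")
        if self.t_initial <= 0 or self.t_min <= 0:
            raise ValueError("temperatures must be positive")
        if self.steps_per_temp < 1 or self.max_displacement < 1:
            raise ValueError("steps_per_temp and max_displacement must be >= 1")


def _check_bounds(record: SequenceRecord, start: int, end: int) -> None:
    if start < 1:
        raise ValueError(f"region start {start} is before position 1")
    if end > len(record):
        raise ValueError(f"region end {end} is past the sequence length {len(record)}")
    if start > end:
        raise ValueError(f"region start {start} is after its end {end}")


def score_region(
    record: SequenceRecord,
    start: int,
    end: int,
    weights: ResidueScale | None = None,
    calibration: LogisticCalibration = PUBLISHED_CALIBRATION,
) -> Region:
    """Score the substring [start, end] (1-based inclusive) of ``record``.

    Flexibility uses only windows fully inside the region.
    """
    _check_bounds(record, start, end)
    sub = record.residues[start - 1 : end]
    report = score_sequence(SequenceRecord(record.id, sub), weights, calibration)
    report = replace(report, start=start, end=end)
    return Region(start, end, report)


def _candidate_bounds(
    record: SequenceRecord, seed_start: int, seed_end: int, allow_shrink: bool
) -> tuple[int, int, int, int]:
    # extension-only: start in [1, seed_start], end in [seed_end, L]
    if allow_shrink:
        return 1, len(record), 1, len(record)
    return 1, seed_start, seed_end, len(record)


def _better(cand: Region, best: Region) -> bool:
    # ties broken toward shorter regions, then toward later starts (stable)
    if not math.isclose(cand.probability, best.probability, rel_tol=0, abs_tol=0):
        return cand.probability > best.probability
    return (cand.length, -cand.start) < (best.length, -best.start)


def anneal_region(
    record: SequenceRecord,
    seed_region: tuple[int, int],
    config: AnnealConfig = AnnealConfig(),
    weights: ResidueScale | None = None,
    calibration: LogisticCalibration = PUBLISHED_CALIBRATION,
) -> list[Region]:
    """Maximize probability of solubility over boundary extensions of a seed.

    Moves displace the start and/or end outward from the seed region by up
    to ``config.max_displacement`` residues (never inside the seed unless
    ``allow_shrink``); better regions are always accepted, worse ones with
    probability exp(Δp / T).  Returns the best-ever region first, followed
    by the other distinct accepted regions in descending probability.
    The best probability is never below the seed region's.
    """
    seed_start, seed_end = seed_region
    _check_bounds(record, seed_start, seed_end)
    weights = weights or get_scale("swi_final")
    lo_s, hi_s, lo_e, hi_e = _candidate_bounds(record, seed_start, seed_end, config.allow_shrink)

    cache: dict[tuple[int, int], Region] = {}

    def scored(s: int, e: int) -> Region:
        if (s, e) not in cache:
            cache[(s, e)] = score_region(record, s, e, weights, calibration)
        return cache[(s, e)]

    rng = np.random.default_rng(config.seed)
    current = best = scored(seed_start, seed_end)
    accepted: dict[tuple[int, int], Region] = {(seed_start, seed_end): current}
    temp = config.t_initial
    d = config.max_displacement
    while temp >= config.t_min:
        for _ in range(config.steps_per_temp):
            ds, de = rng.integers(-d, d + 1, size=2)
            s = int(np.clip(current.start + ds, lo_s, hi_s))
            e = int(np.clip(current.end + de, lo_e, hi_e))
            if config.allow_shrink and s > e:
                continue
            cand = scored(s, e)
            dp = cand.probability - current.probability
            if dp >= 0 or rng.random() < math.exp(dp / temp):
                current = cand
                accepted[(s, e)] = cand
                if _better(cand, best):
                    best = cand
        temp *= config.cooling
    others = [r for key, r in accepted.items() if key != (best.start, best.end)]
    others.sort(key=lambda r: (-r.probability, r.length, r.start))
    return [best] + others


def enumerate_extensions(
    record: SequenceRecord,
    seed_region: tuple[int, int],
    weights: ResidueScale | None = None,
    calibration: LogisticCalibration = PUBLISHED_CALIBRATION,
) -> Iterator[Region]:
    """All regions reachable by extension of the seed (start ≤ seed start,
    end ≥ seed end), scored."""
    seed_start, seed_end = seed_region
    _check_bounds(record, seed_start, seed_end)
    weights = weights or get_scale("swi_final")
    for s in range(1, seed_start + 1):
        for e in range(seed_end, len(record) + 1):
            yield score_region(record, s, e, weights, calibration)


def exhaustive_best_region(
    record: SequenceRecord,
    seed_region: tuple[int, int],
    weights: ResidueScale | None = None,
    calibration: LogisticCalibration = PUBLISHED_CALIBRATION,
) -> Region:
    """Brute-force optimum over all boundary extensions of the seed."""
    best: Region | None = None
    for region in enumerate_extensions(record, seed_region, weights, calibration):
        if best is None or _better(region, best):
            best = region
    assert best is not None
    return best


def score_with_tag(
    tag: SequenceRecord,
    target: SequenceRecord,
    terminus: str = "N",
    weights: ResidueScale | None = None,
    calibration: LogisticCalibration = PUBLISHED_CALIBRATION,
) -> SolubilityReport:
    """Score the tag–target fusion (tag first for terminus="N", last for "C").

    SWI being composition-based, the fusion SWI is exactly the
    length-weighted mean of the component SWIs, independent of terminus;
    the flexibility profile does depend on residue order.
    """
    if not tag.residues:
        raise ValueError("empty tag sequence")
    if terminus not in ("N", "C"):
        raise ValueError(f"terminus must be 'N' or 'C', got {terminus!r}")
    fused = tag.residues + target.residues if terminus == "N" else target.residues + tag.residues
    fusion_id = f"{tag.id}-{target.id}" if terminus == "N" else f"{target.id}-{tag.id}"
    return score_sequence(SequenceRecord(fusion_id, fused), weights, calibration)
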