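"""Per-residue enrichment bit scores and random-sequence controls.

The bit score of residue x in a sequence group against a background is

    bits(x) = log2( f_group(x) / f_background(x) ),

where f(x) is the residue's count normalized by the total residue count of
the group.  Residues with zero frequency on either side are reported as
undefined rather than as infinite substitutes — no pseudocount smoothing
is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .scales import STANDARD_AMINO_ACIDS
from .seqio import SequenceRecord
from .training import composition_matrix


@dataclass(frozen=True)
class EnrichmentTable:
    """Per-residue log2 frequency ratios of a group against a background."""

    group_name: str
    background_name: str
    group_freq: Mapping[str, float]
    background_freq: Mapping[str, float]
    bits: Mapping[str, float]  # only residues with both frequencies > 0
    undefined: frozenset[str]  # residues with a zero frequency on either side


def _residues_of(sequences: Iterable[str | SequenceRecord]) -> list[str]:
    return [s.residues if isinstance(s, SequenceRecord) else s for s in sequences]


def residue_frequencies(sequences: Iterable[str | SequenceRecord]) -> dict[str, float]:
    """Residue counts normalized by the total residue count of the group."""
    seqs = _residues_of(sequences)
    if not seqs or sum(map(len, seqs)) == 0:
        raise ValueError("cannot compute frequencies of an empty sequence group")
    counts, _ = composition_matrix(seqs)
    totals = counts.sum(axis=0)
    freqs = totals / totals.sum()
    return dict(zip(STANDARD_AMINO_ACIDS, freqs.tolist()))


def bit_scores(
    group_sequences: Iterable[str | SequenceRecord],
    background_sequences: Iterable[str | SequenceRecord],
    group_name: str = "group",
    background_name: str = "background",
) -> EnrichmentTable:
    """log2 enrichment of each residue in the group over the background."""
    f_grp = residue_frequencies(group_sequences)
    f_bg = residue_frequencies(background_sequences)
    bits: dict[str, float] = {}
    undefined: set[str] = set()
    for aa in STANDARD_AMINO_ACIDS:
        if f_grp[aa] > 0 and f_bg[aa] > 0:
            bits[aa] = math.log2(f_grp[aa] / f_bg[aa])
        else:
            undefined.add(aa)
    return EnrichmentTable(
        group_name, background_name, f_grp, f_bg, bits, frozenset(undefined)
    )


def generate_random_sequences(
    min_len: int = 50,
    max_len: int = 6000,
    step: int = 50,
    n_per_len: int = 100,
    composition: Mapping[str, float] | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[SequenceRecord]:
    """Random control sequences on a length grid (defaults: 50..6000 step 50,
    100 per length — 12 000 unique sequences).

    Residues are drawn i.i.d. from ``composition`` (uniform over the 20
    standard residues by default).  Duplicates are resampled so the
    returned set is unique.
    """
    if min_len < 1 or max_len < min_len or step < 1:
        raise ValueError("invalid length grid")
    if composition is None:
        probs = np.full(20, 1 / 20)
    else:
        if set(composition) - set(STANDARD_AMINO_ACIDS):
            raise ValueError("composition has non-standard residue keys")
        probs = np.array([composition.get(aa, 0.0) for aa in STANDARD_AMINO_ACIDS])
        if np.any(probs < 0) or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("composition must be non-negative and sum to 1")
        probs = probs / probs.sum()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    alphabet = np.frombuffer(STANDARD_AMINO_ACIDS.encode("ascii"), dtype=np.uint8)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for length in range(min_len, max_len + 1, step):
        made = 0
        while made < n_per_len:
            codes = rng.choice(20, size=length, p=probs)
            seq = alphabet[codes].tobytes().decode("ascii")
            if seq in seen:
                continue  # resample duplicates to keep the set unique
            seen.add(seq)
            records.append(SequenceRecord(f"random_len{length}_{made + 1}", seq))
            made += 1
    return records
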