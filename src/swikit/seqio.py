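"""Sequence input/output and preprocessing.

Reads and writes protein FASTA, validates residues against the 20 standard
amino acids under a configurable policy, translates nucleotide input, and
trims the fixed polyhistidine-tag affixes used by common expression vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .scales import STANDARD_AMINO_ACIDS

#: Fixed N- and C-terminal affixes (His-tag plus linkers) of the
#: pET15/pET21-style expression constructs.
NTERM_HIS_TAG = "MRGSHHHHHHTDPALRA"
CTERM_HIS_TAG = "GLCGR"

_STANDARD_SET = frozenset(STANDARD_AMINO_ACIDS)
_NUCLEOTIDE_SET = frozenset("ACGTU")

Policy = Literal["error", "drop", "reject"]


class SequenceError(ValueError):
    """Raised for invalid sequences or malformed sequence files."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named protein sequence over the 20 standard residues."""

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


def clean_residues(raw: str, policy: Policy = "error", *, context: str = "sequence") -> str:
    """Uppercase ``raw`` and apply the nonstandard-residue policy.

    policy="error" raises on any character outside the 20 standard codes,
    policy="drop" removes such characters, policy="reject" raises a
    distinct error used by bulk readers to skip the whole record.
    """
    residues = "".join(raw.split()).upper()
    bad = sorted(set(residues) - _STANDARD_SET)
    if bad:
        if policy == "drop":
            residues = "".join(c for c in residues if c in _STANDARD_SET)
        elif policy in ("error", "reject"):
            raise SequenceError(
                f"{context}: nonstandard residue(s) {''.join(bad)!r} "
                f"(policy={policy!r}; use policy='drop' to remove them)"
            )
        else:
            raise ValueError(f"unknown policy {policy!r}")
    if not residues:
        raise SequenceError(f"{context}: empty after applying policy {policy!r}")
    return residues


def read_fasta(path: str | Path, policy: Policy = "error") -> list[SequenceRecord]:
    """Read a protein FASTA file into validated records, order preserved.

    With ``policy="reject"`` records containing nonstandard residues are
    skipped; ``"drop"`` removes the offending characters; ``"error"``
    (default) raises.
    """
    path = Path(path)
    if not path.exists():
        raise SequenceError(f"no such file: {path}")
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise SequenceError(
                        f"{path}: malformed FASTA, line {lineno} is not a header: {line.strip()!r}"
                    )
                break
        else:
            raise SequenceError(f"{path}: empty FASTA file")
    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        try:
            residues = clean_residues(str(entry.seq), policy, context=entry.id)
        except SequenceError:
            if policy == "reject":
                continue
            raise
        records.append(SequenceRecord(entry.id, residues))
    if not records:
        raise SequenceError(f"{path}: no usable records")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def translate_if_nucleotide(record: SequenceRecord) -> SequenceRecord:
    """Translate ``record`` if it looks like a coding nucleotide sequence.

    A sequence over {A,C,G,T,U} only, with length a multiple of 3, is
    translated with the standard genetic code, stopping at the first stop
    codon.  Any other alphabet is returned unchanged.  A pure-nucleotide
    alphabet with length not a multiple of 3 is ambiguous (A/C/G/T are also
    amino-acid codes) and raises.
    """
    if not set(record.residues) <= _NUCLEOTIDE_SET:
        return record
    if len(record.residues) % 3 != 0:
        raise SequenceError(
            f"{record.id}: sequence uses only A/C/G/T/U but its length "
            f"({len(record.residues)}) is not a multiple of 3; it is ambiguous "
            "between nucleotide and protein — pass an explicit sequence-type flag"
        )
    protein = str(Seq(record.residues.replace("U", "T")).translate(to_stop=True))
    if not protein:
        raise SequenceError(f"{record.id}: translation starts with a stop codon")
    return replace(record, residues=protein)


def trim_his_tag(
    record: SequenceRecord,
    nterm: str = NTERM_HIS_TAG,
    cterm: str = CTERM_HIS_TAG,
) -> SequenceRecord:
    """Remove exact-match His-tag affixes from either terminus.

    Exact prefix/suffix matching only; both ends may be trimmed.  Raises if
    trimming would leave an empty sequence.
    """
    residues = record.residues
    if nterm and residues.startswith(nterm):
        residues = residues[len(nterm):]
    if cterm and residues.endswith(cterm):
        residues = residues[: len(residues) - len(cterm)]
    if not residues:
        raise SequenceError(f"{record.id}: nothing left after His-tag trimming")
    return replace(record, residues=residues)


def read_labels_tsv(path: str | Path) -> dict[str, float]:
    """Read ``id <tab> label`` (binary 0/1 or percentage in [0, 100])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 2:
        raise SequenceError(f"{path}: expected two tab-separated columns (id, label)")
    labels: dict[str, float] = {}
    for sid, raw in zip(df[0], df[1]):
        val = float(raw)
        if not 0.0 <= val <= 100.0:
            raise SequenceError(f"{path}: label {val} for {sid!r} outside [0, 100]")
        labels[sid] = val
    return labels


def read_clusters_tsv(path: str | Path) -> dict[str, str]:
    """Read ``id <tab> cluster_id`` assignments."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise SequenceError(f"{path}: expected two tab-separated columns (id, cluster)")
    return dict(zip(df[0], df[1]))
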