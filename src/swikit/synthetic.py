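"""Synthetic labeled, clustered protein datasets with a planted weight vector.

The generator emulates the statistical structure of a homology-clustered
solubility screen: sequence families descended from random ancestors by
point substitution, with each sequence's soluble/insoluble label driven by
its SWI under a planted per-residue weight vector through a logistic link
(or a hard threshold).  Labels are assigned per sequence, not per family,
so families can contain a mix of soluble and insoluble members — as real
similarity clusters do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
from scipy.special import expit

from .scales import STANDARD_AMINO_ACIDS, ResidueScale, get_scale
from .seqio import SequenceRecord
from .training import LabeledDataset, composition_matrix


@dataclass(frozen=True)
class LabelLink:
    """How planted SWI drives labels.

    mode="logistic": P(soluble) = expit(slope * (swi - center));
    mode="threshold": soluble iff swi > center, with sequences closer than
    ``margin`` to the center dropped (guaranteeing separability).
    ``center=None`` uses the median planted SWI of the generated set.
    """

    mode: Literal["logistic", "threshold"] = "logistic"
    slope: float = 800.0
    center: float | None = None
    margin: float = 0.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation settings; defaults give 400 sequences in 20 families with
    a strong (but not deterministic) logistic label link."""

    n_families: int = 20
    family_size: int = 20
    length_range: tuple[int, int] = (100, 300)
    mutation_rate: float = 0.1
    planted_weights: ResidueScale | None = None  # defaults to the shipped final weights
    link: LabelLink = field(default_factory=LabelLink)
    composition: Mapping[str, float] | None = None  # ancestor residue frequencies
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.mutation_rate < 1):
            raise ValueError("mutation rate must be in [0, 1)")
        if self.length_range[0] < 9 or self.length_range[0] > self.length_range[1]:
            raise ValueError("lengths must be >= 9 and min <= max")
        if self.n_families < 1 or self.family_size < 1:
            raise ValueError("n_families and family_size must be >= 1")


def _composition_probs(composition: Mapping[str, float] | None) -> np.ndarray:
    if composition is None:
        return np.full(20, 1 / 20)
    probs = np.array([composition.get(aa, 0.0) for aa in STANDARD_AMINO_ACIDS])
    if np.any(probs < 0) or probs.sum() <= 0:
        raise ValueError("invalid ancestor composition")
    return probs / probs.sum()


def generate_dataset(spec: SyntheticSpec = SyntheticSpec()) -> LabeledDataset:
    """Generate a clustered, labeled dataset from ``spec`` (reproducible)."""
    rng = np.random.default_rng(spec.seed)
    planted = spec.planted_weights or get_scale("swi_final")
    probs = _composition_probs(spec.composition)
    alphabet = np.frombuffer(STANDARD_AMINO_ACIDS.encode("ascii"), dtype=np.uint8)

    sequences: list[SequenceRecord] = []
    clusters: list[str] = []
    for fam in range(spec.n_families):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        ancestor = rng.choice(20, size=length, p=probs)
        for m in range(spec.family_size):
            member = ancestor.copy()
            hit = rng.random(length) < spec.mutation_rate
            member[hit] = rng.choice(20, size=int(hit.sum()), p=probs)
            sequences.append(
                SequenceRecord(
                    f"fam{fam + 1}_m{m + 1}",
                    alphabet[member].tobytes().decode("ascii"),
                )
            )
            clusters.append(f"fam{fam + 1}")

    counts, lengths = composition_matrix([s.residues for s in sequences])
    swi_vals = counts @ np.array(planted.as_vector()) / lengths
    center = spec.link.center if spec.link.center is not None else float(np.median(swi_vals))

    if spec.link.mode == "logistic":
        p_soluble = expit(spec.link.slope * (swi_vals - center))
        labels = (rng.random(len(sequences)) < p_soluble).astype(int)
        keep = np.ones(len(sequences), dtype=bool)
    elif spec.link.mode == "threshold":
        labels = (swi_vals > center).astype(int)
        keep = np.abs(swi_vals - center) > spec.link.margin
    else:
        raise ValueError(f"unknown label link mode {spec.link.mode!r}")

    records = tuple(
        (sequences[i], int(labels[i]), clusters[i])
        for i in range(len(sequences))
        if keep[i]
    )
    return LabeledDataset(records)


def perturb_weights(
    scale: ResidueScale,
    relative_noise: float,
    rng: np.random.Generator | int | None = None,
) -> ResidueScale:
    """Multiply each weight by (1 + ε), ε uniform in ±relative_noise.

    Provides imperfect initial weights for recovery experiments.
    """
    if relative_noise < 0:
        raise ValueError("relative_noise must be >= 0")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    eps = rng.uniform(-relative_noise, relative_noise, size=20)
    values = {
        aa: scale.values[aa] * (1 + eps[i])
        for i, aa in enumerate(STANDARD_AMINO_ACIDS)
    }
    return ResidueScale(
        f"{scale.name}_perturbed",
        values,
        provenance=f"{scale.name} with ±{relative_noise:.0%} multiplicative noise",
    )
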