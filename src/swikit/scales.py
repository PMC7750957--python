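"""Per-residue weight tables (residue scales).

A :class:`ResidueScale` maps each of the 20 standard amino acids to a real
number.  The package ships, as packaged JSON data:

* three published normalized B-factor / flexibility scales
  (``smith2003``, ``vihinen1994``, ``bhaskaran1988``),
* the final Solubility-Weighted Index weights (``swi_final``), and
* the Kyte–Doolittle hydropathy index (``kyte_doolittle``).

The shipped registry is read-only; user-derived weight sets enter through
:func:`load_weights` / :func:`save_weights` (a small JSON schema that
round-trips floats exactly via their ``repr``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

STANDARD_AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
"""The 20 standard one-letter amino-acid codes, alphabetical."""

_BUNDLED = ("swi_final", "smith2003", "vihinen1994", "bhaskaran1988", "kyte_doolittle")


class ScaleError(ValueError):
    """Raised for malformed or unknown residue scales."""


@dataclass(frozen=True)
class ResidueScale:
    """A named mapping from the 20 standard residues to real values.

    Parameters
    ----------
    name
        Short identifier of the scale.
    values
        Mapping with exactly one finite value per standard residue.
    provenance
        Free-text citation describing where the numbers come from.
    """

    name: str
    values: Mapping[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        keys = set(self.values)
        expected = set(STANDARD_AMINO_ACIDS)
        if missing := expected - keys:
            raise ScaleError(
                f"scale {self.name!r} missing residue(s): {sorted(missing)}"
            )
        if extra := keys - expected:
            raise ScaleError(
                f"scale {self.name!r} has non-standard residue key(s): {sorted(extra)}"
            )
        for aa, v in self.values.items():
            if not isinstance(v, (int, float)) or isinstance(v, bool) or not math.isfinite(v):
                raise ScaleError(f"scale {self.name!r}: value for {aa!r} is not a finite number: {v!r}")
        object.__setattr__(
            self,
            "values",
            MappingProxyType({aa: float(self.values[aa]) for aa in STANDARD_AMINO_ACIDS}),
        )

    def __getitem__(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise ScaleError(
                f"residue {residue!r} is not covered by scale {self.name!r}"
            ) from None

    def as_vector(self) -> "list[float]":
        """Values ordered as :data:`STANDARD_AMINO_ACIDS`."""
        return [self.values[aa] for aa in STANDARD_AMINO_ACIDS]

    def min(self) -> float:
        return min(self.values.values())

    def max(self) -> float:
        return max(self.values.values())


def _load_bundled(name: str) -> ResidueScale:
    text = resources.files("swikit.data").joinpath(f"{name}.json").read_text()
    payload = json.loads(text)
    return ResidueScale(payload["name"], payload["values"], payload.get("provenance", ""))


_REGISTRY: dict[str, ResidueScale] = {}


def available_scales() -> tuple[str, ...]:
    """Names of the scales shipped with the package."""
    return _BUNDLED


def get_scale(name: str) -> ResidueScale:
    """Return a bundled scale by name.

    Raises
    ------
    ScaleError
        If ``name`` is not registered; the message lists valid choices.
    """
    if name not in _BUNDLED:
        raise ScaleError(
            f"unknown scale {name!r}; available scales: {', '.join(_BUNDLED)}"
        )
    if name not in _REGISTRY:
        _REGISTRY[name] = _load_bundled(name)
    return _REGISTRY[name]


def load_weights(path: str | Path) -> ResidueScale:
    """Read a residue scale from a weight-file JSON.

    Schema: ``{"name": str, "provenance": str, "values": {"A": float, ..., "Y": float}}``
    with exactly the 20 standard residues as keys of ``values``.
    """
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ScaleError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(payload, dict) or "values" not in payload:
        raise ScaleError(f"{path}: weight file must be a JSON object with a 'values' key")
    values = payload["values"]
    if not isinstance(values, dict):
        raise ScaleError(f"{path}: 'values' must be an object mapping residues to numbers")
    return ResidueScale(
        str(payload.get("name", Path(path).stem)),
        values,
        str(payload.get("provenance", "")),
    )


def save_weights(scale: ResidueScale, path: str | Path) -> None:
    """Write ``scale`` as weight-file JSON (full float precision)."""
    payload = {
        "name": scale.name,
        "provenance": scale.provenance,
        "values": {aa: scale.values[aa] for aa in STANDARD_AMINO_ACIDS},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
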