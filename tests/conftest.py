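import numpy as np
import pytest

from swikit.scales import STANDARD_AMINO_ACIDS, ResidueScale


@pytest.fixture
def toy_scale():
    """A 20-entry scale with distinct, easily hand-checked values."""
    values = {aa: 0.1 + 0.05 * i for i, aa in enumerate(STANDARD_AMINO_ACIDS)}
    return ResidueScale("toy", values, provenance="test fixture")


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_protein(rng, length):
    return "".join(rng.choice(list(STANDARD_AMINO_ACIDS), size=length))


@pytest.fixture
def make_fasta(tmp_path):
    def _write(entries, name="input.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for sid, seq in entries:
                fh.write(f">{sid}\n{seq}\n")
        return path

    return _write
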