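import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gibbsmotif.pdbio import ProteinStructure, Residue

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def triangle_structure(d12, d13, d23, id="tri", symbols="AAC", offset=(0, 0, 0)):
    """Three residues with prescribed internal distances (planar placement)."""
    x = (d12**2 + d13**2 - d23**2) / (2 * d12)
    y = np.sqrt(max(d13**2 - x**2, 0.0))
    coords = np.array([[0, 0, 0], [d12, 0, 0], [x, y, 0]], dtype=float)
    coords += np.asarray(offset, dtype=float)
    residues = [
        Residue(symbol=symbols[i], seq_index=i + 1, chain_id="A", coords=coords[i])
        for i in range(3)
    ]
    return ProteinStructure(id=id, residues=residues)


def line_structure(xs, id="line", symbols=None):
    """Residues placed on the x axis at the given abscissae."""
    symbols = symbols or "A" * len(xs)
    residues = [
        Residue(
            symbol=symbols[i],
            seq_index=i + 1,
            chain_id="A",
            coords=np.array([float(x), 0.0, 0.0]),
        )
        for i, x in enumerate(xs)
    ]
    return ProteinStructure(id=id, residues=residues)


def random_structure(n, rng, id="rnd", scale=8.0):
    """n residues at Gaussian random coordinates with random symbols."""
    from gibbsmotif.sampler import ALPHABET

    coords = rng.normal(size=(n, 3)) * scale
    syms = rng.choice(list(ALPHABET), size=n)
    residues = [
        Residue(symbol=str(syms[i]), seq_index=i + 1, chain_id="A", coords=coords[i])
        for i in range(n)
    ]
    return ProteinStructure(id=id, residues=residues)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


SAMPLE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000  -1.400  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA A   2       3.000   4.000   0.000  1.00  0.00           C
ATOM      4  CA  CYS A   3       1.000   2.000   2.000  1.00  0.00           C
END
"""
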