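import pytest

from optoxr import (
    ProteinSequence,
    Segment,
    TopologyAnnotation,
    blosum62,
)


@pytest.fixture(scope="session")
def matrix():
    return blosum62()


@pytest.fixture
def toy_backbone():
    """13-residue toy backbone; W residues mark the ICL1 boundaries."""
    seq = ProteinSequence("rho_toy", "MAAAWLLLWAAAC")
    topo = TopologyAnnotation(
        "rho_toy",
        (
            Segment("NTERM", 1, 1),
            Segment("TM1", 2, 4),
            Segment("ICL1", 5, 9),
            Segment("TM2", 10, 12),
            Segment("CTERM", 13, 13),
        ),
    )
    return seq, topo


@pytest.fixture
def toy_target():
    """Homologous toy target; Y residues mirror the backbone's W markers."""
    return ProteinSequence("dop_toy", "MGGGYKKKYGGGD")
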