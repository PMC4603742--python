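import pytest

from scaffex.model import ScaffoldGraph


@pytest.fixture
def four_cycle() -> ScaffoldGraph:
    """Two contigs ab, cd; links bc (w=2) and da (w=3) closing a 4-cycle."""
    return ScaffoldGraph.from_edges(
        [
            ("a", "b", 0, True),
            ("c", "d", 0, True),
            ("b", "c", 2, False),
            ("d", "a", 3, False),
        ]
    )


@pytest.fixture
def two_contig_path() -> ScaffoldGraph:
    """Contigs ab, cd joined by the single link bc of weight 5."""
    return ScaffoldGraph.from_edges(
        [
            ("a", "b", 0, True),
            ("c", "d", 0, True),
            ("b", "c", 5, False),
        ]
    )
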