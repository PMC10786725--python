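import pytest

from pausekit.gene_model import GeneRecord
from pausekit.synthetic_data import SyntheticConfig


@pytest.fixture
def toy_genes():
    """Hand-built 10-gene annotation: 2 short genes, one 2.5 kb-gap pair.

    Expected to survive the filters: G01, G02, G06, G08, G09, G10 (6 genes).
    """
    spans = [
        ("G01", "+", 10_000, 15_000),
        ("G02", "-", 20_000, 26_000),
        ("G03", "+", 30_000, 30_900),   # short (<1 kb)
        ("G04", "+", 40_000, 45_000),   # proximal pair with G05 (gap 2,500)
        ("G05", "-", 47_500, 52_000),
        ("G06", "+", 60_000, 64_000),
        ("G07", "-", 70_000, 70_800),   # short (<1 kb)
        ("G08", "+", 80_000, 85_000),
        ("G09", "-", 90_000, 96_000),
        ("G10", "+", 105_000, 110_000),
    ]
    return [
        GeneRecord(gid, f"{gid}.t1", "chr1", strand, s, e)
        for gid, strand, s, e in spans
    ]


@pytest.fixture
def small_config():
    """Reduced-scale synthetic study for fast end-to-end tests."""
    return SyntheticConfig(seed=7, n_genes=120)
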