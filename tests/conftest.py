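import numpy as np
import pytest

from cernaforge import de_analysis
from cernaforge.core import Gene, GenomeAnnotation, StudyDesign
from cernaforge.synthetic_data import generate_bundle


@pytest.fixture(scope="session")
def design():
    return StudyDesign()


@pytest.fixture(scope="session")
def toy_annotation():
    """Two genes on chr1 (opposite strands, separated), one on chr2."""
    genes = [
        Gene("gA", "chr1", "+", ((100, 200), (300, 400), (500, 650))),
        Gene("gB", "chr1", "-", ((2000, 2150), (2400, 2600))),
        Gene("gC", "chr2", "+", ((50, 180), (400, 560))),
    ]
    return GenomeAnnotation(genes, {"chr1": 5000, "chr2": 2000})


@pytest.fixture(scope="session")
def bundle():
    """Default strong-signal synthetic bundle (8 planted triplets)."""
    return generate_bundle(seed=1)


@pytest.fixture(scope="session")
def bundle_de_sets(bundle):
    """Union of significant features over all comparisons, per matrix."""
    return {
        kind: de_analysis.significant_union(
            de_analysis.run_all_comparisons(bundle.counts[kind])
        )
        for kind in ("circ", "mirna", "mrna")
    }
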