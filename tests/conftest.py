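import numpy as np
import pytest

from ndjmap.chromosome_model import (ArmSpec, ChromosomeModel, GeneticMapAnchor,
                                     METACENTRIC, TELOCENTRIC,
                                     TELOMERE_TO_CENTROMERE, CENTROMERE_TO_TELOMERE,
                                     dm6_chr2, dm6_chrX)
from ndjmap.xo_caller import GenotypeSegmentation, Segment, SegmentationParams


@pytest.fixture(scope="session")
def chr2_model():
    return dm6_chr2()


@pytest.fixture(scope="session")
def chrx_model():
    return dm6_chrX()


@pytest.fixture
def small_model():
    """A 10+10 Mb metacentric toy chromosome for fast geometry tests."""
    left = ArmSpec(
        label="L", contig="tL", assembly_span=(0, 10_000_000),
        euchromatin_span=(0, 9_000_000), orientation=TELOMERE_TO_CENTROMERE,
        heterochromatin_intervals=[(9_000_000, 10_000_000)],
        anchors=[GeneticMapAnchor("a", 1_000_000, 0.0),
                 GeneticMapAnchor("b", 5_000_000, 20.0),
                 GeneticMapAnchor("c", 9_000_000, 30.0)],
    )
    right = ArmSpec(
        label="R", contig="tR", assembly_span=(0, 10_000_000),
        euchromatin_span=(1_000_000, 10_000_000), orientation=CENTROMERE_TO_TELOMERE,
        heterochromatin_intervals=[(0, 1_000_000)],
        anchors=[GeneticMapAnchor("d", 1_000_000, 30.0),
                 GeneticMapAnchor("e", 9_000_000, 60.0)],
    )
    return ChromosomeModel(name="t", arms=[left, right], shape=METACENTRIC,
                           centromere_gap_bp=2_000_000)


def make_segmentation(contig, spans, spacing=50_000, start=0):
    """Build a GenotypeSegmentation from (n_markers, state_label) runs."""
    segments, pos, idx = [], [], 0
    p = start
    for n, state in spans:
        seg_pos = [p + i * spacing for i in range(n)]
        pos.extend(seg_pos)
        p = seg_pos[-1] + spacing
        freq = {"HOM_P1": 0.0, "HET": 0.25, "HOM_P2": 0.5}[state]
        segments.append(Segment(idx, idx + n, state, freq, n))
        idx += n
    return GenotypeSegmentation(contig=contig, positions=np.asarray(pos, dtype=float),
                                segments=segments, params=SegmentationParams())


@pytest.fixture
def seg_factory():
    return make_segmentation
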