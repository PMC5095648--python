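import numpy as np
import pytest

from risprofile import (
    GenomeLayout,
    GenomicInterval,
    GeneModel,
    Peak,
    ReferenceBundle,
    RepeatFeature,
    generate_reference,
)


@pytest.fixture(scope="session")
def tiny_bundle() -> ReferenceBundle:
    """A hand-built reference small enough to annotate by eye."""
    layout = GenomeLayout([("chr1", 1_000_000), ("chr2", 1_000_000)])
    genes = [
        GeneModel("GENEA", GenomicInterval("chr1", 100_000, 150_000, "+", "GENEA"),
                  100_000, is_oncogene=False),
        GeneModel("ONCO1", GenomicInterval("chr1", 400_000, 450_000, "-", "ONCO1"),
                  449_999, is_oncogene=True),
        GeneModel("GENEB", GenomicInterval("chr2", 200_000, 260_000, "+", "GENEB"),
                  200_000, is_oncogene=False),
    ]
    cpg = [GenomicInterval("chr1", 99_000, 99_500)]
    repeats = [
        RepeatFeature(GenomicInterval("chr1", 500_000, 520_000), "Satellite"),
        RepeatFeature(GenomicInterval("chr1", 10_000, 12_000), "LINE"),
        RepeatFeature(GenomicInterval("chr2", 700_000, 702_000), "SINE"),
    ]
    centromeres = [GenomicInterval("chr1", 490_000, 530_000)]
    peaks = [
        Peak(GenomicInterval("chr1", 600_000, 605_000, name="pk_weak"), 5.0),
        Peak(GenomicInterval("chr1", 700_000, 705_000, name="pk_strong"), 500.0),
        Peak(GenomicInterval("chr2", 100_000, 104_000, name="pk_mid"), 50.0),
    ]
    return ReferenceBundle(
        layout=layout, genes=genes, cpg_islands=cpg, repeats=repeats,
        centromeres=centromeres, peak_sets={"H3K9me3": peaks},
        oncogene_names={"ONCO1"},
    )


@pytest.fixture(scope="session")
def synth_ref():
    """Default coordinate-level synthetic reference, shared across tests."""
    return generate_reference(seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
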