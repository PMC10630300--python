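import numpy as np
import pytest

from regenscreen.library import SampleEntry, SampleManifest, ShRNALibrary, ShRNARecord


@pytest.fixture
def tiny_library() -> ShRNALibrary:
    """Three hairpins over two genes plus one non-targeting control."""
    return ShRNALibrary(
        [
            ShRNARecord("sh_A1", "GeneA", "ACGTACGTACGTACGTACGTAC", "targeting"),
            ShRNARecord("sh_A2", "GeneA", "TTGCATGCATGCATGCATGCAT", "targeting"),
            ShRNARecord("sh_NC", "", "GGGTTTAAACCCGGGTTTAAAC", "non_targeting"),
        ]
    )


@pytest.fixture
def small_manifest() -> SampleManifest:
    return SampleManifest(
        [
            SampleEntry("AACCGGTT", "pool", "reference_pool"),
            SampleEntry("TTGGCCAA", "rep_1", "replicate"),
            SampleEntry("GATCGATC", "rep_2", "replicate"),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
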