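import numpy as np
import pytest

from viropipe.io import SequenceRecord
from viropipe.screen import detect_circularity
from viropipe.synth import CommunitySpec, assign_abundances, emit_contigs, generate_genomes


@pytest.fixture(scope="session")
def small_spec() -> CommunitySpec:
    return CommunitySpec(
        n_dsdna=5, n_micro=2, n_cress=3, n_contaminant=2, n_read_pairs=4000, seed=42
    )


@pytest.fixture(scope="session")
def small_community(small_spec):
    genomes, truth = generate_genomes(small_spec)
    truth = assign_abundances(truth, small_spec)
    return genomes, truth


@pytest.fixture(scope="session")
def small_contigs(small_spec, small_community):
    genomes, truth = small_community
    raw = emit_contigs(genomes, truth, small_spec.terminal_repeat_len)
    return [
        detect_circularity(SequenceRecord(id=c.id, seq=c.seq), viral_category=c.viral_category)
        for c in raw
    ]
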