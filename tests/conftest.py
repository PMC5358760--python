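import numpy as np
import pytest

from pol3roadblock import scenarios, synthio
from pol3roadblock.tagweight import assign_weights, build_coverage

SEED = 1234


@pytest.fixture(scope="session")
def repeat_genome():
    """100 kb contig with a 3-copy zero-divergence 260 bp family, each copy
    planted as an 8-fold Pol III locus."""
    return synthio.generate_genome(scenarios.repeat_family_spec(seed=SEED))


@pytest.fixture(scope="session")
def repeat_ip_tags(repeat_genome):
    return synthio.simulate_chip_tags(
        repeat_genome, "pol3_ip", depth=scenarios.DEPTH,
        tag_length=scenarios.TAG_LENGTH, seed=SEED + 1)


@pytest.fixture(scope="session")
def funnel_genome():
    """10 genes with mixed-orientation nested units and 3-fold pileups;
    events 3 and 7 carry NELF co-enrichment (decoy internal TSSs)."""
    return synthio.generate_genome(
        scenarios.funnel_spec(n_genes=10, decoy_idx=(3, 7), seed=SEED))


@pytest.fixture(scope="session")
def funnel_tracks(funnel_genome):
    tracks = {}
    for i, kind in enumerate(["pol3_ip", "input", "pol2", "nelf", "dsif"]):
        tags = synthio.simulate_chip_tags(
            funnel_genome, kind, depth=scenarios.DEPTH,
            tag_length=scenarios.TAG_LENGTH, seed=SEED + 10 + i)
        tracks[kind] = build_coverage(
            assign_weights(tags, "uniform"), scenarios.BIN_SIZE,
            funnel_genome.contig_lengths())
    return tracks


def make_rng(offset=0):
    return np.random.default_rng(SEED + offset)
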