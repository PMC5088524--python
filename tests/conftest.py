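"""Shared fixtures: worked-example fragment file and a synthetic community."""

from __future__ import annotations

import io

import pytest

from glocalmap.extension import extend_all
from glocalmap.fragments import parse_fragment_file
from glocalmap.mapping import MappingParams, map_all
from glocalmap.scoring import ScoreScheme, rescore_all
from glocalmap.simulate import (
    community_taxonomy,
    generate_community,
    generate_reads,
    simulate_fragments,
)

# A self-consistent reconstruction of the published before-extension example:
# two ungapped candidate fragments of one read against one genome, separated
# by 14 read bases (147 - 133) and 11 genome bases, that extension joins into
# a single glocal fragment ending at read position 249 and spanning genome
# 1631420..1631665 with one opened and two extension gaps.
TABLE1_BEFORE = (
    ">029701.102903 — NC_004663.1 — Bacteroides thetaiotaomicron — len=249\n"
    "1\t-\t124\t133\t93.23\t0\t0\tPlus/Plus\t1\t133\t1631420\t1631552\n"
    "2\t-\t96\t103\t93.20\t0\t0\tPlus/Plus\t147\t249\t1631563\t1631665\n"
)

@pytest.fixture()
def table1_groups():
    return parse_fragment_file(io.StringIO(TABLE1_BEFORE))


@pytest.fixture()
def table1_sequences():
    """Read/genome strings consistent with the worked-example coordinates."""
    read_seg = "ACGTACGTACGTA"  # read positions 134..146
    genome_seg = read_seg[:5] + read_seg[8:]  # 3-base deletion -> 10 genome bases
    read = "C" * 133 + read_seg + "C" * 103
    genome = "A" * 1631552 + genome_seg + "A" * (1631700 - 1631552 - len(genome_seg))
    return read, genome


@pytest.fixture(scope="session")
def scheme():
    return ScoreScheme(db_length=18_000).calibrate()


@pytest.fixture(scope="session")
def small_community():
    """Three 6 kb genomes; G1 and G2 share a 1.8 kb block (30% of G2)."""
    return generate_community(
        3,
        6_000,
        shared_blocks=[("G1", "G2", 1_800, None, 2_001)],
        seed=11,
    )


@pytest.fixture(scope="session")
def small_run(small_community):
    """Full pipeline on the small community: truth, records, taxonomy."""
    com = small_community
    reads, truth = generate_reads(
        com.genomes,
        [0.5, 0.3, 0.2],
        1_500,
        sub_rate=0.02,
        indel_rate=0.1,
        seed=23,
    )
    groups = simulate_fragments(truth, com, split_indel_hsps=True)
    scheme = ScoreScheme()
    extended = extend_all(groups, reads, com.genomes, scheme, max_gap=20)
    rescore_all(extended, scheme)
    taxonomy = community_taxonomy(com)
    records, summary = map_all(extended, scheme, taxonomy, MappingParams())
    return {
        "community": com,
        "reads": reads,
        "truth": truth,
        "groups": groups,
        "extended": extended,
        "scheme": scheme,
        "taxonomy": taxonomy,
        "records": records,
        "summary": summary,
    }


def read_overlaps_shared_block(truth_read, community) -> bool:
    for b in community.blocks:
        for g, s in ((b.genome_a, b.start_a), (b.genome_b, b.start_b)):
            if truth_read.genome_id == g and truth_read.start <= s + b.length - 1 and truth_read.end >= s:
                return True
    return False
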