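"""Glocal extension: chaining, Needleman-Wunsch bridging, merging."""

import random

import pytest
from Bio import Align

from glocalmap.extension import (
    bridge_alignment,
    bridge_score,
    extend_all,
    find_joinable_chains,
    merge_chain,
)
from glocalmap.fragments import FORWARD, REVERSE, Fragment
from glocalmap.scoring import ScoreScheme
from glocalmap.simulate import generate_community, generate_reads, simulate_fragments

SCHEME = ScoreScheme()


def _frag(k, r1, r2, g1, g2, strand=FORWARD, ident=None):
    length = r2 - r1 + 1
    return Fragment(k, None, ident if ident is not None else length, length,
                    100.0, 0, 0, strand, r1, r2, g1, g2)


class TestChaining:
    def test_worked_example_joins_at_max_gap_20(self, table1_groups):
        frags = table1_groups[0].per_genome["NC_004663.1"]
        chains = find_joinable_chains(frags, max_gap=20)
        assert len(chains) == 1 and len(chains[0]) == 2

    def test_worked_example_split_at_max_gap_10(self, table1_groups):
        frags = table1_groups[0].per_genome["NC_004663.1"]
        chains = find_joinable_chains(frags, max_gap=10)
        assert [len(c) for c in chains] == [1, 1]

    def test_overlapping_fragments_stay_singletons(self):
        frags = [_frag(1, 1, 100, 1, 100), _frag(2, 90, 150, 95, 155)]
        assert [len(c) for c in find_joinable_chains(frags, 20)] == [1, 1]

    def test_strand_mismatch_blocks_chaining(self):
        frags = [_frag(1, 1, 100, 1, 100), _frag(2, 105, 150, 110, 155, strand=REVERSE)]
        assert [len(c) for c in find_joinable_chains(frags, 20)] == [1, 1]

    def test_genome_side_gap_also_bounded(self):
        # read gap 5 but genome gap 500: no chain
        frags = [_frag(1, 1, 100, 1, 100), _frag(2, 105, 150, 600, 645)]
        assert [len(c) for c in find_joinable_chains(frags, 20)] == [1, 1]

    def test_reverse_strand_collinearity(self):
        # ascending read order walks the genome backwards on the reverse strand
        f1 = Fragment(1, None, 50, 50, 100.0, 0, 0, REVERSE, 1, 50, 951, 1000)
        f2 = Fragment(2, None, 40, 40, 100.0, 0, 0, REVERSE, 56, 95, 906, 945)
        chains = find_joinable_chains([f1, f2], 20)
        assert len(chains) == 1 and len(chains[0]) == 2

    def test_three_collinear_fragments_one_chain(self):
        frags = [_frag(1, 1, 50, 1, 50), _frag(2, 56, 100, 56, 100), _frag(3, 106, 150, 106, 150)]
        chains = find_joinable_chains(frags, 20)
        assert len(chains) == 1 and len(chains[0]) == 3


class TestBridgeAlignment:
    def test_identical_segments(self):
        st = bridge_alignment("ACGT", "ACGT", SCHEME)
        assert (st.identities, st.aligned_length, st.igaps, st.egaps) == (4, 4, 0, 0)

    def test_pure_gap_one_open_two_extensions(self):
        st = bridge_alignment("", "AAA", SCHEME)
        assert (st.identities, st.aligned_length, st.igaps, st.egaps) == (0, 3, 1, 2)

    def test_single_deletion_bridge(self):
        st = bridge_alignment("ACGTAC", "ACTAC", SCHEME)
        assert (st.identities, st.aligned_length, st.igaps, st.egaps) == (5, 6, 1, 0)

    def test_empty_both(self):
        st = bridge_alignment("", "", SCHEME)
        assert st.aligned_length == 0

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            bridge_alignment("AXGT", "ACGT", SCHEME)

    @staticmethod
    def _enumerate_optimal(a, b, sch):
        """Independent oracle: exhaustive enumeration of all alignment paths."""
        best = [float("-inf")]

        def rec(i, j, state, score):
            if i == len(a) and j == len(b):
                best[0] = max(best[0], score)
                return
            if i < len(a) and j < len(b):
                s = sch.match if a[i] == b[j] else sch.mismatch
                rec(i + 1, j + 1, "M", score + s)
            if i < len(a):
                rec(i + 1, j, "X", score + (sch.gap_extend if state == "X" else sch.gap_open))
            if j < len(b):
                rec(i, j + 1, "Y", score + (sch.gap_extend if state == "Y" else sch.gap_open))

        rec(0, 0, "M", 0.0)
        return best[0]

    def test_matches_exhaustive_enumeration_on_small_pairs(self):
        rng = random.Random(101)
        for _ in range(150):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 6)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 6)))
            st = bridge_alignment(a, b, SCHEME)
            assert bridge_score(st, SCHEME) == pytest.approx(self._enumerate_optimal(a, b, SCHEME))

    def test_matches_independent_affine_aligner(self):
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = SCHEME.match
        aligner.mismatch_score = SCHEME.mismatch
        aligner.open_gap_score = SCHEME.gap_open
        aligner.extend_gap_score = SCHEME.gap_extend
        rng = random.Random(77)
        for _ in range(200):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 20)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 20)))
            st = bridge_alignment(a, b, SCHEME)
            assert bridge_score(st, SCHEME) == pytest.approx(aligner.score(a, b))


class TestMerge:
    def test_singleton_chain_identity(self, table1_groups, table1_sequences):
        frag = table1_groups[0].per_genome["NC_004663.1"][0]
        merged = merge_chain([frag], *table1_sequences, SCHEME)
        assert merged == frag

    def test_worked_example_merge_coordinates_and_gaps(self, table1_groups, table1_sequences):
        frags = table1_groups[0].per_genome["NC_004663.1"]
        chain = find_joinable_chains(frags, 20)[0]
        merged = merge_chain(chain, *table1_sequences, SCHEME)
        assert merged.r_end == 249
        assert merged.g_start == 1631420
        assert merged.g_end == 1631665
        assert (merged.igaps, merged.egaps) == (1, 2)  # one opening, two extensions
        assert merged.identities == 124 + 96 + 10
        assert merged.length == 133 + 103 + 13
        assert merged.score == pytest.approx(
            merged.identities * 1 + (merged.length - 3 - merged.identities) * -1 - 5 - 4
        )

    def test_adjacent_fragments_merge_without_new_gaps(self):
        read = "A" * 100
        genome = "A" * 200
        f1 = _frag(1, 1, 50, 11, 60)
        f2 = _frag(2, 51, 100, 61, 110)
        merged = merge_chain([f1, f2], read, genome, SCHEME)
        assert merged.length == 100 and merged.igaps == merged.egaps == 0
        assert merged.identities == 100

    def test_merge_associative_along_chain(self):
        rng = random.Random(5)
        genome = "".join(rng.choice("ACGT") for _ in range(400))
        read = genome[:120] + genome[125:240] + genome[243:360]
        f1 = _frag(1, 1, 120, 1, 120)
        f2 = Fragment(2, None, 115, 115, 100.0, 0, 0, FORWARD, 121, 235, 126, 240)
        f3 = Fragment(3, None, 117, 117, 100.0, 0, 0, FORWARD, 236, 352, 244, 360)
        left = merge_chain([merge_chain([f1, f2], read, genome, SCHEME), f3], read, genome, SCHEME)
        inner = merge_chain([f2, f3], read, genome, SCHEME)
        right = merge_chain([f1, inner], read, genome, SCHEME)
        for attr in ("identities", "length", "igaps", "egaps", "r_start", "r_end", "g_start", "g_end"):
            assert getattr(left, attr) == getattr(right, attr)


class TestExtendAll:
    def test_max_gap_zero_is_identity(self, small_run):
        groups = small_run["groups"]
        com = small_run["community"]
        out = extend_all(groups, small_run["reads"], com.genomes, SCHEME, max_gap=0)
        assert sum(g.n_fragments() for g in out) == sum(g.n_fragments() for g in groups)

    def test_fragment_count_never_increases(self, small_run):
        n_in = sum(g.n_fragments() for g in small_run["groups"])
        n_out = sum(g.n_fragments() for g in small_run["extended"])
        assert n_out <= n_in

    def test_split_indel_reads_remerge_to_truth(self):
        """Reads split into two HSPs around a planted indel merge back to the
        exact unsplit fragment statistics."""
        com = generate_community(2, 4_000, seed=3)
        reads, truth = generate_reads(
            com.genomes, [0.5, 0.5], 300, sub_rate=0.01, indel_rate=0.95, seed=4
        )
        split = simulate_fragments(truth, com, split_indel_hsps=True)
        whole = simulate_fragments(truth, com, split_indel_hsps=False)
        scheme = ScoreScheme()
        merged = extend_all(split, reads, com.genomes, scheme, max_gap=20)
        for grp_m, grp_w in zip(merged, whole):
            assert grp_m.read_id == grp_w.read_id
            for genome_id, frags_w in grp_w.per_genome.items():
                frags_m = grp_m.per_genome[genome_id]
                assert len(frags_m) == len(frags_w)
                for fm, fw in zip(frags_m, frags_w):
                    assert (fm.identities, fm.length, fm.igaps, fm.egaps) == (
                        fw.identities,
                        fw.length,
                        fw.igaps,
                        fw.egaps,
                    )
                    assert (fm.r_start, fm.r_end, fm.g_start, fm.g_end) == (
                        fw.r_start,
                        fw.r_end,
                        fw.g_start,
                        fw.g_end,
                    )

    def test_missing_sequences_pass_through_with_warning(self, table1_groups):
        with pytest.warns(UserWarning, match="no sequence"):
            out = extend_all(table1_groups, {}, {}, SCHEME, 20)
        assert sum(g.n_fragments() for g in out) == 2  # unextended
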