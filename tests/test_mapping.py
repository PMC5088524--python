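"""Mapping kernel: filters, option selection, oracle agreement, CSV round-trip."""

import io
import math
import random

import pytest

from glocalmap.fragments import FORWARD, Fragment, ReadMatchGroup, TaxonomyEntry
from glocalmap.mapping import (
    MappingParams,
    filter_fragments,
    map_all,
    read_mapping_csv,
    select_options,
    write_mapping_csv,
)
from glocalmap.scoring import ScoreScheme
from tests.conftest import read_overlaps_shared_block


def _frag(k, ident, length, r1=None, r2=None, g1=1, igaps=0, egaps=0, score=None):
    r1 = r1 or 1
    r2 = r2 or r1 + length - 1
    return Fragment(k, score, ident, length, 100.0 * ident / length, igaps, egaps,
                    FORWARD, r1, r2, g1, g1 + length - 1)


class TestFiltering:
    def test_coverage_ratio(self):
        f = _frag(1, 140, 145)
        assert filter_fragments([f], 250, 0.5, 0.0) == [f]  # 145/250 = 0.58
        assert filter_fragments([f], 250, 0.6, 0.0) == []

    def test_identity_ratio(self):
        f = _frag(1, 134, 145)  # 0.924
        assert filter_fragments([f], 145, 0.0, 0.95) == []
        assert filter_fragments([f], 145, 0.0, 0.9) == [f]

    def test_zero_thresholds_keep_everything(self):
        frags = [_frag(1, 10, 100), _frag(2, 1, 200)]
        assert filter_fragments(frags, 250, 0.0, 0.0) == frags

    def test_order_preserved(self):
        frags = [_frag(1, 200, 200), _frag(2, 180, 200), _frag(3, 190, 200)]
        assert [f.k for f in filter_fragments(frags, 200, 0.5, 0.5)] == [1, 2, 3]

    def test_bad_read_length(self):
        with pytest.raises(ValueError):
            filter_fragments([], 0, 0.5, 0.5)

    def test_coverage_may_exceed_one(self):
        # genome-side gaps inflate L beyond the read length; not capped
        f = Fragment(1, None, 100, 110, 90.9, 1, 9, FORWARD, 1, 100, 1, 110)
        assert filter_fragments([f], 100, 1.05, 0.0) == [f]


def _brute_force_options(group, scheme, tax, params):
    """Literal re-implementation of the decision procedure, kept independent:
    filter by the two ratios and the E-value ceiling, then repeatedly scan all
    surviving fragments of active genomes for the smallest E-value."""
    survivors = []
    for genome_id, frags in group.per_genome.items():
        for f in frags:
            if f.length / group.read_length < params.coverage_threshold:
                continue
            if f.identities / f.length < params.identity_threshold:
                continue
            ev = scheme.K * group.read_length * scheme.db_length * math.exp(-scheme.lam * f.score)
            if ev > scheme.max_evalue:
                continue
            survivors.append((genome_id, f, ev))
    chosen = []
    dead_genomes, dead_species = set(), set()
    for _ in range(params.n_options):
        best = None
        for genome_id, f, ev in survivors:
            if genome_id in dead_genomes:
                continue
            if params.collapse_strains and tax[genome_id].n in dead_species:
                continue
            key = (ev, -f.identities / f.length, -f.length, genome_id, f.k)
            if best is None or key < best[0]:
                best = (key, genome_id, f, ev)
        if best is None:
            break
        _, genome_id, f, ev = best
        chosen.append((genome_id, f.k, ev))
        dead_genomes.add(genome_id)
        dead_species.add(tax[genome_id].n)
    return chosen


class TestSelectOptions:
    TAX = {
        "A": TaxonomyEntry(1, 0, "A", "a", 1000),
        "B": TaxonomyEntry(2, 0, "B", "b", 1000),
        "C": TaxonomyEntry(3, 0, "C", "c", 1000),
    }

    def _scheme(self):
        return ScoreScheme(db_length=3000, max_evalue=1e-3).calibrate()

    def test_single_passing_fragment(self):
        grp = ReadMatchGroup("r", 100, {"A": [_frag(1, 95, 100, score=90.0)]})
        rec = select_options(grp, self._scheme(), self.TAX, MappingParams())
        assert [o.genome_id for o in rec.options] == ["A"]

    def test_options_ordered_by_evalue(self):
        grp = ReadMatchGroup(
            "r",
            100,
            {
                "B": [_frag(1, 90, 100, score=80.0)],
                "A": [_frag(1, 95, 100, score=90.0)],
                "C": [_frag(1, 85, 100, score=70.0)],
            },
        )
        rec = select_options(grp, self._scheme(), self.TAX, MappingParams())
        assert [o.genome_id for o in rec.options] == ["A", "B", "C"]
        assert rec.options[0].evalue <= rec.options[1].evalue <= rec.options[2].evalue

    def test_strain_collapse_skips_sister_strain(self):
        tax = {
            "A": TaxonomyEntry(7, 0, "A", "strain 1", 1000),
            "B": TaxonomyEntry(7, 1, "B", "strain 2", 1000),
            "C": TaxonomyEntry(9, 0, "C", "other", 1000),
        }
        grp = ReadMatchGroup(
            "r",
            100,
            {
                "A": [_frag(1, 95, 100, score=90.0)],
                "B": [_frag(1, 94, 100, score=88.0)],
                "C": [_frag(1, 80, 100, score=60.0)],
            },
        )
        rec = select_options(
            grp, self._scheme(), tax, MappingParams(collapse_strains=True)
        )
        assert [o.genome_id for o in rec.options] == ["A", "C"]
        rec = select_options(grp, self._scheme(), tax, MappingParams())
        assert [o.genome_id for o in rec.options] == ["A", "B", "C"]

    def test_no_candidates_gives_empty_record(self):
        grp = ReadMatchGroup("r", 100, {"A": [_frag(1, 40, 100, score=-20.0)]})
        rec = select_options(grp, self._scheme(), self.TAX, MappingParams())
        assert rec.options == []

    def test_agrees_with_brute_force_on_randomized_instances(self):
        """500 random toy instances (≤5 genomes, ≤10 fragments, ties likely,
        with and without strain collapse) against the literal re-implementation."""
        rng = random.Random(2024)
        scheme = ScoreScheme(db_length=5000, max_evalue=1e-2).calibrate()
        for trial in range(500):
            n_genomes = rng.randint(1, 5)
            genomes = [f"g{i}" for i in range(n_genomes)]
            tax = {
                g: TaxonomyEntry(rng.randint(1, 3), i, g, g, 1000)
                for i, g in enumerate(genomes)
            }
            read_length = rng.choice([100, 150])
            grp = ReadMatchGroup(f"r{trial}", read_length)
            counters = dict.fromkeys(genomes, 0)
            for _ in range(rng.randint(0, 10)):
                g = rng.choice(genomes)
                length = rng.choice([60, 80, 100])
                ident = rng.choice([length, length - 5, length - 20, length // 2])
                counters[g] += 1
                f = _frag(counters[g], ident, length)
                f.score = float(
                    rng.choice([ident - (length - ident), 50, 60, 60, 70])
                )
                grp.add(g, f)
            params = MappingParams(
                n_options=rng.randint(1, 3),
                coverage_threshold=rng.choice([0.0, 0.5, 0.7]),
                identity_threshold=rng.choice([0.0, 0.7, 0.9]),
                collapse_strains=rng.random() < 0.5,
            )
            expected = _brute_force_options(grp, scheme, tax, params)
            rec = select_options(grp, scheme, tax, params)
            got = [(o.genome_id, o.fragment.k, o.evalue) for o in rec.options]
            assert [(g, k) for g, k, _ in got] == [(g, k) for g, k, _ in expected], (
                trial,
                got,
                expected,
            )
            for (_, _, ev_got), (_, _, ev_exp) in zip(got, expected):
                assert ev_got == pytest.approx(ev_exp)


class TestMapAll:
    def test_empty_input(self, scheme):
        records, summary = map_all([], scheme, [TaxonomyEntry(1, 0, "A", "a", 100)])
        assert records == [] and summary["mapped"] == 0

    def test_unknown_genome_raises_listing_accession(self, scheme):
        grp = ReadMatchGroup("r", 100, {"MYSTERY": [_frag(1, 95, 100, score=90.0)]})
        with pytest.raises(KeyError, match="MYSTERY"):
            map_all([grp], scheme, [TaxonomyEntry(1, 0, "A", "a", 100)])

    def test_unambiguous_synthetic_reads_map_to_origin(self, small_run):
        truth = small_run["truth"].by_id()
        com = small_run["community"]
        for rec in small_run["records"]:
            t = truth[rec.read_id]
            if read_overlaps_shared_block(t, com):
                continue
            assert rec.mapped and rec.options[0].genome_id == t.genome_id

    def test_raising_identity_threshold_shrinks_mapped_set(self, small_run):
        scheme = small_run["scheme"]
        tax = small_run["taxonomy"]
        groups = small_run["extended"]
        mapped = {}
        for thr in (0.7, 0.9, 0.97):
            records, summary = map_all(
                groups, scheme, tax, MappingParams(identity_threshold=thr)
            )
            mapped[thr] = {r.read_id for r in records if r.mapped}
        assert mapped[0.97] <= mapped[0.9] <= mapped[0.7]

    def test_evalues_non_decreasing_within_records(self, small_run):
        for rec in small_run["records"]:
            evs = [o.evalue for o in rec.options]
            assert evs == sorted(evs)

    def test_option_genomes_distinct_within_records(self, small_run):
        for rec in small_run["records"]:
            ids = [o.genome_id for o in rec.options]
            assert len(ids) == len(set(ids))


class TestMappingCsv:
    def test_round_trip(self, small_run):
        records = small_run["records"][:50]
        text = write_mapping_csv(records)
        back = read_mapping_csv(io.StringIO(text))
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert a.read_id == b.read_id and a.read_length == b.read_length
            assert len(a.options) == len(b.options)
            for oa, ob in zip(a.options, b.options):
                assert oa.genome_id == ob.genome_id
                assert oa.evalue == pytest.approx(ob.evalue)
                assert oa.fragment.length == ob.fragment.length
                assert oa.fragment.g_start == ob.fragment.g_start
                assert oa.fragment.strand == ob.fragment.strand

    def test_unmapped_read_row_has_only_read_columns(self):
        from glocalmap.mapping import MappingRecord

        text = write_mapping_csv([MappingRecord("lonely", 180)])
        row = text.splitlines()[1].split(",")
        assert row[0] == "lonely" and all(c == "" for c in row[2:])
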