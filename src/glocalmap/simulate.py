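"""Synthetic communities with ground truth.

Generates a small collection of i.i.d.-nucleotide genomes with planted
shared (conserved) blocks between chosen genome pairs and unique inserts
guaranteed absent from every other genome; samples reads multinomially by
abundance with substitution and single-indel errors at recorded positions;
and emits fragment files directly from the ground truth, bypassing external
aligners: each read yields its true-origin alignment (optionally split into
two ungapped HSPs around an indel, the situation the glocal extension is
built for) plus spurious alignments against the partner genome wherever the
read overlaps a shared block.

Because every error position is recorded, all fragment statistics
(identities, length, gap counts) are computed exactly, which makes the
generator the oracle for the downstream mapping stages.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from glocalmap.fragments import FORWARD, REVERSE, Fragment, ReadMatchGroup, TaxonomyEntry

__all__ = [
    "SharedBlock",
    "UniqueInsert",
    "SyntheticCommunity",
    "TruthRead",
    "SyntheticTruth",
    "generate_community",
    "generate_reads",
    "simulate_fragments",
    "community_taxonomy",
]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = str.maketrans("ACGT", "TGCA")

#: k-mer size used for the unique-insert guarantee.
UNIQUE_K = 16

#: Minimum block overlap (bp) for a spurious cross-genome fragment to be emitted.
MIN_SPURIOUS_OVERLAP = 20

INDEL_LENGTH_RANGE = (1, 5)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SharedBlock:
    """A block copied verbatim between two genomes (1-based starts)."""

    genome_a: str
    genome_b: str
    length: int
    start_a: int
    start_b: int


@dataclass(frozen=True)
class UniqueInsert:
    """A stretch present in exactly one genome (no 16-mer shared elsewhere)."""

    genome: str
    length: int
    start: int

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass
class SyntheticCommunity:
    genomes: dict[str, str]
    blocks: list[SharedBlock]
    inserts: list[UniqueInsert]
    seed: int


@dataclass(frozen=True)
class TruthRead:
    """Ground truth of one simulated read.

    ``start``/``end`` bound the origin interval on the forward genome axis;
    ``subs`` are the absolute genome positions carrying a planted
    substitution; ``event`` is ``None`` or ``(kind, offset, length)`` with
    ``kind`` in {del, ins} and ``offset`` the number of aligned genome bases
    of the interval before the event.
    """

    read_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    read_length: int
    subs: tuple[int, ...] = ()
    event: tuple[str, int, int] | None = None


@dataclass
class SyntheticTruth:
    reads: list[TruthRead] = field(default_factory=list)

    def by_id(self) -> dict[str, TruthRead]:
        return {t.read_id: t for t in self.reads}

    def to_csv(self, stream=None) -> str:
        out = io.StringIO()
        out.write("read_id,genome,start,end,strand,read_length,subs,event\n")
        for t in self.reads:
            ev = "" if t.event is None else f"{t.event[0]}:{t.event[1]}:{t.event[2]}"
            subs = ";".join(map(str, t.subs))
            out.write(
                f"{t.read_id},{t.genome_id},{t.start},{t.end},{t.strand},"
                f"{t.read_length},{subs},{ev}\n"
            )
        text = out.getvalue()
        if stream is not None:
            stream.write(text)
        return text

    @classmethod
    def from_csv(cls, source) -> "SyntheticTruth":
        if isinstance(source, str) and "\n" in source:
            source = io.StringIO(source)
        elif isinstance(source, str):
            source = open(source)
        truth = cls()
        header = True
        for line in source:
            if header:
                header = False
                continue
            if not line.strip():
                continue
            rid, gid, start, end, strand, rlen, subs, ev = line.rstrip("\n").split(",")
            event = None
            if ev:
                kind, off, ln = ev.split(":")
                event = (kind, int(off), int(ln))
            truth.reads.append(
                TruthRead(
                    rid,
                    gid,
                    int(start),
                    int(end),
                    strand,
                    int(rlen),
                    tuple(int(s) for s in subs.split(";") if s),
                    event,
                )
            )
        return truth


# ---------------------------------------------------------------------------
# community generation


def _random_genome(rng: np.random.Generator, length: int) -> np.ndarray:
    return _ALPHABET[rng.integers(0, 4, size=length)]


def _place(
    rng: np.random.Generator,
    genome_length: int,
    length: int,
    occupied: list[tuple[int, int]],
    fixed: int | None,
    attempts: int = 200,
) -> int:
    """Pick a 1-based start for a block of ``length`` avoiding occupied spans."""
    if length > genome_length:
        raise ValueError(f"block of {length} bp does not fit a {genome_length} bp genome")

    def clashes(s: int) -> bool:
        e = s + length - 1
        return any(s <= oe and e >= os_ for os_, oe in occupied)

    if fixed is not None:
        if fixed < 1 or fixed + length - 1 > genome_length or clashes(fixed):
            raise ValueError(f"cannot place block of {length} bp at position {fixed}")
        return fixed
    for _ in range(attempts):
        s = int(rng.integers(1, genome_length - length + 2))
        if not clashes(s):
            return s
    raise ValueError(f"no room for a block of {length} bp after {attempts} attempts")


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def generate_community(
    n_genomes: int,
    genome_length: int,
    shared_blocks: list[tuple] | None = None,
    unique_inserts: list[tuple] | None = None,
    seed: int = 0,
) -> SyntheticCommunity:
    """Generate genomes ``G1..Gn`` with planted shared blocks and unique inserts.

    ``shared_blocks`` entries are ``(genomeA, genomeB, length)`` with
    optional trailing ``startA, startB`` (1-based; ``None`` → random
    non-overlapping placement).  ``unique_inserts`` entries are
    ``(genome, length)`` with an optional fixed start.  Shared blocks are
    copied verbatim; unique inserts are regenerated until none of their
    16-mers (either strand) occurs in any other genome.  Deterministic for
    a fixed seed.
    """
    if n_genomes < 1 or genome_length < 1:
        raise ValueError("need at least one genome of positive length")
    rng = np.random.default_rng(seed)
    names = [f"G{i}" for i in range(1, n_genomes + 1)]
    arrays = {g: _random_genome(rng, genome_length) for g in names}
    occupied: dict[str, list[tuple[int, int]]] = {g: [] for g in names}

    blocks: list[SharedBlock] = []
    for spec in shared_blocks or []:
        ga, gb, length = spec[0], spec[1], int(spec[2])
        fixed_a = spec[3] if len(spec) > 3 else None
        fixed_b = spec[4] if len(spec) > 4 else None
        if ga not in arrays or gb not in arrays or ga == gb:
            raise ValueError(f"bad shared-block pair ({ga!r}, {gb!r})")
        sa = _place(rng, genome_length, length, occupied[ga], fixed_a)
        sb = _place(rng, genome_length, length, occupied[gb], fixed_b)
        arrays[gb][sb - 1 : sb - 1 + length] = arrays[ga][sa - 1 : sa - 1 + length]
        occupied[ga].append((sa, sa + length - 1))
        occupied[gb].append((sb, sb + length - 1))
        blocks.append(SharedBlock(ga, gb, length, sa, sb))

    inserts: list[UniqueInsert] = []
    for spec in unique_inserts or []:
        g, length = spec[0], int(spec[1])
        fixed = spec[2] if len(spec) > 2 else None
        if g not in arrays:
            raise ValueError(f"unknown genome {g!r} for unique insert")
        if length < UNIQUE_K:
            raise ValueError(f"unique insert must be at least {UNIQUE_K} bp")
        start = _place(rng, genome_length, length, occupied[g], fixed)
        others_kmers: set[str] = set()
        for og, arr in arrays.items():
            if og == g:
                continue
            s = arr.tobytes().decode()
            others_kmers |= _kmers(s, UNIQUE_K)
            others_kmers |= _kmers(_revcomp(s), UNIQUE_K)
        for _ in range(100):
            cand = _random_genome(rng, length)
            cs = cand.tobytes().decode()
            if not (_kmers(cs, UNIQUE_K) | _kmers(_revcomp(cs), UNIQUE_K)) & others_kmers:
                break
        else:  # pragma: no cover - astronomically unlikely for sane sizes
            raise ValueError("failed to draw a unique insert; genomes too large or insert too short")
        arrays[g][start - 1 : start - 1 + length] = cand
        occupied[g].append((start, start + length - 1))
        inserts.append(UniqueInsert(g, length, start))

    genomes = {g: arr.tobytes().decode() for g, arr in arrays.items()}
    return SyntheticCommunity(genomes=genomes, blocks=blocks, inserts=inserts, seed=seed)


def community_taxonomy(community: SyntheticCommunity) -> list[TaxonomyEntry]:
    return [
        TaxonomyEntry(n=i, m=0, accession=g, name=f"synthetic genome {g}", length=len(seq))
        for i, (g, seq) in enumerate(community.genomes.items(), start=1)
    ]


# ---------------------------------------------------------------------------
# read generation

DEFAULT_LENGTH_RANGE = (172, 237)
DEFAULT_SUB_RATE = 0.02


def generate_reads(
    genomes: dict[str, str],
    abundances,
    n_reads: int,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    sub_rate: float = DEFAULT_SUB_RATE,
    indel_rate: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Sample reads multinomially by abundance with planted errors.

    Starts are uniform, lengths uniform in ``length_range``, each read is
    reverse-complemented with probability 1/2, substitutions hit aligned
    positions at ``sub_rate``, and with probability ``indel_rate`` a read
    carries one insertion or deletion of 1-5 bp (single-event model, so the
    alignment statistics stay exactly computable).  Returns the reads and
    their ground truth.
    """
    names = list(genomes)
    abundances = list(abundances)
    if len(abundances) != len(names):
        raise ValueError("need one abundance per genome")
    if abs(sum(abundances) - 1.0) > 1e-9 or min(abundances) < 0:
        raise ValueError("abundances must be non-negative and sum to 1")
    if not (0 <= sub_rate < 1 and 0 <= indel_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError("bad length range")
    max_glen = hi + INDEL_LENGTH_RANGE[1]
    for g in names:
        if max_glen > len(genomes[g]):
            raise ValueError(f"read length may exceed genome {g!r} length")

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, abundances)
    reads: dict[str, str] = {}
    truth = SyntheticTruth()
    idx = 0
    for g, cnt in zip(names, counts):
        seq = genomes[g]
        glen_total = len(seq)
        for _ in range(cnt):
            idx += 1
            rid = f"R{idx:06d}"
            rlen = int(rng.integers(lo, hi + 1))
            event: tuple[str, int, int] | None = None
            g_len = rlen
            if indel_rate > 0 and rng.random() < indel_rate and rlen >= INDEL_LENGTH_RANGE[1] + 2:
                kind = "del" if rng.random() < 0.5 else "ins"
                ev_len = int(rng.integers(INDEL_LENGTH_RANGE[0], INDEL_LENGTH_RANGE[1] + 1))
                if kind == "del":
                    g_len = rlen + ev_len
                    offset = int(rng.integers(1, rlen))  # aligned bases before the event
                else:
                    g_len = rlen - ev_len
                    offset = int(rng.integers(1, g_len))
                event = (kind, offset, ev_len)
            start = int(rng.integers(1, glen_total - g_len + 2))
            end = start + g_len - 1
            segment = np.frombuffer(seq[start - 1 : end].encode(), dtype=np.uint8).copy()

            if event is None:
                aligned_abs = np.arange(start, end + 1)
                read_arr = segment
            elif event[0] == "del":
                _, offset, ev_len = event
                keep = np.concatenate(
                    [np.arange(0, offset), np.arange(offset + ev_len, g_len)]
                )
                aligned_abs = keep + start
                read_arr = segment[keep]
            else:
                _, offset, ev_len = event
                aligned_abs = np.arange(start, end + 1)
                ins = _random_genome(rng, ev_len)
                read_arr = np.concatenate([segment[:offset], ins, segment[offset:]])

            # substitutions on aligned positions only (inserted bases are
            # already gap columns, deleted ones are absent from the read)
            hit = rng.random(aligned_abs.size) < sub_rate
            sub_positions = tuple(int(p) for p in aligned_abs[hit])
            if sub_positions:
                if event is None:
                    read_offsets = aligned_abs[hit] - start
                elif event[0] == "del":
                    offs = aligned_abs[hit] - start
                    read_offsets = np.where(offs >= event[1] + event[2], offs - event[2], offs)
                else:
                    offs = aligned_abs[hit] - start
                    read_offsets = np.where(offs >= event[1], offs + event[2], offs)
                for ro in read_offsets:
                    old = read_arr[ro]
                    choices = _ALPHABET[_ALPHABET != old]
                    read_arr[ro] = choices[rng.integers(0, 3)]

            strand = FORWARD if rng.random() < 0.5 else REVERSE
            read_seq = read_arr.tobytes().decode()
            if strand == REVERSE:
                read_seq = _revcomp(read_seq)
            reads[rid] = read_seq
            truth.reads.append(
                TruthRead(
                    read_id=rid,
                    genome_id=g,
                    start=start,
                    end=end,
                    strand=strand,
                    read_length=len(read_seq),
                    subs=sub_positions,
                    event=event,
                )
            )
    return reads, truth


# ---------------------------------------------------------------------------
# fragment simulation


def _read_offset(t: TruthRead, g_pos: int) -> int:
    """Pre-reverse-complement 1-based read position of aligned genome position."""
    off = g_pos - t.start + 1
    if t.event is None:
        return off
    kind, ev_off, ev_len = t.event
    if kind == "del":
        return off - ev_len if g_pos - t.start >= ev_off + ev_len else off
    return off + ev_len if g_pos - t.start >= ev_off else off


def _interval_fragments(
    t: TruthRead,
    a: int,
    b: int,
    split: bool,
) -> list[tuple[int, int, int, int, int, int]]:
    """Fragment stats (r1, r2, I, L, igaps, egaps) for genome interval [a, b].

    Pre-reverse-complement read coordinates; the caller flips them for
    reverse-strand reads.  The interval is snapped off deleted positions at
    its edges so alignments never start or end in a gap.
    """
    kind, ev_off, ev_len = t.event if t.event else (None, 0, 0)
    if kind == "del":
        ds = t.start + ev_off
        de = ds + ev_len - 1
        if a >= ds and a <= de:
            a = de + 1
        if b >= ds and b <= de:
            b = ds - 1
    if a > b:
        return []

    def subs_in(x: int, y: int) -> int:
        return sum(1 for p in t.subs if x <= p <= y)

    if kind == "del":
        ds = t.start + ev_off
        de = ds + ev_len - 1
        inside = a < ds and b > de
        if inside:
            if split:
                return _interval_fragments(t, a, ds - 1, split) + _interval_fragments(
                    t, de + 1, b, split
                )
            aligned = (b - a + 1) - ev_len
            ident = aligned - subs_in(a, b)
            return [(_read_offset(t, a), _read_offset(t, b), ident, b - a + 1, 1, ev_len - 1)]
    elif kind == "ins":
        boundary = t.start + ev_off  # insertion sits before this genome position
        inside = a < boundary <= b
        if inside:
            if split:
                return _interval_fragments(t, a, boundary - 1, split) + _interval_fragments(
                    t, boundary, b, split
                )
            aligned = b - a + 1
            ident = aligned - subs_in(a, b)
            return [(_read_offset(t, a), _read_offset(t, b), ident, aligned + ev_len, 1, ev_len - 1)]
    aligned = b - a + 1
    ident = aligned - subs_in(a, b)
    return [(_read_offset(t, a), _read_offset(t, b), ident, aligned, 0, 0)]


def _emit(
    group: ReadMatchGroup,
    genome_id: str,
    t: TruthRead,
    stats: list[tuple[int, int, int, int, int, int]],
    g_intervals: list[tuple[int, int]],
) -> None:
    existing = len(group.per_genome.get(genome_id, []))
    items = list(zip(stats, g_intervals))
    if t.strand == REVERSE:
        items = items[::-1]
    for j, ((r1, r2, ident, length, igaps, egaps), (ga, gb)) in enumerate(items):
        if t.strand == REVERSE:
            r1, r2 = t.read_length - r2 + 1, t.read_length - r1 + 1
        group.add(
            genome_id,
            Fragment(
                k=existing + j + 1,
                score=None,
                identities=ident,
                length=length,
                similarity=100.0 * ident / length,
                igaps=igaps,
                egaps=egaps,
                strand=t.strand,
                r_start=r1,
                r_end=r2,
                g_start=ga,
                g_end=gb,
            ),
        )


def _genome_intervals(t: TruthRead, a: int, b: int, split: bool) -> list[tuple[int, int]]:
    """Genome intervals matching the fragments of ``_interval_fragments``."""
    kind, ev_off, ev_len = t.event if t.event else (None, 0, 0)
    if kind == "del":
        ds, de = t.start + ev_off, t.start + ev_off + ev_len - 1
        if ds <= a <= de:
            a = de + 1
        if ds <= b <= de:
            b = ds - 1
        if a > b:
            return []
        if split and a < ds and b > de:
            return [(a, ds - 1), (de + 1, b)]
    elif kind == "ins":
        boundary = t.start + ev_off
        if split and a < boundary <= b:
            return [(a, boundary - 1), (boundary, b)]
    if a > b:
        return []
    return [(a, b)]


def simulate_fragments(
    truth: SyntheticTruth,
    community: SyntheticCommunity,
    split_indel_hsps: bool = False,
) -> list[ReadMatchGroup]:
    """Emit the fragment file implied by the ground truth.

    Per read: the true-origin alignment (two flanking ungapped HSPs instead,
    when ``split_indel_hsps`` and the read carries an indel), plus a
    spurious fragment against the partner genome for every shared block the
    read overlaps by at least ``MIN_SPURIOUS_OVERLAP`` aligned bases —
    mimicking what a local aligner reports for conserved regions.
    """
    # per-genome translation maps to shared-block partners
    partner_blocks: dict[str, list[tuple[int, int, str, int]]] = {}
    for blk in community.blocks:
        partner_blocks.setdefault(blk.genome_a, []).append(
            (blk.start_a, blk.start_a + blk.length - 1, blk.genome_b, blk.start_b - blk.start_a)
        )
        partner_blocks.setdefault(blk.genome_b, []).append(
            (blk.start_b, blk.start_b + blk.length - 1, blk.genome_a, blk.start_a - blk.start_b)
        )

    groups: list[ReadMatchGroup] = []
    for t in truth.reads:
        grp = ReadMatchGroup(t.read_id, t.read_length)
        stats = _interval_fragments(t, t.start, t.end, split_indel_hsps)
        ivals = _genome_intervals(t, t.start, t.end, split_indel_hsps)
        _emit(grp, t.genome_id, t, stats, ivals)
        for bs, be, partner, shift in partner_blocks.get(t.genome_id, []):
            oa, ob = max(t.start, bs), min(t.end, be)
            if ob - oa + 1 < MIN_SPURIOUS_OVERLAP:
                continue
            stats = _interval_fragments(t, oa, ob, split_indel_hsps)
            ivals = [
                (ga + shift, gb + shift) for ga, gb in _genome_intervals(t, oa, ob, split_indel_hsps)
            ]
            _emit(grp, partner, t, stats, ivals)
        groups.append(grp)
    return groups
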