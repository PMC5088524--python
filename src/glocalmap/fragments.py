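"""Fragment, taxonomy and annotation file formats.

A *fragment* is one (possibly extended) local alignment between a read and a
genome, carried as a 12-tuple: ordinal ``k`` within the read-genome pair, raw
score, identities ``I``, alignment length ``L`` in columns, percent
similarity, opened gaps ``G_i``, extension gaps ``G_e``, strand, and the read
and genome anchoring coordinates.  Fragment files are plain text: a header
line per read-genome pair followed by one tab-separated 12-field row per
fragment.

Coordinates are 1-based and inclusive on both ends.  Reverse-strand
fragments store ascending forward-axis genome coordinates plus the strand
flag, so a single sort order and plain interval arithmetic apply to both
orientations.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO

FORWARD = "+"
REVERSE = "-"

#: Header/field separator of the fragment-file dialect.
_HDR_SEP = " — "


class FragmentFormatError(ValueError):
    """Raised for malformed fragment, taxonomy or annotation input."""


@dataclass
class Fragment:
    """One read-genome alignment (the 12-tuple plus bookkeeping flags).

    ``score=None`` means "to be recomputed" and is serialized as ``-``,
    which is how unscored fragments appear before affine rescoring.
    ``gap_detail_known=False`` marks fragments converted from formats that
    do not separate gap openings from extensions (BLAST tabular); rescoring
    then treats every gap column as an opening.
    """

    k: int
    score: float | None
    identities: int
    length: int
    similarity: float
    igaps: int
    egaps: int
    strand: str
    r_start: int
    r_end: int
    g_start: int
    g_end: int
    gap_detail_known: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise FragmentFormatError(f"fragment ordinal k must be >= 1, got {self.k}")
        if self.strand not in (FORWARD, REVERSE):
            raise FragmentFormatError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.r_start > self.r_end:
            raise FragmentFormatError(
                f"read coordinates must be ascending, got {self.r_start}..{self.r_end}"
            )
        if self.g_start > self.g_end:
            raise FragmentFormatError(
                f"genome coordinates must be ascending, got {self.g_start}..{self.g_end}"
            )
        if min(self.identities, self.igaps, self.egaps) < 0 or self.length < 1:
            raise FragmentFormatError("negative alignment statistics")
        if self.identities > self.length:
            raise FragmentFormatError(
                f"identities ({self.identities}) exceed length ({self.length})"
            )
        if self.identities + self.igaps + self.egaps > self.length:
            raise FragmentFormatError("identities + gap columns exceed alignment length")

    @property
    def mismatches(self) -> int:
        return self.length - (self.igaps + self.egaps) - self.identities

    @property
    def identity_frac(self) -> float:
        return self.identities / self.length

    def coverage(self, read_length: int) -> float:
        """Match length over read length; may exceed 1 with genome-side gaps."""
        return self.length / read_length


@dataclass
class ReadMatchGroup:
    """All fragments reported for one read, keyed by genome accession."""

    read_id: str
    read_length: int | None = None
    per_genome: dict[str, list[Fragment]] = field(default_factory=dict)

    def add(self, genome_id: str, fragment: Fragment) -> None:
        self.per_genome.setdefault(genome_id, []).append(fragment)

    def n_fragments(self) -> int:
        return sum(len(v) for v in self.per_genome.values())


@dataclass(frozen=True)
class TaxonomyEntry:
    """One reference genome: species id ``n``, strain id ``m``, accession, name, length."""

    n: int
    m: int
    accession: str
    name: str
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise FragmentFormatError(f"genome length must be >= 1, got {self.length}")


@dataclass(frozen=True)
class AnnotationInterval:
    """A labeled feature interval on a genome, 1-based inclusive."""

    genome_id: str
    start: int
    end: int
    strand: str = "?"
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise FragmentFormatError(
                f"bad annotation interval {self.start}..{self.end} on {self.genome_id}"
            )


# ---------------------------------------------------------------------------
# fragment files


def _parse_score(tok: str) -> float | None:
    return None if tok == "-" else float(tok)


def _parse_strand(tok: str) -> str:
    t = tok.strip()
    if t in (FORWARD, "Plus/Plus", "Plus\\Plus", "Plus∖Plus", "forward"):
        return FORWARD
    if t in (REVERSE, "Plus/Minus", "Plus\\Minus", "Plus∖Minus", "reverse"):
        return REVERSE
    raise FragmentFormatError(f"unrecognized strand field {tok!r}")


def parse_fragment_file(stream) -> list[ReadMatchGroup]:
    """Parse a fragment file into per-read match groups.

    ``stream`` is an iterable of lines (or an open text file).  Header lines
    start with ``>`` and carry ``readId — genomeId — genome name`` (an
    optional fourth ``len=<bp>`` field records the read length).  Groups
    preserve input order; a header without rows yields an empty genome entry
    and a warning.
    """
    groups: dict[str, ReadMatchGroup] = {}
    order: list[str] = []
    cur: tuple[str, str] | None = None
    had_rows = True
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        if line.startswith(">"):
            if cur is not None and not had_rows:
                warnings.warn(f"header for {cur} has no fragment rows", stacklevel=2)
            fields = [f.strip() for f in line[1:].split(_HDR_SEP)]
            if len(fields) < 2:
                raise FragmentFormatError(f"line {lineno}: header needs readId and genomeId")
            read_id, genome_id = fields[0], fields[1]
            read_len = None
            for extra in fields[2:]:
                if extra.startswith("len="):
                    read_len = int(extra[4:])
            if read_id not in groups:
                groups[read_id] = ReadMatchGroup(read_id, read_len)
                order.append(read_id)
            elif read_len is not None:
                groups[read_id].read_length = read_len
            groups[read_id].per_genome.setdefault(genome_id, [])
            cur = (read_id, genome_id)
            had_rows = False
            continue
        if cur is None:
            raise FragmentFormatError(f"line {lineno}: fragment row before any header")
        toks = line.split("\t")
        if len(toks) != 12:
            raise FragmentFormatError(
                f"line {lineno}: expected 12 tab-separated fields, got {len(toks)}"
            )
        try:
            frag = Fragment(
                k=int(toks[0]),
                score=_parse_score(toks[1]),
                identities=int(toks[2]),
                length=int(toks[3]),
                similarity=float(toks[4]),
                igaps=int(toks[5]),
                egaps=int(toks[6]),
                strand=_parse_strand(toks[7]),
                r_start=int(toks[8]),
                r_end=int(toks[9]),
                g_start=int(toks[10]),
                g_end=int(toks[11]),
            )
        except (ValueError, FragmentFormatError) as exc:
            raise FragmentFormatError(f"line {lineno}: {exc}") from exc
        groups[cur[0]].add(cur[1], frag)
        had_rows = True
    if cur is not None and not had_rows:
        warnings.warn(f"header for {cur} has no fragment rows", stacklevel=2)
    return [groups[r] for r in order]


def _fmt_score(score: float | None) -> str:
    if score is None:
        return "-"
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def write_fragment_file(groups, stream=None, genome_names: dict[str, str] | None = None) -> str:
    """Serialize match groups back to the fragment-file dialect.

    Groups (and per-genome entries) with zero fragments are omitted.
    Returns the text; also writes it to ``stream`` when given.
    """
    out = io.StringIO()
    names = genome_names or {}
    for grp in groups:
        for genome_id, frags in grp.per_genome.items():
            if not frags:
                continue
            hdr = [grp.read_id, genome_id, names.get(genome_id, genome_id)]
            if grp.read_length is not None:
                hdr.append(f"len={grp.read_length}")
            out.write(">" + _HDR_SEP.join(hdr) + "\n")
            for f in frags:
                row = [
                    str(f.k),
                    _fmt_score(f.score),
                    str(f.identities),
                    str(f.length),
                    f"{f.similarity:.2f}",
                    str(f.igaps),
                    str(f.egaps),
                    "Plus/Plus" if f.strand == FORWARD else "Plus/Minus",
                    str(f.r_start),
                    str(f.r_end),
                    str(f.g_start),
                    str(f.g_end),
                ]
                out.write("\t".join(row) + "\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# BLAST tabular conversion


def convert_blast_tabular(stream, read_lengths: dict[str, int]) -> list[ReadMatchGroup]:
    """Convert 12-column BLAST tabular output (outfmt-6-like) to match groups.

    Identities are recovered as ``round(%identity * length / 100)``; opened
    gaps come from the gap-opens column and extension gaps are set to 0 with
    the ``gap_detail_known`` flag cleared, since the tabular dialect does not
    report per-column gap extensions.  ``sstart > send`` flags the reverse
    strand and the genome coordinates are normalized ascending.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    groups: dict[str, ReadMatchGroup] = {}
    order: list[str] = []
    counters: dict[tuple[str, str], int] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split("\t")
        if len(toks) != 12:
            raise FragmentFormatError(
                f"line {lineno}: BLAST tabular needs 12 columns, got {len(toks)}"
            )
        qid, sid = toks[0], toks[1]
        if qid not in read_lengths:
            raise FragmentFormatError(f"line {lineno}: read {qid!r} absent from read lengths")
        pident = float(toks[2])
        length = int(toks[3])
        gap_opens = int(toks[5])
        qstart, qend = int(toks[6]), int(toks[7])
        sstart, send = int(toks[8]), int(toks[9])
        strand = FORWARD if sstart <= send else REVERSE
        g_start, g_end = min(sstart, send), max(sstart, send)
        identities = min(length, round(pident * length / 100.0))
        key = (qid, sid)
        counters[key] = counters.get(key, 0) + 1
        frag = Fragment(
            k=counters[key],
            score=None,
            identities=identities,
            length=length,
            similarity=pident,
            igaps=gap_opens,
            egaps=0,
            strand=strand,
            r_start=min(qstart, qend),
            r_end=max(qstart, qend),
            g_start=g_start,
            g_end=g_end,
            gap_detail_known=False,
        )
        if qid not in groups:
            groups[qid] = ReadMatchGroup(qid, read_lengths[qid])
            order.append(qid)
        groups[qid].add(sid, frag)
    return [groups[r] for r in order]


# ---------------------------------------------------------------------------
# taxonomy


def build_taxonomy(
    genomes,
    grouping: dict[str, tuple[int, int]] | None = None,
) -> list[TaxonomyEntry]:
    """Build taxonomy entries from ``(accession, name, length)`` triples.

    Without ``grouping`` each genome gets a distinct species id ``n`` (1-based
    input order) and strain id ``m=0``; with it, the supplied ``(n, m)`` pairs
    are used verbatim, which is how strain relationships between genomes are
    expressed (same ``n``, different ``m``).
    """
    entries: list[TaxonomyEntry] = []
    seen_nm: set[tuple[int, int]] = set()
    seen_acc: set[str] = set()
    for i, (acc, name, length) in enumerate(genomes, start=1):
        if acc in seen_acc:
            raise FragmentFormatError(f"duplicate accession {acc!r}")
        seen_acc.add(acc)
        n, m = grouping[acc] if grouping else (i, 0)
        if (n, m) in seen_nm:
            raise FragmentFormatError(f"duplicate (n, m) pair ({n}, {m})")
        seen_nm.add((n, m))
        entries.append(TaxonomyEntry(n=n, m=m, accession=acc, name=name, length=int(length)))
    return entries


def write_taxonomy_file(entries, stream=None) -> str:
    out = io.StringIO()
    for e in entries:
        out.write(f"{e.n}\t{e.m}\t{e.accession}\t{e.name}\t{e.length}\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def parse_taxonomy_file(stream) -> list[TaxonomyEntry]:
    """Parse the 5-tuple-per-line taxonomy file (n, m, accession, name, length)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    entries = []
    seen_nm: set[tuple[int, int]] = set()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        toks = line.split("\t")
        if len(toks) != 5:
            raise FragmentFormatError(f"line {lineno}: taxonomy needs 5 fields, got {len(toks)}")
        try:
            e = TaxonomyEntry(int(toks[0]), int(toks[1]), toks[2], toks[3], int(toks[4]))
        except ValueError as exc:
            raise FragmentFormatError(f"line {lineno}: {exc}") from exc
        if (e.n, e.m) in seen_nm:
            raise FragmentFormatError(f"line {lineno}: duplicate (n, m) pair ({e.n}, {e.m})")
        seen_nm.add((e.n, e.m))
        entries.append(e)
    return entries


def taxonomy_index(entries) -> dict[str, TaxonomyEntry]:
    return {e.accession: e for e in entries}


def total_reference_length(entries) -> int:
    """Total reference length n used in the E-value K·m·n·e^(−λ·RS)."""
    return sum(e.length for e in entries)


# ---------------------------------------------------------------------------
# annotations


def parse_annotations(stream, genome_lengths: dict[str, int] | None = None) -> list[AnnotationInterval]:
    """Parse feature intervals from a GFF3 subset or a 5-column table.

    GFF3 rows use columns 1 (seqid), 4 (start), 5 (end), 7 (strand) and, when
    present, the ``ID=``/``Name=`` attribute as label.  The simplified table
    is ``genomeId<TAB>start<TAB>end<TAB>strand<TAB>label``.  Intervals are
    clipped to ``[1, genome length]`` when the genome length is known.
    Overlapping features are all retained.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out: list[AnnotationInterval] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        toks = line.split("\t")
        if len(toks) >= 8:  # GFF3 row
            gid, start, end, strand = toks[0], toks[3], toks[4], toks[6]
            label = ""
            if len(toks) >= 9:
                for attr in toks[8].split(";"):
                    if attr.startswith(("ID=", "Name=")):
                        label = attr.split("=", 1)[1]
                        break
            if not label:
                label = toks[2]
        elif len(toks) == 5:
            gid, start, end, strand, label = toks
        else:
            raise FragmentFormatError(
                f"line {lineno}: expected GFF3 (>=8 cols) or 5-column interval table"
            )
        try:
            s, e = int(start), int(end)
        except ValueError as exc:
            raise FragmentFormatError(f"line {lineno}: non-integer coordinates") from exc
        if e < s:
            raise FragmentFormatError(f"line {lineno}: end {e} < start {s}")
        s = max(1, s)
        if genome_lengths and gid in genome_lengths:
            e = min(e, genome_lengths[gid])
            if e < s:
                continue
        st = FORWARD if strand == "+" else REVERSE if strand == "-" else "?"
        out.append(AnnotationInterval(genome_id=gid, start=s, end=e, strand=st, label=label))
    return out


# ---------------------------------------------------------------------------
# sequences


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file into ``{id: uppercase sequence}``."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, comment: str | None = None) -> None:
    """Write FASTA; an optional comment (e.g. the generator seed) is carried
    in each header description so any parser round-trips it."""
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name} {comment}\n" if comment else f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def groups_round_trip_equal(a: list[ReadMatchGroup], b: list[ReadMatchGroup]) -> bool:
    """Field-for-field structural equality of two group collections."""
    if len(a) != len(b):
        return False
    for ga, gb in zip(a, b):
        if ga.read_id != gb.read_id or ga.read_length != gb.read_length:
            return False
        pa = {g: f for g, f in ga.per_genome.items() if f}
        pb = {g: f for g, f in gb.per_genome.items() if f}
        if pa.keys() != pb.keys():
            return False
        for g in pa:
            fa, fb = pa[g], pb[g]
            if len(fa) != len(fb):
                return False
            for x, y in zip(fa, fb):
                same_score = (x.score is None and y.score is None) or (
                    x.score is not None
                    and y.score is not None
                    and math.isclose(x.score, y.score)
                )
                if not same_score:
                    return False
                if replace(x, score=0.0, similarity=0.0) != replace(y, score=0.0, similarity=0.0):
                    return False
                if not math.isclose(x.similarity, y.similarity, abs_tol=5e-3):
                    return False
    return True
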