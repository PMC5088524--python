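"""Glocal extension of ungapped HSPs.

Local aligners report a read's match to a genome as one or more HSP-like
fragments.  When two consecutive fragments of the same read-genome pair lie
on the same strand, in collinear order, and are separated by at most
``max_gap`` bases on both the read and the genome, they are joined: the
bases between them are aligned globally (Needleman-Wunsch with affine gaps)
and the bridge's identities, length and gap counts are added to the merged
fragment.  The result is a "glocal" alignment — global across the spanned
read region, local with respect to the genome.

Gap definition: the gap between consecutive fragments is the coordinate
difference ``rStart(next) − rEnd(prev)`` (and its genome-side analogue), so
adjacent fragments have gap 1 and a gap of g means g−1 intervening bases.
Chaining requires ``1 ≤ gap ≤ max_gap`` on both sides; overlapping
fragments (gap ≤ 0) are never joined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from glocalmap.fragments import FORWARD, Fragment, ReadMatchGroup
from glocalmap.scoring import ScoreScheme, raw_score

__all__ = [
    "BridgeStats",
    "find_joinable_chains",
    "bridge_alignment",
    "merge_chain",
    "extend_all",
]

DEFAULT_MAX_GAP = 20

_NUC = set("ACGTN")
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class BridgeStats:
    """Contribution of a bridged inter-fragment region to I, L, G_i, G_e."""

    identities: int
    aligned_length: int
    igaps: int
    egaps: int

    def __post_init__(self) -> None:
        if self.identities > self.aligned_length or self.igaps + self.egaps > self.aligned_length:
            raise ValueError("inconsistent bridge statistics")


_EMPTY_BRIDGE = BridgeStats(0, 0, 0, 0)


def _gaps(prev: Fragment, nxt: Fragment) -> tuple[int, int]:
    """(read gap, genome gap) between consecutive fragments, orientation-aware."""
    read_gap = nxt.r_start - prev.r_end
    if prev.strand == FORWARD:
        genome_gap = nxt.g_start - prev.g_end
    else:
        # reverse strand: ascending read order walks the genome backwards
        genome_gap = prev.g_start - nxt.g_end
    return read_gap, genome_gap


def find_joinable_chains(fragments: list[Fragment], max_gap: int = DEFAULT_MAX_GAP) -> list[list[Fragment]]:
    """Partition one read-genome pair's fragments into maximal joinable chains.

    Fragments must be sorted by read start.  Consecutive fragments chain iff
    they share a strand, are collinear, and both the read-side and the
    genome-side gap lie in ``[1, max_gap]``.  Unchainable fragments become
    singleton chains.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    chains: list[list[Fragment]] = []
    for frag in sorted(fragments, key=lambda f: (f.r_start, f.r_end)):
        if chains:
            prev = chains[-1][-1]
            if prev.strand == frag.strand:
                rg, gg = _gaps(prev, frag)
                if 1 <= rg <= max_gap and 1 <= gg <= max_gap:
                    chains[-1].append(frag)
                    continue
        chains.append([frag])
    return chains


def _check_nucleotides(seq: str, what: str) -> None:
    bad = set(seq.upper()) - _NUC
    if bad:
        raise ValueError(f"non-nucleotide characters in {what}: {sorted(bad)!r}")


def bridge_alignment(read_seg: str, genome_seg: str, scheme: ScoreScheme) -> BridgeStats:
    """Optimal global (NW) alignment statistics of two bridge segments.

    Affine gap model: the first column of a gap run costs ``gap_open``, each
    further column ``gap_extend`` — matching how fragment statistics count
    one opened gap plus extensions per run.  Traceback breaks score ties
    preferring diagonal over up (gap in genome) over left (gap in read), so
    the reported statistics are deterministic.
    """
    a, b = read_seg.upper(), genome_seg.upper()
    _check_nucleotides(a, "read segment")
    _check_nucleotides(b, "genome segment")
    la, lb = len(a), len(b)
    if la == 0 and lb == 0:
        return _EMPTY_BRIDGE
    if la == 0 or lb == 0:
        n = max(la, lb)
        return BridgeStats(identities=0, aligned_length=n, igaps=1, egaps=n - 1)

    neg = -np.inf
    go, ge = scheme.gap_open, scheme.gap_extend
    M_, X_, Y_ = 0, 1, 2  # states: diagonal / gap-in-genome (up) / gap-in-read (left)
    score = np.full((3, la + 1, lb + 1), neg)
    ptr = np.full((3, la + 1, lb + 1), -1, dtype=np.int8)  # predecessor state
    score[M_, 0, 0] = 0.0
    for i in range(1, la + 1):
        score[X_, i, 0] = go + (i - 1) * ge
        ptr[X_, i, 0] = M_ if i == 1 else X_
    for j in range(1, lb + 1):
        score[Y_, 0, j] = go + (j - 1) * ge
        ptr[Y_, 0, j] = M_ if j == 1 else Y_

    def _argmax(cands: tuple[float, float, float]) -> int:
        # tie preference M > X > Y ("diagonal > up > left")
        best = M_
        if cands[X_] > cands[best]:
            best = X_
        if cands[Y_] > cands[best]:
            best = Y_
        return best

    for i in range(1, la + 1):
        ai = a[i - 1]
        for j in range(1, lb + 1):
            s = scheme.match if ai == b[j - 1] else scheme.mismatch
            c = (score[M_, i - 1, j - 1], score[X_, i - 1, j - 1], score[Y_, i - 1, j - 1])
            p = _argmax(c)
            score[M_, i, j] = c[p] + s
            ptr[M_, i, j] = p
            c = (score[M_, i - 1, j] + go, score[X_, i - 1, j] + ge, score[Y_, i - 1, j] + go)
            p = _argmax(c)
            score[X_, i, j] = c[p]
            ptr[X_, i, j] = p
            c = (score[M_, i, j - 1] + go, score[X_, i, j - 1] + go, score[Y_, i, j - 1] + ge)
            p = _argmax(c)
            score[Y_, i, j] = c[p]
            ptr[Y_, i, j] = p

    i, j = la, lb
    state = _argmax((score[M_, i, j], score[X_, i, j], score[Y_, i, j]))
    ident = length = igaps = egaps = 0
    while i > 0 or j > 0:
        length += 1
        pred = int(ptr[state, i, j])
        if state == M_:
            if a[i - 1] == b[j - 1]:
                ident += 1
            i, j = i - 1, j - 1
        elif state == X_:
            if pred == X_:
                egaps += 1
            else:
                igaps += 1
            i -= 1
        else:
            if pred == Y_:
                egaps += 1
            else:
                igaps += 1
            j -= 1
        state = pred
    return BridgeStats(identities=ident, aligned_length=length, igaps=igaps, egaps=egaps)


def bridge_score(stats: BridgeStats, scheme: ScoreScheme) -> float:
    """Affine score implied by bridge statistics (for oracle comparisons)."""
    return raw_score(stats.identities, stats.aligned_length, stats.igaps, stats.egaps, scheme)


def _bridge_segments(prev: Fragment, nxt: Fragment, read_seq: str, genome_seq: str) -> tuple[str, str]:
    """Sequences strictly between two chained fragments (read, genome)."""
    read_seg = read_seq[prev.r_end : nxt.r_start - 1]
    if prev.strand == FORWARD:
        genome_seg = genome_seq[prev.g_end : nxt.g_start - 1]
    else:
        genome_seg = revcomp(genome_seq[nxt.g_end : prev.g_start - 1])
    return read_seg, genome_seg


def merge_chain(
    chain: list[Fragment],
    read_seq: str,
    genome_seq: str,
    scheme: ScoreScheme,
    k: int = 1,
) -> Fragment:
    """Merge a joinable chain into one glocal fragment.

    Coordinates take the min/max over members; identities, length and gap
    counts are the sums over members plus every bridge's NW statistics; the
    score is recomputed under the affine model and similarity as 100·I/L.
    A singleton chain is returned unchanged (except for ``k``).
    """
    if not chain:
        raise ValueError("empty chain")
    if len(chain) == 1:
        return replace(chain[0], k=k)
    ident = sum(f.identities for f in chain)
    length = sum(f.length for f in chain)
    igaps = sum(f.igaps for f in chain)
    egaps = sum(f.egaps for f in chain)
    for prev, nxt in zip(chain, chain[1:]):
        rseg, gseg = _bridge_segments(prev, nxt, read_seq, genome_seq)
        st = bridge_alignment(rseg, gseg, scheme)
        ident += st.identities
        length += st.aligned_length
        igaps += st.igaps
        egaps += st.egaps
    rs = raw_score(ident, length, igaps, egaps, scheme)
    return Fragment(
        k=k,
        score=rs,
        identities=ident,
        length=length,
        similarity=100.0 * ident / length,
        igaps=igaps,
        egaps=egaps,
        strand=chain[0].strand,
        r_start=min(f.r_start for f in chain),
        r_end=max(f.r_end for f in chain),
        g_start=min(f.g_start for f in chain),
        g_end=max(f.g_end for f in chain),
    )


def extend_all(
    groups: list[ReadMatchGroup],
    reads: dict[str, str],
    genomes: dict[str, str],
    scheme: ScoreScheme,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[ReadMatchGroup]:
    """Extend every read-genome pair's fragments; returns new groups.

    Pairs whose read or genome sequence is missing pass through unextended
    with a warning.  The total fragment count never increases.
    """
    out: list[ReadMatchGroup] = []
    missing: set[str] = set()
    for grp in groups:
        new = ReadMatchGroup(grp.read_id, grp.read_length)
        for genome_id, frags in grp.per_genome.items():
            if grp.read_id not in reads or genome_id not in genomes:
                missing.add(grp.read_id if grp.read_id not in reads else genome_id)
                new.per_genome[genome_id] = list(frags)
                continue
            merged: list[Fragment] = []
            for chain in find_joinable_chains(frags, max_gap):
                merged.append(
                    merge_chain(chain, reads[grp.read_id], genomes[genome_id], scheme, k=len(merged) + 1)
                )
            new.per_genome[genome_id] = merged
        out.append(new)
    if missing:
        warnings.warn(
            f"{len(missing)} read/genome ids had no sequence; their fragments pass through "
            f"unextended (e.g. {sorted(missing)[:3]})",
            stacklevel=2,
        )
    return out
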