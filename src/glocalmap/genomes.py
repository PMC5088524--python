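"""Genome-level analyses of mapped reads.

Coverage profiles (accumulated reads per genome position, smoothed with a
centered moving window), classification of mapped reads by overlap with
annotated features (none / semi / full), per-annotation differential
abundance between two samples, and detection of genome-specific regions —
stretches not covered by alignments from any other genome in the collection,
whose reads are strong evidence for a low-abundance species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from glocalmap.fragments import AnnotationInterval
from glocalmap.mapping import MappingRecord

__all__ = [
    "GenomeProfile",
    "SpecificRegion",
    "ForeignAlignment",
    "genome_profile",
    "classify_annotation_overlap",
    "classify_mapped_reads",
    "annotated_region_abundance",
    "detect_specific_regions",
    "kmer_foreign_alignments",
    "reads_in_specific_regions",
]

DEFAULT_PROFILE_WINDOW = 10_000
DEFAULT_MIN_REGION_LENGTH = 500
DEFAULT_MAX_FOREIGN_IDENTITY = 0.6
KMER_SIZE = 16

_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass
class GenomeProfile:
    """Accumulated option-1 read depth per genome position plus a smoothed track."""

    genome_id: str
    raw: np.ndarray
    smoothed: np.ndarray
    window: int


@dataclass(frozen=True, order=True)
class SpecificRegion:
    """A maximal genome stretch free of foreign-genome similarity."""

    genome_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ForeignAlignment:
    """An alignment interval on the target genome coming from another genome."""

    start: int
    end: int
    identity_frac: float


def _option1_intervals(records: list[MappingRecord], genome_id: str) -> list[tuple[str, int, int]]:
    out = []
    for rec in records:
        if rec.mapped and rec.options[0].genome_id == genome_id:
            f = rec.options[0].fragment
            out.append((rec.read_id, f.g_start, f.g_end))
    return out


def genome_profile(
    records: list[MappingRecord],
    genome_id: str,
    genome_length: int,
    window: int = DEFAULT_PROFILE_WINDOW,
) -> GenomeProfile:
    """Per-position accumulated count of option-1 reads covering the position.

    The smoothed track is a centered moving mean of the raw track; edge
    windows are truncated to the available positions, so ``window=1``
    returns the raw track unchanged.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if genome_length < 1:
        raise ValueError(f"genome length unknown or invalid for {genome_id!r}")
    diff = np.zeros(genome_length + 1, dtype=np.int64)
    for _, g_start, g_end in _option1_intervals(records, genome_id):
        lo = max(1, g_start)
        hi = min(genome_length, g_end)
        if lo <= hi:
            diff[lo - 1] += 1
            diff[hi] -= 1
    raw = np.cumsum(diff[:-1])
    half_lo = (window - 1) // 2
    half_hi = window // 2
    csum = np.concatenate(([0], np.cumsum(raw, dtype=np.float64)))
    idx = np.arange(genome_length)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi, genome_length - 1)
    smoothed = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return GenomeProfile(genome_id=genome_id, raw=raw, smoothed=smoothed, window=window)


# ---------------------------------------------------------------------------
# annotation overlap


def _merged_intervals(annotations: list[AnnotationInterval]) -> np.ndarray:
    """Merge annotation intervals into disjoint sorted [start, end] rows."""
    if not annotations:
        return np.empty((0, 2), dtype=np.int64)
    ivs = sorted((a.start, a.end) for a in annotations)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def classify_annotation_overlap(
    read_interval: tuple[int, int],
    annotations: list[AnnotationInterval],
) -> str:
    """Classify a mapped read interval against a genome's annotations.

    ``full`` iff every base lies inside the union of annotated intervals,
    ``none`` iff no base does, ``semi`` otherwise.
    """
    s, e = read_interval
    if s > e:
        raise ValueError("empty read interval")
    merged = _merged_intervals(annotations)
    covered = 0
    for ms, me in merged:
        lo, hi = max(s, ms), min(e, me)
        if lo <= hi:
            covered += hi - lo + 1
    if covered == 0:
        return "none"
    if covered == e - s + 1:
        return "full"
    return "semi"


def classify_mapped_reads(
    records: list[MappingRecord],
    genome_id: str,
    annotations: list[AnnotationInterval],
) -> pd.DataFrame:
    """Annotation class of every option-1 read of a genome.

    Returns a DataFrame (read_id, g_start, g_end, annotation_class); the
    three classes partition the genome's mapped reads.
    """
    anns = [a for a in annotations if a.genome_id == genome_id]
    rows = [
        {
            "read_id": rid,
            "g_start": s,
            "g_end": e,
            "annotation_class": classify_annotation_overlap((s, e), anns),
        }
        for rid, s, e in _option1_intervals(records, genome_id)
    ]
    return pd.DataFrame(rows, columns=["read_id", "g_start", "g_end", "annotation_class"])


def annotated_region_abundance(
    records_a: list[MappingRecord],
    records_b: list[MappingRecord],
    annotations: list[AnnotationInterval],
    genome_id: str,
) -> pd.DataFrame:
    """Per-annotation fraction of each sample's mapped reads overlapping it.

    For every annotated interval of the genome, the fraction of sample A's
    (and B's) mapped reads whose option-1 interval overlaps it by at least
    one base, each normalized by that sample's total mapped reads.  This is
    the scatter table behind a DNA-seq differential "expression" plot: equal
    samples fall on the diagonal.
    """
    anns = [a for a in annotations if a.genome_id == genome_id]
    if not anns:
        raise ValueError(f"no annotations for genome {genome_id!r}")
    totals = []
    overlaps = []
    for records in (records_a, records_b):
        total = sum(1 for r in records if r.mapped)
        if total == 0:
            raise ValueError("a sample has no mapped reads")
        ivs = [(s, e) for _, s, e in _option1_intervals(records, genome_id)]
        counts = []
        for a in anns:
            counts.append(sum(1 for s, e in ivs if s <= a.end and e >= a.start))
        totals.append(total)
        overlaps.append(counts)
    return pd.DataFrame(
        {
            "label": [a.label for a in anns],
            "start": [a.start for a in anns],
            "end": [a.end for a in anns],
            "frac_a": np.asarray(overlaps[0]) / totals[0],
            "frac_b": np.asarray(overlaps[1]) / totals[1],
        }
    )


# ---------------------------------------------------------------------------
# specific regions


def detect_specific_regions(
    genome_id: str,
    genome_length: int,
    foreign_alignments: list[ForeignAlignment] | list[tuple[int, int, float]],
    min_length: int = DEFAULT_MIN_REGION_LENGTH,
    max_foreign_identity: float = DEFAULT_MAX_FOREIGN_IDENTITY,
) -> list[SpecificRegion]:
    """Maximal target stretches with no similar foreign alignment.

    Every target position covered by a foreign alignment whose identity
    fraction reaches ``max_foreign_identity`` is marked; the specific
    regions are the maximal unmarked runs of at least ``min_length`` bases,
    returned sorted and disjoint.  The result does not depend on the order
    of the foreign genomes' alignments.
    """
    if genome_length < 1:
        raise ValueError("genome length must be >= 1")
    marked = np.zeros(genome_length, dtype=bool)
    for fa in foreign_alignments:
        start, end, ident = (fa.start, fa.end, fa.identity_frac) if isinstance(fa, ForeignAlignment) else fa
        if ident >= max_foreign_identity:
            lo, hi = max(1, start), min(genome_length, end)
            if lo <= hi:
                marked[lo - 1 : hi] = True
    regions = []
    pos = 0
    free = ~marked
    while pos < genome_length:
        if free[pos]:
            end = pos
            while end + 1 < genome_length and free[end + 1]:
                end += 1
            if end - pos + 1 >= min_length:
                regions.append(SpecificRegion(genome_id, pos + 1, end + 1))
            pos = end + 1
        else:
            pos += 1
    return regions


def kmer_foreign_alignments(
    target_seq: str,
    other_seqs: dict[str, str],
    k: int = KMER_SIZE,
) -> list[ForeignAlignment]:
    """Exact-k-mer stand-in for whole-genome alignments against the target.

    Marks every target window whose k-mer occurs (forward or reverse
    complement) in any other genome, merging the covered positions into
    intervals reported with identity fraction 1.0.  This is a built-in
    fallback for synthetic collections; precomputed alignment files from a
    genome comparison tool can be supplied instead.
    """
    target = target_seq.upper()
    n = len(target)
    if n < k:
        return []
    foreign: set[str] = set()
    for seq in other_seqs.values():
        s = seq.upper()
        for i in range(len(s) - k + 1):
            foreign.add(s[i : i + k])
    covered = np.zeros(n, dtype=bool)
    for i in range(n - k + 1):
        kmer = target[i : i + k]
        if kmer in foreign or kmer.translate(_COMP)[::-1] in foreign:
            covered[i : i + k] = True
    out: list[ForeignAlignment] = []
    pos = 0
    while pos < n:
        if covered[pos]:
            end = pos
            while end + 1 < n and covered[end + 1]:
                end += 1
            out.append(ForeignAlignment(pos + 1, end + 1, 1.0))
            pos = end + 1
        else:
            pos += 1
    return out


def reads_in_specific_regions(
    records: list[MappingRecord],
    regions: list[SpecificRegion],
) -> pd.DataFrame:
    """Reads whose option-1 interval lies entirely inside a specific region.

    Strict containment is required: a read straddling a region boundary
    also fits sequence outside the region and is weaker evidence.  Returns
    a DataFrame (read_id, genome, region_start, region_end).
    """
    by_genome: dict[str, list[SpecificRegion]] = {}
    for r in sorted(regions):
        by_genome.setdefault(r.genome_id, []).append(r)
    rows = []
    for rec in records:
        if not rec.mapped:
            continue
        gid = rec.options[0].genome_id
        f = rec.options[0].fragment
        for region in by_genome.get(gid, []):
            if region.start <= f.g_start and f.g_end <= region.end:
                rows.append(
                    {
                        "read_id": rec.read_id,
                        "genome": gid,
                        "region_start": region.start,
                        "region_end": region.end,
                    }
                )
                break
    return pd.DataFrame(rows, columns=["read_id", "genome", "region_start", "region_end"])
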