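"""The mapping kernel: filtering and multi-option genome assignment.

Every read's fragments first pass two filters — coverage (alignment length
over read length) and identity fraction (identities over alignment length).
Up to ``n_options`` genome options are then selected iteratively: at each
iteration the fragment with the globally smallest E-value below the allowed
maximum wins, its genome is inactivated for later iterations, and (when
strain collapsing is on) so are all genomes sharing its species id.

Equal E-values are broken deterministically: higher identity fraction, then
greater alignment length, then lexicographically smallest accession.  A
stated tie-break matters here because ties between near-identical genomes
are common and an incidental input ordering would otherwise decide the map.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

from glocalmap.fragments import (
    FORWARD,
    Fragment,
    ReadMatchGroup,
    TaxonomyEntry,
    taxonomy_index,
    total_reference_length,
)
from glocalmap.scoring import ScoreScheme, evalue

__all__ = [
    "MappingOption",
    "MappingRecord",
    "MappingParams",
    "filter_fragments",
    "select_options",
    "map_all",
    "write_mapping_csv",
    "read_mapping_csv",
]


@dataclass(frozen=True)
class MappingOption:
    """One ranked genome assignment of a read."""

    genome_id: str
    fragment: Fragment
    evalue: float
    coverage: float
    identity_frac: float


@dataclass
class MappingRecord:
    """A read's ranked mapping options (0 to 3)."""

    read_id: str
    read_length: int
    options: list[MappingOption] = field(default_factory=list)

    @property
    def mapped(self) -> bool:
        return bool(self.options)


@dataclass
class MappingParams:
    n_options: int = 3
    coverage_threshold: float = 0.5
    identity_threshold: float = 0.7
    collapse_strains: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.n_options <= 3:
            raise ValueError("n_options must be 1..3")
        if not (0 <= self.coverage_threshold and 0 <= self.identity_threshold <= 1):
            raise ValueError("thresholds must be non-negative (identity <= 1)")


def filter_fragments(
    fragments: list[Fragment],
    read_length: int,
    coverage_threshold: float,
    identity_threshold: float,
) -> list[Fragment]:
    """Keep fragments with coverage >= covThr and identity fraction >= idThr.

    Coverage is alignment length / read length (it may exceed 1 when
    genome-side gaps inflate the alignment length; it is deliberately not
    capped).  Order is preserved.
    """
    if read_length <= 0:
        raise ValueError("read length must be positive")
    return [
        f
        for f in fragments
        if f.length / read_length >= coverage_threshold
        and f.identities / f.length >= identity_threshold
    ]


def _sort_key(genome_id: str, frag: Fragment, ev: float):
    # smallest E first; ties: higher identity fraction, longer, smaller accession
    return (ev, -frag.identity_frac, -frag.length, genome_id, frag.k)


def select_options(
    group: ReadMatchGroup,
    scheme: ScoreScheme,
    taxonomy: list[TaxonomyEntry] | dict[str, TaxonomyEntry],
    params: MappingParams | None = None,
) -> MappingRecord:
    """Apply the mapping decision to one read's match group.

    Fragments must already carry raw scores (post-extension, post-rescoring).
    Returns a record with 0 to ``n_options`` options; E-values are
    non-decreasing along the list and option genomes (or species, when
    collapsing strains) are pairwise distinct.
    """
    params = params or MappingParams()
    tax = taxonomy if isinstance(taxonomy, dict) else taxonomy_index(taxonomy)
    if group.read_length is None:
        raise ValueError(f"read {group.read_id!r} has unknown length")
    record = MappingRecord(group.read_id, group.read_length)

    candidates: list[tuple[tuple, str, Fragment, float]] = []
    for genome_id, frags in group.per_genome.items():
        if frags and genome_id not in tax:
            raise KeyError(f"genome {genome_id!r} missing from taxonomy")
        for f in filter_fragments(
            frags, group.read_length, params.coverage_threshold, params.identity_threshold
        ):
            if f.score is None:
                raise ValueError(f"fragment of read {group.read_id!r} has no score")
            ev = evalue(f.score, group.read_length, scheme)
            if ev <= scheme.max_evalue:
                candidates.append((_sort_key(genome_id, f, ev), genome_id, f, ev))
    candidates.sort(key=lambda c: c[0])

    inactive_genomes: set[str] = set()
    inactive_species: set[int] = set()
    for _ in range(params.n_options):
        chosen = None
        for key, genome_id, frag, ev in candidates:
            if genome_id in inactive_genomes:
                continue
            if params.collapse_strains and tax[genome_id].n in inactive_species:
                continue
            chosen = (genome_id, frag, ev)
            break
        if chosen is None:
            break
        genome_id, frag, ev = chosen
        record.options.append(
            MappingOption(
                genome_id=genome_id,
                fragment=frag,
                evalue=ev,
                coverage=frag.length / group.read_length,
                identity_frac=frag.identity_frac,
            )
        )
        inactive_genomes.add(genome_id)
        inactive_species.add(tax[genome_id].n)
    return record


def map_all(
    groups: list[ReadMatchGroup],
    scheme: ScoreScheme,
    taxonomy: list[TaxonomyEntry],
    params: MappingParams | None = None,
) -> tuple[list[MappingRecord], dict[str, int]]:
    """Map every read; returns (records, per-option-level summary counts).

    The scheme's ``db_length`` is set from the taxonomy (total reference
    length) when left at its default.  Genomes present in fragments but
    absent from the taxonomy raise an error listing the accessions.
    """
    params = params or MappingParams()
    tax = taxonomy_index(taxonomy)
    missing = sorted(
        {g for grp in groups for g, frs in grp.per_genome.items() if frs and g not in tax}
    )
    if missing:
        raise KeyError(f"genomes absent from taxonomy: {missing}")
    if scheme.db_length == 1:
        scheme.db_length = total_reference_length(taxonomy)
    scheme.calibrate()
    records = [select_options(grp, scheme, tax, params) for grp in groups]
    summary = {
        "reads": len(records),
        "mapped": sum(1 for r in records if r.mapped),
        "option1": sum(1 for r in records if len(r.options) >= 1),
        "option2": sum(1 for r in records if len(r.options) >= 2),
        "option3": sum(1 for r in records if len(r.options) >= 3),
    }
    return records, summary


# ---------------------------------------------------------------------------
# CSV round-trip

_OPT_COLS = [
    "genome",
    "evalue",
    "coverage",
    "identity_frac",
    "length",
    "identities",
    "igaps",
    "egaps",
    "r_start",
    "r_end",
    "g_start",
    "g_end",
    "strand",
]


def write_mapping_csv(records: list[MappingRecord], stream=None) -> str:
    """One row per read; per-option blocks of columns; blanks for absent options."""
    cols = ["read_id", "read_length"]
    for i in (1, 2, 3):
        cols += [f"opt{i}_{c}" for c in _OPT_COLS]
    rows = []
    for rec in records:
        row: dict[str, object] = {"read_id": rec.read_id, "read_length": rec.read_length}
        for i, opt in enumerate(rec.options, start=1):
            f = opt.fragment
            row.update(
                {
                    f"opt{i}_genome": opt.genome_id,
                    f"opt{i}_evalue": opt.evalue,
                    f"opt{i}_coverage": opt.coverage,
                    f"opt{i}_identity_frac": opt.identity_frac,
                    f"opt{i}_length": f.length,
                    f"opt{i}_identities": f.identities,
                    f"opt{i}_igaps": f.igaps,
                    f"opt{i}_egaps": f.egaps,
                    f"opt{i}_r_start": f.r_start,
                    f"opt{i}_r_end": f.r_end,
                    f"opt{i}_g_start": f.g_start,
                    f"opt{i}_g_end": f.g_end,
                    f"opt{i}_strand": "+" if f.strand == FORWARD else "-",
                }
            )
        rows.append(row)
    df = pd.DataFrame(rows, columns=cols)
    text = df.to_csv(index=False)
    if stream is not None:
        stream.write(text)
    return text


def read_mapping_csv(source) -> list[MappingRecord]:
    """Companion reader; reconstructs records (fragment k is not stored and
    is rebuilt as the option rank)."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source)
    records = []
    for _, row in df.iterrows():
        rec = MappingRecord(str(row["read_id"]), int(row["read_length"]))
        for i in (1, 2, 3):
            gcol = f"opt{i}_genome"
            if gcol not in row or pd.isna(row[gcol]):
                break
            frag = Fragment(
                k=i,
                score=None,
                identities=int(row[f"opt{i}_identities"]),
                length=int(row[f"opt{i}_length"]),
                similarity=100.0 * row[f"opt{i}_identities"] / row[f"opt{i}_length"],
                igaps=int(row[f"opt{i}_igaps"]),
                egaps=int(row[f"opt{i}_egaps"]),
                strand=str(row[f"opt{i}_strand"]),
                r_start=int(row[f"opt{i}_r_start"]),
                r_end=int(row[f"opt{i}_r_end"]),
                g_start=int(row[f"opt{i}_g_start"]),
                g_end=int(row[f"opt{i}_g_end"]),
            )
            rec.options.append(
                MappingOption(
                    genome_id=str(row[gcol]),
                    fragment=frag,
                    evalue=float(row[f"opt{i}_evalue"]),
                    coverage=float(row[f"opt{i}_coverage"]),
                    identity_frac=float(row[f"opt{i}_identity_frac"]),
                )
            )
        records.append(rec)
    return records
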