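"""Community-level post-processing of mapping records.

Abundance tables per option level, the "shared reads" mapping-precision
diagnostic (reads whose second candidate is nearly as good as the first),
second-option profiles for a target genome, and a pooled two-proportion
Z-test for differential abundance between samples with Benjamini-Hochberg
correction across genomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from glocalmap.fragments import TaxonomyEntry, taxonomy_index
from glocalmap.mapping import MappingRecord

__all__ = [
    "abundance_by_option",
    "shared_reads",
    "second_option_profile",
    "zscore_differential",
    "SharedReadDistances",
]

DEFAULT_SHARED_DISTANCES = (0.05, 0.05, 10)


@dataclass(frozen=True)
class SharedReadDistances:
    """Closeness thresholds defining a "shared" read (first vs second option)."""

    identity: float = 0.05
    coverage: float = 0.05
    length: int = 10

    def __post_init__(self) -> None:
        if min(self.identity, self.coverage, self.length) < 0:
            raise ValueError("distances must be >= 0")


def abundance_by_option(
    records: list[MappingRecord],
    taxonomy: list[TaxonomyEntry],
    level: str = "genome",
) -> pd.DataFrame:
    """Counts of reads per genome (or species) at each option level.

    Returns a DataFrame indexed by genome accession (or species id ``n``)
    with columns ``option1``, ``option2``, ``option3``.  Every mapped read
    contributes exactly once to ``option1``, so the ``option1`` column sums
    to the number of mapped reads (asserted).
    """
    if level not in ("genome", "species"):
        raise ValueError("level must be 'genome' or 'species'")
    tax = taxonomy_index(taxonomy)
    keys = (
        sorted({e.accession for e in taxonomy})
        if level == "genome"
        else sorted({e.n for e in taxonomy})
    )
    counts = {k: [0, 0, 0] for k in keys}
    mapped = 0
    for rec in records:
        if rec.mapped:
            mapped += 1
        for i, opt in enumerate(rec.options):
            if opt.genome_id not in tax:
                raise KeyError(f"genome {opt.genome_id!r} missing from taxonomy")
            key = opt.genome_id if level == "genome" else tax[opt.genome_id].n
            counts[key][i] += 1
    df = pd.DataFrame.from_dict(
        counts, orient="index", columns=["option1", "option2", "option3"]
    )
    df.index.name = "genome" if level == "genome" else "species"
    assert df["option1"].sum() == mapped, "option-1 conservation violated"
    return df


def shared_reads(
    records: list[MappingRecord],
    distances: SharedReadDistances | None = None,
) -> pd.DataFrame:
    """Per option-1 genome: total assigned reads and "shared" reads.

    A read is shared iff it has at least two options and the first and
    second options are within the identity-fraction, coverage and length
    distances — i.e. the runner-up was almost as good, so the assignment is
    uncertain.
    """
    d = distances or SharedReadDistances()
    rows: dict[str, list[int]] = {}
    for rec in records:
        if not rec.mapped:
            continue
        first = rec.options[0]
        entry = rows.setdefault(first.genome_id, [0, 0])
        entry[0] += 1
        if len(rec.options) >= 2:
            second = rec.options[1]
            if (
                abs(first.identity_frac - second.identity_frac) <= d.identity
                and abs(first.coverage - second.coverage) <= d.coverage
                and abs(first.fragment.length - second.fragment.length) <= d.length
            ):
                entry[1] += 1
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["option1", "shared"])
    df.index.name = "genome"
    return df.sort_index()


def second_option_profile(
    records: list[MappingRecord],
    target_genome: str,
    restrict_to: list[str] | None = None,
) -> pd.DataFrame:
    """Where do reads best assigned to ``target_genome`` go as second choice?

    For reads whose first option is the target, tallies per second-option
    genome the percentage of such reads and the mean mapped-read length.
    ``restrict_to`` limits the tally to chosen partner genomes (one-vs-one
    or one-vs-some analyses).
    """
    partners: dict[str, list[int]] = {}
    total = 0
    for rec in records:
        if not rec.mapped or rec.options[0].genome_id != target_genome:
            continue
        total += 1
        if len(rec.options) < 2:
            continue
        second = rec.options[1]
        if restrict_to is not None and second.genome_id not in restrict_to:
            continue
        entry = partners.setdefault(second.genome_id, [0, 0])
        entry[0] += 1
        entry[1] += rec.read_length
    rows = {
        g: {"count": c, "percent": 100.0 * c / total, "mean_read_length": s / c}
        for g, (c, s) in partners.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    if df.empty:
        df = pd.DataFrame(columns=["count", "percent", "mean_read_length"])
    df.index.name = "second_genome"
    return df.sort_index()


def zscore_differential(
    counts_a: dict[str, int],
    total_a: int,
    counts_b: dict[str, int],
    total_b: int,
) -> pd.DataFrame:
    """Pooled two-proportion Z-test per genome between two samples.

    For each genome with counts x_A of n_A and x_B of n_B mapped reads,

        p̂ = (x_A + x_B) / (n_A + n_B)
        z = (x_A/n_A − x_B/n_B) / sqrt(p̂(1−p̂)(1/n_A + 1/n_B))

    with two-sided normal p-values and Benjamini-Hochberg adjusted q-values
    across genomes.  Degenerate genomes (pooled proportion 0 or 1) get z=0,
    p=1.  Swapping the samples negates z.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("sample totals must be positive")
    genomes = sorted(set(counts_a) | set(counts_b))
    zs, ps = [], []
    for g in genomes:
        xa, xb = counts_a.get(g, 0), counts_b.get(g, 0)
        if xa < 0 or xb < 0 or xa > total_a or xb > total_b:
            raise ValueError(f"counts out of range for {g!r}")
        pooled = (xa + xb) / (total_a + total_b)
        if pooled in (0.0, 1.0):
            zs.append(0.0)
            ps.append(1.0)
            continue
        se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / total_a + 1.0 / total_b))
        z = (xa / total_a - xb / total_b) / se
        zs.append(z)
        ps.append(2.0 * norm.sf(abs(z)))
    qs = multipletests(ps, method="fdr_bh")[1] if genomes else np.array([])
    return pd.DataFrame(
        {"z": zs, "p": ps, "q": qs},
        index=pd.Index(genomes, name="genome"),
    )
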