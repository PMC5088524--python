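# glocalmap

Fine-grained taxonomic mapping of metagenomic reads against a user-defined
collection of reference genomes.

Shotgun metagenomics asks which species are present in an environmental
sample and how their abundances change between conditions. The organisms are
mostly uncultured, so the reference genomes at hand are *close relatives*
rather than exact matches of the sequenced bacteria, and read-to-genome
matches arrive as short, sometimes split local alignments (HSPs). This
package takes those local alignments — from BLAST tabular output or from any
tool writing the package's plain-text fragment format — and turns them into
ranked, quality-annotated read-to-genome assignments plus community-level
analyses. It is aimed at microbiome researchers who want mapping decisions
they can inspect, re-threshold and post-process with ordinary tools (every
intermediate is a text file; every table is CSV).

## What it computes

**Glocal extension.** Consecutive collinear HSPs of a read against a genome
that lie within `maxGap` bases of each other on both the read and the genome
are joined; the bases between them are aligned with an affine-gap
Needleman-Wunsch matrix and the bridge's statistics are added. The result is
an alignment global across the spanned read region but local in the genome —
longer fragments that tolerate the small indels expected between a sampled
organism and its database relative.

**Affine rescoring and E-values.** An extended fragment with *I* identities,
length *L* columns, *G<sub>i</sub>* opened and *G<sub>e</sub>* extension gaps
gets the raw score

```
RS = I·M_r + (L − (G_i + G_e) − I)·M_p + G_i·P_i + G_e·P_e
```

(defaults M_r=1, M_p=−1, P_i=−5, P_e=−2) and the expected value

```
E = K · m · n · e^(−λ·RS)
```

with *m* the read length and *n* the total reference length. λ is the unique
positive root of Σ p<sub>i</sub>p<sub>j</sub> e^(λ·s(i,j)) = 1 and K comes
from the standard ungapped lattice renewal series; for match +1 / mismatch −1
on uniform base composition, λ = ln 3 ≈ 1.0986 and K ≈ 0.3333.

**Mapping decision.** Per read, fragments are filtered by coverage
(alignment length / read length ≥ 0.5 by default) and identity fraction
(identities / alignment length ≥ 0.7). Up to three genome options are then
chosen by iteratively taking the smallest E-value below 10⁻³ and
inactivating the winning genome (optionally all strains of its species).
Ties are broken deterministically: higher identity fraction, longer
alignment, then smallest accession.

**Post-processing.** Abundance tables per option level, "shared read"
mapping-precision diagnostics, second-option profiles (where do a genome's
reads go as runner-up?), a pooled two-proportion Z-test with BH-FDR for
differential abundance between samples, window-smoothed genome coverage
profiles, none/semi/full annotation-overlap classes, per-annotation
differential abundance, and *specific regions*: genome stretches with no
similarity to any other genome in the collection, whose fully-contained
reads are strong evidence for a low-abundance species.

A synthetic-data module generates communities with planted conserved blocks,
unique inserts and reads with recorded errors, so the whole pipeline is
testable against exact ground truth.

## Worked example

The classic situation the extension step exists for: one read, two ungapped
candidate fragments against *Bacteroides thetaiotaomicron*, 14 read
coordinates apart.

```python
import io
from glocalmap import (parse_fragment_file, find_joinable_chains,
                       merge_chain, ScoreScheme, evalue)

FRAGS = (
    ">029701.102903 — NC_004663.1 — Bacteroides thetaiotaomicron — len=249\n"
    "1\t-\t124\t133\t93.23\t0\t0\tPlus/Plus\t1\t133\t1631420\t1631552\n"
    "2\t-\t96\t103\t93.20\t0\t0\tPlus/Plus\t147\t249\t1631563\t1631665\n"
)

group = parse_fragment_file(io.StringIO(FRAGS))[0]
frags = group.per_genome["NC_004663.1"]
print("read gap:", frags[1].r_start - frags[0].r_end)

# sequences are plain strings; only the 13-base read bridge and its 10-base
# genome counterpart matter here (the genome bridge misses 3 contiguous bases)
read_seg = "ACGTACGTACGTA"
read = "C" * 133 + read_seg + "C" * 103
genome = "A" * 1631552 + read_seg[:5] + read_seg[8:] + "A" * 128

scheme = ScoreScheme(db_length=6_260_361)   # total reference length n
(chain,) = find_joinable_chains(frags, max_gap=20)
merged = merge_chain(chain, read, genome, scheme)
print(f"merged: read {merged.r_start}..{merged.r_end}, "
      f"genome {merged.g_start}..{merged.g_end}")
print(f"I={merged.identities} L={merged.length} G_i={merged.igaps} "
      f"G_e={merged.egaps} RS={merged.score:.0f} "
      f"E={evalue(merged.score, 249, scheme):.3g}")
```

prints

```
read gap: 14
merged: read 1..249, genome 1631420..1631665
I=230 L=249 G_i=1 G_e=2 RS=205 E=8.05e-90
```

The two 133 bp and 103 bp fragments become one 249-column glocal alignment
with a single 3-base gap (one opening, two extensions), scored RS=205; at
that score a chance hit in a 6.3 Mb reference is expected ~10⁻⁹⁰ times, so
the assignment is unambiguous.

The same pipeline from the shell, on a simulated community:

```sh
glocalmap simulate --n-genomes 3 --genome-length 4000 --n-reads 300 \
    --indel-rate 0.1 --seed 5 --out-prefix sim
glocalmap run --fragments sim.frags --reads sim.reads.fasta \
    --genomes sim.genomes.fasta --taxonomy sim.taxonomy.tsv --out-prefix out
```

produces `out.extended.frags`, `out.mapping.csv` and `out.abundance.csv`.
Further subcommands: `convert`, `extend`, `map`, `abundance`, `shared`,
`second-profile`, `zscore`, `profile`, `annotate-classes`,
`region-abundance`, `specific-regions`.

## Layout

- `src/glocalmap/fragments.py` — fragment / taxonomy / annotation formats,
  BLAST tabular conversion, FASTA I/O
- `src/glocalmap/extension.py` — chaining and NW bridge alignment
- `src/glocalmap/scoring.py` — raw scores, λ/K estimation, E-values
- `src/glocalmap/mapping.py` — filters and the 3-option mapping kernel
- `src/glocalmap/abundance.py` — abundance, shared reads, profiles, Z-test
- `src/glocalmap/genomes.py` — coverage profiles, annotation classes,
  specific regions
- `src/glocalmap/simulate.py` — synthetic communities with ground truth
- `src/glocalmap/cli.py` — the `glocalmap` command
- `docs/methods.md` — models, parameters, numerical choices, limitations
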