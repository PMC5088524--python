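# Methods

This note documents the models, conventions and numerical choices behind
`glocalmap`, the defaults and why they were chosen, and what the synthetic
validation does and does not show.

## Fragment model and coordinate conventions

A *fragment* records one alignment between a read and a genome as a 12-tuple:
ordinal `k` within the read-genome pair, raw score, identities `I`, alignment
length `L` (columns), percent similarity, opened gaps `G_i`, extension gaps
`G_e`, strand, and read/genome start and end coordinates. Conventions:

- Coordinates are 1-based and inclusive at both ends.
- Reverse-strand fragments keep ascending forward-axis genome coordinates
  plus a strand flag. One sort order and plain interval arithmetic then work
  for both orientations; the read coordinates always refer to the read as
  sequenced.
- A gap *run* of length g counts one opened gap (`G_i += 1`) and g−1
  extensions (`G_e += g−1`); `G_i + G_e` is the number of gap columns, so
  `I + mismatches + G_i + G_e = L`.
- An unset score serializes as `-` and means "to be recomputed".
- Similarity is recomputed after extension as `100·I/L`, the only percentage
  derivable from the stored statistics alone.

BLAST 12-column tabular input lacks the opening/extension split; converted
fragments get `G_i = gap opens`, `G_e = 0` and a `gap_detail_known=False`
flag, and rescoring then charges every gap column as an opening — the
conservative choice when the true run structure is unknown.

## Glocal extension

Local aligners report a read's match to a diverged relative as several
nearby HSPs. Consecutive fragments of one read-genome pair are joined when
they share a strand, are collinear, and their separation is at most
`max_gap` on *both* the read and the genome; bounding both sides prevents
bridging across genomic rearrangements. The separation is the coordinate
difference `rStart(next) − rEnd(prev)` (adjacent fragments have gap 1;
overlapping ones, gap ≤ 0, are never joined — trimming rules would be
arbitrary, so overlapping HSPs are left as competing fragments).

The intervening sequences are aligned globally with an affine-gap
Needleman-Wunsch (Gotoh three-state) matrix; the bridge's `I`, `L`, `G_i`,
`G_e` are added to the member sums and the merged coordinates are the
min/max over members. Gap sizes are bounded by `max_gap`, so the full
O(d₁·d₂) matrix is trivially cheap and no banded or linear-memory variant is
needed. Traceback ties prefer diagonal over up (gap in genome) over left
(gap in read), making the reported statistics deterministic; all tied
optima have the same score by construction, so scores are unaffected.
Merging is associative along a chain (the statistics are sums).

Default `max_gap` = 20 bp: the same order as the mid-teens separations seen
between HSPs flanking small indels, and small enough that a bridge can never
dominate the fragments it connects.

## Scoring and E-values

Raw score of a fragment:
`RS = I·M_r + (L − (G_i+G_e) − I)·M_p + G_i·P_i + G_e·P_e`,
defaults `(M_r, M_p, P_i, P_e) = (1, −1, −5, −2)`.

λ is the unique positive root of `Σᵢⱼ pᵢpⱼ·e^{λ·s(i,j)} = 1`, solved with
Brent's method to relative tolerance 1e-12 after verifying the
Karlin-Altschul conditions (negative expected score, positive maximum
score). With a single match and mismatch score the identity collapses to
`q·e^{λM_r} + (1−q)·e^{λM_p} = 1`, `q = Σpᵢ²`; for +1/−1 on uniform
composition, λ = ln 3 exactly.

K uses the lattice renewal-series formula

```
K = δ·λ·e^(−2σ) / (H·(1 − e^(−λδ)))
σ = Σ_{k≥1} (1/k)·[ E(e^{λS_k}; S_k<0) + P(S_k ≥ 0) ]
```

where `S_k` is the k-step random walk of per-column scores, `H = λ·E[S·e^{λS}]`
the relative entropy, and δ the span (gcd) of the integerized scores.
The series is truncated at k = 120 terms; it converges geometrically and the
truncation error is far below the reported precision for any scheme whose
expected score is not marginal. Non-integer scores are snapped to a 1/1000
grid for the series. For +1/−1 uniform the formula reproduces the ±1-walk
closed form K = (q−p)²/q = 1/3 to 9 decimals, and K is invariant under
rescaling all scores (λ compensates), so E-values are scale-free.

E-values are `E = K·m·n·e^{−λ·RS}` with m the read length and n the *total
reference length*, taken as the sum of the taxonomy-file genome lengths so
that n is reproducible from the declared inputs. Gapped statistics are
approximated by the ungapped (substitution-only) λ and K; gap penalties
enter through RS. Computation is done in log space; E below e^{−700} is
reported as 0. No finite-size edge corrections or composition adjustment are
applied.

## Mapping decision

Per read: (1) filter fragments by coverage `L/m ≥ covThr` (coverage may
exceed 1 when genome-side gaps inflate L; it is deliberately not capped, to
keep the definition literal) and identity fraction `I/L ≥ idThr`;
(2) up to `n_options` times, pick the fragment with the globally smallest
E-value below `max_evalue`, record it, and inactivate its genome — and, when
strain collapsing is on, every genome sharing its species id — for later
iterations. Defaults: `n_options=3`, `covThr=0.5`, `idThr=0.7`,
`max_evalue=1e-3`, collapse off.

Inactivation is genome-level (not fragment-level), so a genome can
contribute at most one option per read. Equal E-values are resolved by
higher identity fraction, then longer alignment, then lexicographically
smallest accession, then fragment ordinal: near-identical reference genomes
make exact ties common, and an undocumented input-order dependence would
silently bias abundances. The tie-break is explicit precisely so that this
bias is reproducible and inspectable (second-option analyses are the tool
for finding it).

## Post-processing

- **Abundance**: read counts per genome (or species id) at each option
  level; the option-1 column always sums to the number of mapped reads
  (asserted at run time).
- **Shared reads**: a read is "shared" when its second option is within
  distance thresholds of its first (defaults: identity fraction 0.05,
  coverage 0.05, length 10 bp — "almost as good" made concrete; all
  overridable). Shared counts are monotone in each threshold.
- **Second-option profile**: for reads whose best option is a target
  genome, the percentage and mean read length per runner-up genome,
  optionally restricted to chosen partners (one-vs-one / one-vs-some).
- **Differential abundance**: pooled two-proportion Z-test per genome,
  `z = (x_A/n_A − x_B/n_B)/√(p̂(1−p̂)(1/n_A+1/n_B))`, two-sided normal
  p-values, Benjamini-Hochberg q-values across genomes. Genomes with pooled
  proportion 0 or 1 get z=0, p=1. The test is antisymmetric under sample
  swap, and its type-I error is verified by simulation to sit near the
  nominal α. Only the species-level test is implemented; a positional
  (region-level) variant would be a natural extension.
- **Genome profile**: per-position option-1 read depth, smoothed by a
  centered moving mean (default window 10 000 bp) with edge windows
  truncated to the available positions.
- **Annotation classes**: a mapped read is `full` if every base lies in the
  union of annotated intervals, `none` if no base does, `semi` otherwise;
  the three classes partition a genome's mapped reads.
- **Annotated-region abundance**: per annotation, the fraction of each
  sample's mapped reads overlapping it by ≥1 base, normalized by that
  sample's total mapped reads (the scatter table of a DNA-seq differential
  plot).
- **Specific regions**: every target position covered by a foreign-genome
  alignment with identity fraction ≥ `max_foreign_identity` (default 0.6)
  is marked; specific regions are maximal unmarked runs ≥ `min_length`
  (default 500 bp). Raising the identity bar marks fewer positions, so
  regions can only grow. Alignments normally come from a whole-genome
  comparison tool via the fragment format; a built-in exact 16-mer matcher
  (forward and reverse complement) stands in for synthetic collections.
  Evidence reads must lie *entirely inside* a region: a straddling read
  also fits sequence present elsewhere and is weaker evidence. The
  0.6/500 defaults are conventions — "no similarity at all" has no
  canonical threshold — and are exposed as parameters.

## Synthetic data

The generator emulates the study conditions end to end: i.i.d.-nucleotide
genomes; conserved blocks copied verbatim between chosen pairs (the source
of second-option peaks); unique inserts regenerated until no 16-mer (either
strand) occurs elsewhere; reads drawn multinomially by abundance with
uniform starts, uniform lengths in 172–237 bp (the post-trimming range of
the 454 data the workflow targets), reverse-complemented with probability
1/2, substitutions at 2% per aligned base by default, and at most one
1–5 bp indel per read. Single-event indels keep every fragment statistic
exactly computable from the recorded error positions, which is what lets
the generator double as the oracle: fragment files are emitted directly
from the truth (optionally with the two flanking ungapped HSPs that a local
aligner would report around an indel), plus spurious fragments against the
partner genome wherever a read overlaps a conserved block by ≥20 aligned
bases.

The reference validation scenario uses five 10 kb genomes, 10 000 reads,
and one genome at 0.1% abundance built as two 3.5 kb blocks shared with a
partner flanking a 3 kb unique insert — scaled so that the whole pipeline,
including the N−1 genome comparisons, runs in seconds while the
low-abundance genome still leaves a handful of evidence reads.

What passing these tests does *not* show: real reads have
quality-dependent and homopolymer error structure, multiple indels,
chimeras and contamination; real genome collections share homology at all
identity levels, not just exact copies; and abundances estimated from
mapped-read counts inherit the reference collection's biases. The synthetic
results validate the *machinery* (arithmetic, decision rules, statistics),
not field performance.

## Degenerate inputs and edge cases

- Empty fragment streams, headers without rows (warned), reads with no
  surviving fragment (valid empty mapping record) are all legal.
- `merge_chain` on a singleton chain returns the fragment unchanged.
- Bridge alignment of two empty segments contributes nothing; a one-sided
  empty bridge is a pure gap run (one opening).
- λ estimation refuses schemes with non-negative expected score or
  non-positive maximum score, naming the violated condition.
- Z-test refuses zero sample totals; degenerate pooled proportions give
  z=0 rather than 0/0.
- Genome intervals extending past the declared genome length are clipped in
  profiles and annotation parsing.

## Known limitations

- Gapped E-values reuse ungapped λ/K; E-values are comparable with each
  other (which is all the ranking needs) but not calibrated against gapped
  null models.
- The BLAST conversion path cannot recover gap run structure; its scores
  are a lower bound on the affine score.
- Strain inactivation is genome-level per option iteration; a second option
  on the same genome (e.g. a second locus) is never reported.
- The exact k-mer matcher is a stand-in for a genome comparison tool and
  will not detect diverged (<100% identity) homology; supply precomputed
  alignments for realistic collections.
- Protein-space verification, LCA-style inner-node assignment, colour-space
  reads and quality control are out of scope.
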