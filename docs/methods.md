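# Methods

`syntevo` measures how genome architecture diverges between related species
with a conserved karyotype. Given two assemblies it partitions every base of
both genomes into five classes — syntenic, inverted, translocated,
duplicated, unaligned — and then aggregates those partitions across all
pairs of a clade: class proportions against phylogenetic distance, per-base
sharing across all comparisons of one genome, rearrangements conserved
along lineages, genic content of events, and a core/dispensable/private
pangenome. Because genome-scale inputs are impractical to ship, the package
includes a genome-evolution simulator whose ground-truth journal makes every
downstream stage testable.

## Pairwise classification model

**Anchors.** All maximal exact matches ≥ k bp (default k = 40) between the
two genomes are found on both strands; `N` never matches, and repeated
seeds are reported up to a copy cap (default 50 per seed) to bound repeat
blow-up. Discovery is vectorised: chromosomes are concatenated with `N`
spacers, every k-mer window is grouped with `np.unique`, and shared windows
are merged into maximal runs along alignment diagonals, which yields exact
maximal matches (verified against a quadratic brute-force oracle in the
tests).

**Blocks.** Anchors of one orientation and chromosome pair are chained
greedily in reference order when the reference gap and query gap are each
≤ 500 bp and mutually consistent (|Δref − Δqry| ≤ 500 bp); chains with less
than 200 bp of summed anchors are dropped. Block identity is computed
either exactly (global end-gap-free alignment of the two spans via edlib;
identity = matching columns / alignment columns) or by the fast lower bound
anchor-bp / max(span); the default (`auto`) uses exact alignment for spans
up to 50 kbp. Blocks shorter than 200 bp on either genome or below 80%
identity are removed (inclusive thresholds: ≥ 200 bp and ≥ 80% are kept).
The permissive 80% floor reflects the high heterozygosity typical of the
study system.

**Backbone.** Homologous chromosomes are paired by greedy reciprocal-best
summed aligned length. Per chromosome pair, the syntenic backbone is the
maximum-weight chain of forward blocks advancing in both genomes
(weighted longest-increasing-subsequence; weight = min span length). Chain
links may overlap: block envelopes jitter a few bp at breakpoints because
exact matches extend coincidentally across junctions, and a tandem
duplication produces two half-chromosome blocks that overlap by the copy
length. Overlap is deducted from the link's weight, and after selection the
chain is trimmed (`trim_chain`); trimmed-off pieces ≥ 200 bp re-enter the
classification pool — for a tandem duplication the trimmed piece is exactly
the copy↔source alignment. An exhaustive search over all valid chains on
random block sets confirms optimality.

**Classes.** Backbone blocks are syntenic. Maximal runs of reverse-oriented
blocks lying between consecutive backbone blocks (chromosome ends act as
virtual backbone) with reversed query order form one inversion each.
Remaining blocks, largest first, are translocations when both spans are
otherwise uncovered and duplications when either span overlaps
already-annotated sequence; a 100 bp jitter tolerance (the same tolerance
used for breakpoint comparison downstream) keeps envelope noise from
flipping translocations to duplications. Inverted duplications are recorded
as duplications and inverted translocations as translocations — orientation
is an attribute, not a class. Inversion *coverage* is accounted with the
member blocks' actual spans rather than the run envelope, so a segment
translocated out of an inverted region still classifies as a translocation.

**Partition.** Per genome, annotations are projected to single-sided
regions with per-base precedence SYN > INV > TRANS > DUP (later-processed
overlaps trimmed to unassigned sequence), strictly adjacent same-type runs
are merged (length-weighted identity), and the complement becomes
UNALIGNED. The five classes then tile each genome exactly; this is checked
(`check_partition`) and any violation raises. Classification runs once per
unordered pair with one genome as reference; statistics are emitted for
both genomes from that single run.

## Downstream analyses

*Pair summaries* drop events < 200 bp (counts, mean sizes, and proportion
numerators alike) and renormalise proportions over retained bases so
SYN + UNALIGNED + rearranged = 100 per genome; a flag keeps raw
denominators instead. *Trend regressions* are ordinary least squares of a
class proportion (or length-weighted class identity) on patristic distance
(sum of branch lengths between tips), with the two-sided t-test p-value for
a nonzero slope; genome pairs are treated as independent points even though
they share tips — deliberately uncorrected, as is conventional for this
analysis. *Sharing* counts, for every base of a focal genome, the number of
other genomes in which that base falls in an aligned class of the
corresponding pair (difference arrays per chromosome; duplications count as
shared by default, a flag excludes them); unique = count 0, core =
count n−1. *Lineage tracing* classifies every ingroup genome against a
common outgroup, projects INV/TRANS/DUP events > 1 kbp into outgroup
coordinates, and clusters events whose start and end both agree within
±50 bp by seed-anchored greedy matching (same type and chromosome required;
one member per genome; a genome's second candidate seeds a new cluster), so
two events further than the tolerance from a seed never share a cluster.
Projection reads the two-sided event records — a duplication's
outgroup-side source span is usually also syntenic and would be trimmed out
of the partition — and combines near-adjacent (±50 bp) same-type
outgroup-side spans whose ingroup sides are also compatible (same ingroup
chromosome, within 10 kbp — the reach of a single disrupting event), the
analogue of combining an unbroken series of annotations of one type;
nested, strongly overlapping, or ingroup-discordant spans stay distinct so
that adjacent but unrelated events are not fused. Clade counts are the clusters whose member sets contain all tips
of a clade, which is non-increasing toward the root by construction.
*Genic content* drops events < 1 kbp and genes unplaced in any orthogroup,
calls an event genic on ≥ 1 bp overlap with a placed gene's genomic span
(a stricter full-containment mode is available), and averages per-pair
proportions per genome with min/max recorded; classes with no retained
events in a pair are skipped in the average rather than treated as 0, which
would bias rare classes (inversions). *Pangenome* classes are core
(present in all n species), dispensable (2..n−1), private (exactly 1);
percentages are rounded half-up to two decimals, matching how such tables
are printed.

## Simulator

A root genome (default 11 chromosomes — the conserved eucalypt karyotype —
at 39% GC) evolves down a user-supplied rooted phylogeny. Per branch,
event counts per class are Poisson(rate × branch length) unless pinned to
exact counts (used to plant events); structural events are applied first
(INV, TRANS, DUP, INS, DEL), then small indels, then substitutions. Every
mutation is journalled with the coordinates at application time, and the
simulator and the replay path share one `apply_event` implementation, so
replaying the journal reproduces each tip byte-for-byte by construction.
Translocation destinations are intra- or inter-chromosomal with probability
0.5 each; duplications are tandem or dispersed with probability 0.5 each;
both moves may be inverted. Spans that do not fit their chromosome are
resampled up to 100 times, then skipped with a logged warning. Per-edge
seeds derive from SHA-256 of (master seed, head-node label), so results are
independent of traversal order. Coordinates are 0-based half-open
everywhere internally; conversion happens only in writers (GFF3 and the
SyRI-like TSV are 1-based inclusive).

Default rates (per genome per unit branch length: inversion 2,
translocation 20, duplication 40, insertion 15, deletion 15; substitution
0.01/bp, small indels 2×10⁻⁴/bp) and default sizes (inversions 5–10 kbp,
translocations 1–3 kbp, duplications and indel events 0.5–2 kbp) reproduce
the qualitative regime seen between congeneric plant genomes —
duplications shortest and most common, translocations intermediate,
inversions long and very rare — scaled to desk-size genomes. Absolute
rates are not calibrated to any particular genus.

The gene synthesiser plants non-overlapping gene intervals (default
0.05 genes/kbp, 1–3 kbp long — about 10% genic, eucalypt-like) and assigns
each orthogroup a class with default fractions 21.33% core / 76.00%
dispensable / 2.67% private, the proportions reported for the eucalypt
pangenome; ~2% of genes are left unplaced, mimicking orthology-clustering
dropout. Placement is uniform via sorted cuts of the free space, so
intervals never overlap.

What the simulator does **not** emulate: repeat families and TE expansions
(the dominant source of real unaligned sequence), heterozygosity and
assembly artefacts, polyploidy, introgression, or rate heterogeneity along
chromosomes. Passing recovery tests therefore demonstrates correctness of
the classification logic on clean rearrangement signals, not performance on
repeat-rich real assemblies, where anchor filtering and the copy cap do
more work.

## Ground-truth scoring

Journal coordinates refer to the genome state when an event was applied;
`truth.py` transforms an event's expected footprint forward through later
events (and inversely, back to the common-ancestor frame and forward along
the partner lineage) to predict where the annotation should appear in each
tip. Events whose footprint a later event disrupts — on either lineage of
the pair being scored — no longer exist as a distinct two-genome signal and
are excluded from recovery denominators as *confounded* (they are reported
separately). A planted inversion that a later inversion (or inverted move)
on either lineage re-mirrors an odd number of times appears forward in the
pair and is likewise confounded; the tracker carries orientation parity
alongside coordinates to detect this. A short-range intra-chromosomal translocation is accepted in
either of its two equivalent descriptions (segment X moving past its
neighbour Y is indistinguishable from Y moving past X; the classifier keeps
the heavier chunk syntenic). Recovery requires the correct class and both
breakpoints within ±100 bp — anchor-envelope resolution; there is no
base-level breakpoint refinement.

## Problem sizes and numerical choices

The recovery benchmark uses four tips on a balanced tree
(`((A,B),(C,D))`), 11 chromosomes × 100 kbp, with 2 inversions (5–10 kbp),
5 translocations (1–3 kbp) and 8 duplications (0.5–2 kbp) planted per
branch at substitution rate 0.5%/unit; the divergence-trend run uses a
6-tip caterpillar whose pairwise distances span 10× on 4 × 50 kbp genomes;
lineage tracing uses 10 replicates of a 4-tip tree with one tip as
outgroup. These sizes were chosen so the full suite completes in minutes on
one CPU while leaving dozens to hundreds of planted events per check.
Ties are broken deterministically throughout (documented per function);
all randomness flows from explicit seeds, and every reported percentage
that mirrors a printed table is rounded half-up to two decimals.

## Known limitations

- Breakpoints have block-envelope resolution; ±100 bp is the honest
  tolerance, and sub-100 bp events are invisible.
- Nested rearrangements (an event inside or across another) may be
  classified as the surrounding class or split; the truth tracker flags
  these as confounded rather than pretending they are recoverable.
- The classifier emits only the five coarse classes — no SNP/small-indel
  catalogue, no nested multi-resolution annotation.
- OLS on pairwise points inherits phylogenetic non-independence; R² and
  p-values are descriptive, as in the analyses this package mirrors.
- `maxmatch` semantics are approximated by the per-seed copy cap; on
  repeat-dense sequence some repeat matches beyond the cap are not
  reported (a warning is logged).
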