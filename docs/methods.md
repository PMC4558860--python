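# Methods

This note documents the models and procedures implemented in retroscape,
the defaults chosen where the underlying method leaves room, and what the
synthetic benchmarks do and do not establish about behaviour on real data.

## The simulator: what it emulates

`synthio` generates the statistical structure the analysis assumes rather
than a biophysically faithful genome. An ancestral sequence of i.i.d.
uniform ACGT carries `n_genes` non-overlapping multi-exon genes (default
4–8 exons of 100–300 nt, introns 500–3,000 nt). Exonic sequence is rewritten
as random sense codons so that a CDS can be projected without internal
stops, and introns open with GT and close with AG on the gene strand so
spliced and chimeric reads have canonical junctions to satisfy. Repeat
intervals (default 15% of the genome, 150–800 nt, subfamily labels drawn
from configurable weights) are annotation-only: their sequence is not
repetitive, so they exercise flank-masking and composition logic without
creating mapping ambiguity. An optional X chromosome (default 5% of the
genome) carries genes and insertion sites for the X-flux statistics.

Evolution walks the tree root-to-leaves. Each branch applies point
substitutions at `substitution_rate × branch_length` (every substitution
changes the base; no indels), then plants its configured insertions at the
branch midpoint: the parental transcript as of that moment, optionally
5′-truncated (probability 0.35, removing up to 40% of the transcript — a
range under which the two-exon detectability requirement survives
essentially always), a polyA tail of 10–30 nt, inserted at a uniform
non-genic position, or intronic when `intragenic_prob` fires. Chimeric
copies are forced onto the plus strand of a plus-strand host and the
reference bases at the future junction (donor GT after the upstream host
exon, acceptor AG immediately before the insertion point) are set at
planting time. Descendants inherit every insertion at the syntenic position
and keep diverging.

With the default rate of 0.0015 substitutions/site/Myr on the `(A:6,B:6):2`
tree, a root-edge copy diverges from its leaf parent by ≈ 2 × 0.0015 × 7 ≈
2.1% and a leaf-edge copy by ≈ 0.9%; the benchmark "2% divergence" regime
therefore describes the ancestral copies, which dominate the default
scenario (100 of 200). These numbers were fixed once as the study
conditions of the benchmark.

Not modelled, hence not demonstrated by passing tests: realistic base
composition and repeat sequence (so no mapping ambiguity from the repeat
complement itself), indel evolution (the internal aligner is
substitution-only; real data should come in as externally produced PSL),
target-site duplications, segmental duplications, assembly gaps, and
expression noise beyond uniform coverage with lognormal per-gene levels.

## Detection

Internal alignment is exact-k-mer seeding (k = 12, mirroring common
seed-and-extend practice), per-(reference, diagonal) grouping with ≥ 2
seeds, maximal-scoring ungapped extension under +1/−3 scoring, and a small
DP that chains colinear segments across target gaps up to 15 kb — the same
bound as the intron-gap exclusion filter, so a parental locus chains into
one alignment (then rejected) while a retrocopy inserted near its parent
separates. Chains are extracted iteratively per cluster so two loci within
one window both survive.

Filter semantics: identity is matches/(matches + mismatches), ignoring
unaligned query sequence; a candidate needs identity > 0.75 and (coverage >
0.5 or ≥ 120 nt aligned) and no internal target gap > 15 kb. The call
requires a run of ≥ 2 consecutive parental exons, each > 50 nt aligned,
joined by junctions whose target-side displacement is ≤ 30 nt ("adjacently
aligned"; 30 nt admits small indels while excluding any real intron, whose
minimum plausible size is an order of magnitude larger). Overlap with the
parental gene's annotated span — any overlap, not merely exonic — discards
a candidate; this is deliberately conservative against partially annotated
isoforms calling their own locus. Overlapping candidate loci collapse to
the representative with the highest identity × coverage (ties: longer
alignment, then lexicographically smallest transcript id) regardless of
which isoform or gene produced them, which makes outputs deterministic. A
curated exclusion list (gene ids) replaces any manual removal step.

## Orthology, dating, rates

Flank signatures collect, outward from each locus edge, maximal
repeat-free runs ≥ 150 nt until 3,000 nt per side (the last run truncated
to hit the cap). The scan starts beyond a guard band equal to the call's
unaligned query remainder — protection against under-annotated copy
boundaries (an unaligned 5′ stub, the polyA tail) leaking into the
fingerprint — plus an optional fixed `search_offset` (0 by default; 5,000
is the documented preset for heavily under-annotated inputs). Sides are in
genome orientation; inversions are out of scope.

Two calls pair when they share the parental gene and one side's flank
aligns to the other call's same side covering ≥ 50% of the collected nt at
≥ 70% identity. Support is evaluated in both directions and the better
taken, making the relation symmetric; pairing is 1-to-1 per species pair
(best coverage, then identity, then call ids). The 50%/70% thresholds are
configuration with documented defaults: they translate a score-based
alignment cutoff into reproducible coverage/identity semantics.

Groups are connected components of the pairwise match graph, split per
parental gene; a call matched to no other species is species-specific. The
origin branch is the edge above the MRCA of the presence pattern (gains
only; losses are not modelled). Patterns smaller than the MRCA's full leaf
set are kept and flagged discordant rather than dropped, since
species-specific and sparse patterns are known to carry false negatives.
Branch rate is simply count/duration (Myr); the reporting layer rounds to
the nearest integer, matching the precision such tables are printed at.

The X-flux statistic counts, in a designated subset, copies whose parent is
X-linked but which sit on an autosome (out of X) and the converse (into X);
expected counts come from the corresponding proportions among all calls
outside the subset, and significance from a one-sided binomial test. The
choice of the binomial construction is ours; the underlying method names no
test.

## Ka/Ks

CDS projection: the parent transcript is re-aligned locally to the called
locus (±200 nt), parent CDS positions are mapped through the alignment
blocks, and codons pair exactly. Codons not fully covered (alignment gaps,
truncation) are dropped; codon columns containing a stop in either sequence
are dropped and counted in a diagnostics field — retrocopies accumulate
nonsense changes, and removing the column follows the same logic as gap
removal without inventing pathway semantics through stops. The retrocopy
"CDS" is thus the projection of the parent's; no independent retrogene
annotation is assumed.

NG86: per-position synonymous-site fractions (substitutions to stops count
as nonsynonymous sites), sites averaged between the two sequences;
difference counts average over all shortest substitution pathways,
excluding pathways through stop intermediates; when every pathway is
blocked the raw difference count is split by the codon pair's mean site
proportions. Jukes–Cantor is undefined at p ≥ 3/4 (flagged `saturated`);
Ka/Ks with Ks = 0 is reported as undefined and excluded from medians, so a
handful of short, barely diverged pairs cannot inject infinities into a
distribution summary. The implementation is checked in two independent
ways: closed-form anchors (one synonymous change in ten GGG codons gives
Ks = 0.1073; TTT→TTC alone saturates at pS = 3/4) and a brute-force
enumeration oracle kept in the test suite.

`compare_to_random` draws sets without replacement, reports the target
median against the median of per-set medians, and a two-sample
Mann–Whitney U (normal approximation, tie-corrected) between the target and
one random draw — the simplest null consistent with "random sets of equal
size".

## Expression

The decoy reference holds each retrocopy locus ± 300 nt of genomic flank
(long enough to absorb boundary-spanning reads, short enough not to create
spurious uniqueness) plus the parental mature mRNAs; identical sequences
are deliberately not collapsed — ambiguity must surface as low mapping
quality, because that is the decoy's entire purpose. The bundled read
aligner assigns MAPQ = min(60, 6 × (best − second-best score)) under +1/−3
scoring, so a read needs at least two bases distinguishing the copy from
its parent to clear the MAPQ > 40 filter. A read counts when it clears that
filter and overlaps the retrocopy portion (flank-only placements are
discarded); a copy is expressed in a tissue at ≥ 2 unique reads — one read
is indistinguishable from noise, and the threshold is configurable since no
canonical value exists. Normalized expression is reads per kilobase per
million counted reads per tissue.

Chimeric events are (host gene, retrocopy, junction) triples supported by
≥ 5 junction-spanning reads, each MAPQ > 40, with one side in a host exon,
the other inside the called locus (± 5 nt slack for edge trimming), and
GT…AG at the reference junction interior in the host's transcription
orientation.

τ is computed on normalized means without log transform (the index is
defined on relative levels; a log2(x+1) transform can be applied by the
caller). Context classes follow the precedence chimeric-intragenic >
intragenic > near-TSS > near-polyA > distant with an exclusive 15-kb bound
measured from the locus edges. The permutation test drops length-matched
loci uniformly and scores the intragenic-or-near fraction against the
observed one with p = (1 + #{null ≥ obs})/(n + 1); because gene spans
expanded by 15 kb bound both TSS and polyA proximity for single-isoform
annotations, the null classification reduces to interval membership and
runs vectorised. Correlation analysis reports plain per-pair Spearman ρ
with average-rank ties; aggregated or binned variants are intentionally not
implemented.

## Numerical and degenerate-input choices

Identity of an alignment with no aligned columns is 0; zero-length queries
raise. τ raises on all-zero vectors and on fewer than two tissues.
Divergence tables reject non-positive durations; `branch_rate` rejects
non-positive durations. Empty flank sides are flagged, not errors. The χ²
enrichment test rejects tables with a zero marginal. All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; reruns of
the pipeline with the same manifest are byte-identical, which the test
suite asserts file by file.

## Benchmark problem sizes

The standing benchmarks use 2 species × 10 Mb with 200 planted copies for
detection, a 4-leaf tree at 2 Mb per species with insertions on all seven
edges for branch dating, 1,000 random 30-codon pairs for the NG86 oracle
check, and 1,000 seeded null replicates for the calibration of the
permutation and Mann–Whitney tests (the permutation replicate uses 63 loci
and 199 permutations, granular enough that the discrete p-value's type-I
error stays near the nominal 5%). These sizes were chosen as the smallest
at which the recovery statistics are stable to well under the tested
margins.

## Known limitations

Real genomes bring repeat-derived mapping ambiguity, indels, inversions and
incomplete annotation that the simulator does not generate; the recovery
rates measured here are therefore upper bounds on real-data performance,
and the detection aligner should be replaced by externally produced PSL for
anything beyond desk scale. Losses are not modelled in dating, so a true
loss inflates younger branches. Ka/Ks uses unweighted pathway averaging
without transition/transversion or codon-frequency corrections. The
species-specific-expression notion (expressed in exactly one species of a
group) is implemented as a report column but has no calibrated benchmark.
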