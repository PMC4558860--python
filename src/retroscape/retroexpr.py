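"""Expressed-retrocopy calling, tissue specificity and genomic context.

Two complementary strategies mirror how transcription of a near-identical
gene copy can be established despite multi-mapping reads:

* chimeric strategy — spliced reads joining a host-gene exon to an
  intragenic retrocopy across a canonical GT-AG junction prove the retrocopy
  is exonified into the host transcript;
* unique-alignment strategy — reads are aligned against a decoy reference
  holding every retrocopy locus (plus short genomic flanks) alongside the
  parental mature mRNAs, and only confidently unique placements inside the
  retrocopy portion are counted.

On top of the per-tissue read support: the tau specificity index, a
precedence-based genomic-context classification, a permutation test for
enrichment near genes, and Spearman expression correlations.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from . import _seq, aligner
from .io_formats import GeneSet, SamRead
from .retrofind import RetrocopyCall

__all__ = [
    "ExpressionThresholds",
    "ExpressionProfile",
    "ChimericEvent",
    "detect_chimeric",
    "build_decoy_reference",
    "align_to_decoy",
    "call_expressed",
    "tau",
    "classify_context",
    "permutation_context_test",
    "expression_correlations",
]

CONTEXT_CLASSES = (
    "intragenic_same_chimeric",
    "intragenic_opposite_chimeric",
    "intragenic",
    "near_TSS_same",
    "near_TSS_opposite",
    "near_polyA_same",
    "near_polyA_opposite",
    "distant",
)


@dataclass(frozen=True)
class ExpressionThresholds:
    min_chimeric_reads: int = 5
    min_mapq: int = 40
    canonical_donor: str = "GT"
    canonical_acceptor: str = "AG"
    context_distance: int = 15_000
    n_permutations: int = 10_000
    min_unique_reads: int = 2

    def __post_init__(self) -> None:
        for name in ("min_chimeric_reads", "min_mapq", "context_distance",
                     "n_permutations", "min_unique_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ChimericEvent:
    host_gene: str
    retro_id: str
    junction: tuple[int, int]  # intron interval on the reference
    n_reads: int
    host_strand: str


@dataclass
class ExpressionProfile:
    retro_id: str
    counts: dict[str, int] = field(default_factory=dict)
    rpkm: dict[str, float] = field(default_factory=dict)
    expressed: bool = False
    chimeric: bool = False
    tau: float | None = None
    context_class: str | None = None

    @property
    def mean_expression(self) -> float:
        return float(np.mean(list(self.rpkm.values()))) if self.rpkm else 0.0


# ---------------------------------------------------------------------------
# chimeric strategy
# ---------------------------------------------------------------------------


def detect_chimeric(
    reads: list[SamRead],
    genes: GeneSet,
    calls: list[RetrocopyCall],
    genome: dict[str, np.ndarray],
    thresholds: ExpressionThresholds = ExpressionThresholds(),
) -> list[ChimericEvent]:
    """Host-gene/retrocopy junction events with canonical splice sites.

    An event is one (host gene, retrocopy, junction) triple. It is accepted
    when it is supported by at least ``min_chimeric_reads`` reads, every
    supporting read maps with MAPQ above ``min_mapq``, one junction side
    lies in a host exon while the other falls inside the retrocopy locus,
    and the reference junction interior reads GT..AG in the host gene's
    transcription orientation.
    """
    exon_trees: dict[str, IntervalTree] = {}
    for tx in genes.transcripts():
        tree = exon_trees.setdefault(tx.chrom, IntervalTree())
        for e in tx.exons:
            tree.addi(e.start, e.end, (tx.gene_id, tx.strand))
    call_trees: dict[str, IntervalTree] = {}
    for c in calls:
        # 5 nt of slack absorbs edge trimming of the called locus relative
        # to the physical insertion boundary
        call_trees.setdefault(c.locus.chrom, IntervalTree()).addi(
            max(0, c.locus.start - 5), c.locus.end + 5, c.call_id
        )

    support: dict[tuple, int] = {}
    meta: dict[tuple, ChimericEvent] = {}
    for read in sorted(reads, key=lambda r: (r.chrom, r.start, r.name)):
        if read.mapq <= thresholds.min_mapq:
            continue
        if read.chrom not in genome:
            raise KeyError(f"read {read.name} maps to unknown contig {read.chrom}")
        for js, je in read.junctions():
            chrom = read.chrom
            left_exons = {d for iv in exon_trees.get(chrom, IntervalTree()).at(js - 1) for d in [iv.data]}
            right_exons = {d for iv in exon_trees.get(chrom, IntervalTree()).at(je) for d in [iv.data]}
            left_retro = {iv.data for iv in call_trees.get(chrom, IntervalTree()).at(js - 1)}
            right_retro = {iv.data for iv in call_trees.get(chrom, IntervalTree()).at(je)}
            pairs = [(g, r, st) for (g, st) in left_exons for r in right_retro] + [
                (g, r, st) for (g, st) in right_exons for r in left_retro
            ]
            for host_gene, retro_id, host_strand in pairs:
                donor = _seq.decode(genome[chrom][js : js + 2])
                acceptor = _seq.decode(genome[chrom][je - 2 : je])
                if host_strand == "+":
                    ok = donor == thresholds.canonical_donor and acceptor == thresholds.canonical_acceptor
                else:
                    # transcription orientation: revcomp of the interval
                    rc_donor = _seq.decode(_seq.revcomp(genome[chrom][je - 2 : je]))
                    rc_acceptor = _seq.decode(_seq.revcomp(genome[chrom][js : js + 2]))
                    ok = (
                        rc_donor == thresholds.canonical_donor
                        and rc_acceptor == thresholds.canonical_acceptor
                    )
                if not ok:
                    continue
                key = (host_gene, retro_id, js, je)
                support[key] = support.get(key, 0) + 1
                meta[key] = ChimericEvent(host_gene, retro_id, (js, je), 0, host_strand)
    events = []
    for key, n in sorted(support.items()):
        if n >= thresholds.min_chimeric_reads:
            ev = meta[key]
            ev.n_reads = n
            events.append(ev)
    return events


# ---------------------------------------------------------------------------
# unique-alignment strategy
# ---------------------------------------------------------------------------


@dataclass
class DecoyReference:
    """Retrocopy loci (with genomic flanks) plus parental mature mRNAs."""

    sequences: dict[str, np.ndarray]
    retro_portion: dict[str, tuple[int, int]]  # entry -> retro interval within it


def build_decoy_reference(
    calls: list[RetrocopyCall],
    genome: dict[str, np.ndarray],
    genes: GeneSet,
    flank: int = 300,
) -> DecoyReference:
    seqs: dict[str, np.ndarray] = {}
    portion: dict[str, tuple[int, int]] = {}
    for c in calls:
        lo = max(0, c.locus.start - flank)
        hi = min(genome[c.locus.chrom].size, c.locus.end + flank)
        name = f"retro|{c.call_id}"
        seqs[name] = genome[c.locus.chrom][lo:hi].copy()
        portion[name] = (c.locus.start - lo, c.locus.end - lo)
    parental = {c.parental_gene for c in calls}
    for tx in genes.transcripts():
        if tx.gene_id in parental:
            seqs[f"mrna|{tx.transcript_id}"] = tx.sequence(genome)
    return DecoyReference(seqs, portion)


@dataclass
class DecoyAlignment:
    read_name: str
    entry: str
    start: int
    end: int
    score: int
    mapq: int


def align_to_decoy(
    reads: list[SamRead],
    decoy: DecoyReference,
    k: int = 12,
    mapq_per_score: int = 6,
) -> list[DecoyAlignment]:
    """Best placement of each read in the decoy reference, with a
    uniqueness-derived mapping quality.

    MAPQ = min(60, ``mapq_per_score`` x (best score - second-best score))
    under +1/-3 scoring, so a read needs at least two bases distinguishing
    the retrocopy from its parent to clear a MAPQ-40 filter — the decoy's
    whole purpose.
    """
    index = aligner.GenomeIndex(decoy.sequences, k=k)
    out = []
    for read in reads:
        qarr = _seq.encode(read.seq)
        best = None  # (score, entry, start, end)
        second = 0
        for aln in aligner.align_query(index, read.name, qarr, min_seeds=1, min_chain_matches=20):
            score = aln.matches - 3 * aln.mismatches
            placement = (score, aln.target_name, aln.target_start, aln.target_end)
            if best is None or score > best[0]:
                if best is not None:
                    second = max(second, best[0])
                best = placement
            else:
                second = max(second, score)
        if best is None:
            continue
        mapq = min(60, mapq_per_score * (best[0] - second)) if second else 60
        out.append(DecoyAlignment(read.name, best[1], best[2], best[3], best[0], mapq))
    return out


def call_expressed(
    alignments_by_tissue: dict[str, list[DecoyAlignment]],
    calls: list[RetrocopyCall],
    decoy: DecoyReference,
    thresholds: ExpressionThresholds = ExpressionThresholds(),
) -> dict[str, ExpressionProfile]:
    """Per-retrocopy expression profiles from unique decoy alignments.

    A read counts for a retrocopy in a tissue iff its MAPQ exceeds
    ``min_mapq`` and its placement overlaps the retrocopy portion of the
    entry (flank-only placements are discarded). A retrocopy is expressed
    in a tissue when its unique-read count reaches ``min_unique_reads``;
    normalized expression is reads per kilobase per million counted reads.
    """
    entry_of = {f"retro|{c.call_id}": c for c in calls}
    profiles = {c.call_id: ExpressionProfile(c.call_id) for c in calls}
    for tissue, alns in alignments_by_tissue.items():
        total_unique = 0
        counts: dict[str, int] = {c.call_id: 0 for c in calls}
        for a in alns:
            if a.mapq <= thresholds.min_mapq:
                continue
            total_unique += 1
            call = entry_of.get(a.entry)
            if call is None:
                continue
            lo, hi = decoy.retro_portion[a.entry]
            if a.start < hi and lo < a.end:
                counts[call.call_id] += 1
        for c in calls:
            n = counts[c.call_id]
            profiles[c.call_id].counts[tissue] = n
            kb = len(c.locus) / 1000.0
            denom = max(total_unique, 1) / 1e6
            profiles[c.call_id].rpkm[tissue] = n / kb / denom
    for c in calls:
        prof = profiles[c.call_id]
        prof.expressed = any(
            n >= thresholds.min_unique_reads for n in prof.counts.values()
        )
        if prof.expressed and len(prof.rpkm) >= 2:
            vec = [
                prof.rpkm[t] if prof.counts[t] >= thresholds.min_unique_reads else 0.0
                for t in prof.rpkm
            ]
            prof.tau = tau(vec)
    return profiles


# ---------------------------------------------------------------------------
# tissue specificity
# ---------------------------------------------------------------------------


def tau(expression: list[float] | np.ndarray) -> float:
    """Yanai's tissue-specificity index: 0 = uniform, 1 = single-tissue."""
    x = np.asarray(expression, dtype=float)
    if x.size < 2:
        raise ValueError("tau requires at least 2 tissues")
    if (x < 0).any():
        raise ValueError("expression values must be non-negative")
    m = x.max()
    if m == 0:
        raise ValueError("tau undefined for an all-zero vector")
    return float(np.sum(1.0 - x / m) / (x.size - 1))


# ---------------------------------------------------------------------------
# genomic context
# ---------------------------------------------------------------------------


def classify_context(
    call: RetrocopyCall,
    genes: GeneSet,
    chimeric_events: list[ChimericEvent],
    thresholds: ExpressionThresholds = ExpressionThresholds(),
) -> str:
    """One context class per call, by precedence:

    chimeric intragenic (same/opposite host strand) > intragenic >
    near TSS (<15 kb, same/opposite strand) > near polyA (<15 kb) > distant.
    Distances are measured from the retrocopy edges, exclusive bound.
    """
    locus = call.locus
    chimeric = [e for e in chimeric_events if e.retro_id == call.call_id]
    host = None
    for gene in genes.genes.values():
        if gene.gene_id == call.parental_gene:
            continue
        if gene.span.overlaps(locus):
            host = gene
            break
    if chimeric and host is not None:
        same = chimeric[0].host_strand == locus.strand
        return "intragenic_same_chimeric" if same else "intragenic_opposite_chimeric"
    if chimeric:
        same = chimeric[0].host_strand == locus.strand
        return "intragenic_same_chimeric" if same else "intragenic_opposite_chimeric"
    if host is not None:
        return "intragenic"
    best_tss = best_polya = None
    for tx in genes.transcripts():
        if tx.gene_id == call.parental_gene or tx.chrom != locus.chrom:
            continue
        d_tss = _point_distance(locus, tx.tss)
        d_pa = _point_distance(locus, tx.polya_site)
        if d_tss < thresholds.context_distance and (best_tss is None or d_tss < best_tss[0]):
            best_tss = (d_tss, tx.strand)
        if d_pa < thresholds.context_distance and (best_polya is None or d_pa < best_polya[0]):
            best_polya = (d_pa, tx.strand)
    if best_tss is not None:
        return "near_TSS_same" if best_tss[1] == locus.strand else "near_TSS_opposite"
    if best_polya is not None:
        return "near_polyA_same" if best_polya[1] == locus.strand else "near_polyA_opposite"
    return "distant"


def _point_distance(locus, point: int) -> int:
    """Nt separating a point from the nearest locus base (0 if inside)."""
    return max(locus.start - point, point - (locus.end - 1), 0)


# ---------------------------------------------------------------------------
# permutation context test
# ---------------------------------------------------------------------------


def permutation_context_test(
    expressed_calls: list[RetrocopyCall],
    genome_sizes: dict[str, int],
    genes: GeneSet,
    thresholds: ExpressionThresholds = ExpressionThresholds(),
    seed: int = 0,
) -> tuple[float, np.ndarray, float]:
    """Are expressed retrocopies enriched near or within genes?

    Each permutation drops length-matched loci uniformly on the genome and
    scores the fraction that land intragenic-or-near (within
    ``context_distance`` of a gene span, which bounds both TSS and polyA
    proximity). One-sided p = (1 + #{null >= observed}) / (n + 1).
    """
    if not expressed_calls:
        raise ValueError("no expressed calls given")
    n_perm = thresholds.n_permutations
    if n_perm <= 0:
        raise ValueError("n_permutations must be positive")
    d = thresholds.context_distance
    # merged "non-distant" intervals per chromosome: gene spans +- d
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, size in genome_sizes.items():
        ivs = sorted(
            (max(0, g.span.start - d + 1), min(size, g.span.end + d - 1))
            for g in genes.genes.values()
            if g.chrom == chrom
        )
        out: list[list[int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        arr = np.asarray(out, dtype=np.int64).reshape(-1, 2)
        merged[chrom] = (arr[:, 0], arr[:, 1])

    def near_fraction(chroms: list[str], starts: np.ndarray, lengths: np.ndarray) -> float:
        hits = 0
        for chrom, s, ln in zip(chroms, starts, lengths):
            ms, me = merged[chrom]
            if ms.size == 0:
                continue
            e = s + ln
            i = int(np.searchsorted(ms, e, side="left")) - 1
            # locus [s,e) overlaps merged interval i or the one starting before e
            if i >= 0 and me[i] > s:
                hits += 1
            elif i + 1 < ms.size and ms[i + 1] < e:
                hits += 1
        return hits / len(lengths)

    obs_chroms = [c.locus.chrom for c in expressed_calls]
    obs_starts = np.array([c.locus.start for c in expressed_calls])
    lengths = np.array([len(c.locus) for c in expressed_calls])
    observed = near_fraction(obs_chroms, obs_starts, lengths)

    rng = np.random.default_rng(seed)
    names = sorted(genome_sizes)
    sizes = np.array([genome_sizes[c] for c in names], dtype=float)
    probs = sizes / sizes.sum()
    null = np.empty(n_perm)
    for i in range(n_perm):
        which = rng.choice(len(names), size=lengths.size, p=probs)
        chroms = [names[w] for w in which]
        limits = np.array([genome_sizes[c] for c in chroms]) - lengths
        starts = (rng.random(lengths.size) * np.maximum(limits, 1)).astype(np.int64)
        null[i] = near_fraction(chroms, starts, lengths)
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return observed, null, p


# ---------------------------------------------------------------------------
# expression correlations
# ---------------------------------------------------------------------------


def expression_correlations(
    pairings: dict[str, tuple[list[float], list[float]]],
) -> list[dict]:
    """Spearman rank correlation (average ranks for ties) per pairing type.

    ``pairings`` maps a label (e.g. ``parental``, ``host_same_strand``,
    ``downstream_neighbor``) to matched expression vectors. Fewer than three
    pairs yields an undefined, flagged entry.
    """
    out = []
    for label in sorted(pairings):
        x, y = pairings[label]
        if len(x) != len(y):
            raise ValueError(f"pairing {label!r} has mismatched lengths")
        if len(x) < 3:
            out.append({"pair_type": label, "rho": None, "p": None, "n": len(x), "defined": False})
            continue
        rho, p = stats.spearmanr(x, y)
        out.append({"pair_type": label, "rho": float(rho), "p": float(p), "n": len(x), "defined": True})
    return out
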