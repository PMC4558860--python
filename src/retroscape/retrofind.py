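"""Retrocopy detection from transcript-to-genome chained alignments.

A retrocopy of a multiexonic gene betrays itself as an intronless genomic
alignment of the mature mRNA: consecutive parental exons land adjacently on
the target with no intron-sized gap between them. The filters here encode
that signature: minimum identity, minimum coverage (or absolute aligned
length), exclusion of intron-sized internal gaps, a requirement for at least
two adjacently aligned parental exons, and exclusion of the parental locus
itself. Single-exon genes are undetectable by construction.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import aligner
from .io_formats import ChainedAlignment, GeneSet, GenomicInterval, Transcript

__all__ = [
    "DetectionThresholds",
    "RetrocopyCall",
    "align_transcripts",
    "filter_alignments",
    "call_retrocopies",
    "catalog_summary",
    "detect",
    "write_calls",
    "read_calls",
    "write_bed",
]


@dataclass(frozen=True)
class DetectionThresholds:
    """Filter settings; defaults follow the published pipeline."""

    min_identity: float = 0.75
    min_query_coverage: float = 0.50
    min_aligned_nt: int = 120
    max_internal_gap: int = 15_000
    min_exon_aligned_nt: int = 50
    min_adjacent_exons: int = 2
    junction_gap_tolerance: int = 30

    def __post_init__(self) -> None:
        if not 0 <= self.min_identity <= 1 or not 0 <= self.min_query_coverage <= 1:
            raise ValueError("min_identity and min_query_coverage must lie in [0,1]")
        for name in ("min_aligned_nt", "max_internal_gap", "min_exon_aligned_nt",
                     "min_adjacent_exons", "junction_gap_tolerance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class RetrocopyCall:
    """One called retrocopy locus with its parental assignment."""

    locus: GenomicInterval
    parental_gene: str
    parental_transcript: str
    identity: float
    query_coverage: float
    aligned_nt: int
    n_exons_bridged: int
    on_x: bool = False
    parent_on_x: bool = False

    @property
    def call_id(self) -> str:
        return f"{self.locus.chrom}:{self.locus.start}-{self.locus.end}|{self.parental_gene}"

    @property
    def score(self) -> tuple:
        return (self.identity * self.query_coverage, self.aligned_nt, self.parental_transcript)


def align_transcripts(
    genes: GeneSet, genome: dict[str, np.ndarray], **kwargs
) -> list[ChainedAlignment]:
    """Align every annotated transcript back to its genome."""
    seqs = {tx.transcript_id: tx.sequence(genome) for tx in genes.transcripts()}
    return aligner.align_transcripts(seqs, genome, **kwargs)


def filter_alignments(
    alignments: list[ChainedAlignment], thresholds: DetectionThresholds = DetectionThresholds()
) -> list[ChainedAlignment]:
    """Identity / coverage / internal-gap filters on raw alignments.

    Keeps an alignment iff identity > min_identity, and either query coverage
    > min_query_coverage or at least min_aligned_nt nucleotides aligned, and
    no target gap between blocks exceeds max_internal_gap (a putative intron).
    """
    kept = []
    for aln in alignments:
        if aln.query_length == 0:
            raise ValueError(f"alignment of {aln.query_name} has query_length 0")
        if aln.identity <= thresholds.min_identity:
            continue
        if not (
            aln.query_coverage > thresholds.min_query_coverage
            or aln.aligned_nt >= thresholds.min_aligned_nt
        ):
            continue
        if any(g > thresholds.max_internal_gap for g in aln.target_gaps()):
            continue
        kept.append(aln)
    return kept


def call_retrocopies(
    alignments: list[ChainedAlignment],
    genes: GeneSet,
    thresholds: DetectionThresholds = DetectionThresholds(),
    exclude_genes: set[str] | None = None,
) -> list[RetrocopyCall]:
    """Apply the intronless-signature test and per-locus merging.

    ``exclude_genes`` plays the role of a curated removal list (e.g. known
    problematic gene families); matching parental genes are dropped.
    """
    candidates: list[RetrocopyCall] = []
    for aln in alignments:
        try:
            tx = genes.transcript(aln.query_name)
        except KeyError as exc:
            raise KeyError(f"no gene model for transcript {aln.query_name}") from exc
        if exclude_genes and tx.gene_id in exclude_genes:
            continue
        gene = genes.genes[tx.gene_id]
        if aln.target_interval.overlaps(gene.span):
            continue  # the parental locus itself
        if tx.n_exons < 2:
            continue  # single-exon genes are not detectable
        run, _aligned_nt = _exon_support_strict(aln, tx, thresholds)
        if run < thresholds.min_adjacent_exons:
            continue
        candidates.append(
            RetrocopyCall(
                locus=aln.target_interval,
                parental_gene=tx.gene_id,
                parental_transcript=tx.transcript_id,
                identity=aln.identity,
                query_coverage=aln.query_coverage,
                aligned_nt=aln.aligned_nt,
                n_exons_bridged=run,
                on_x=aln.target_name == "chrX",
                parent_on_x=gene.chrom == "chrX",
            )
        )
    return _merge_overlapping(candidates)


def _exon_support_strict(aln, tx, thresholds) -> tuple[int, list[int]]:
    """Longest run of consecutive exons, each contributing more than the
    per-exon aligned minimum, joined by target-bridged junctions."""
    offsets = tx.exon_offsets()
    blocks = sorted(aln.blocks)
    aligned_nt = []
    for (estart, eend) in offsets:
        total = 0
        for q, _, ln in blocks:
            total += max(0, min(q + ln, eend) - max(q, estart))
        aligned_nt.append(total)
    qualifying = [nt > thresholds.min_exon_aligned_nt for nt in aligned_nt]
    bridged = _junctions_bridged(aln, tx, thresholds.junction_gap_tolerance)
    best, i, n = 0, 0, len(offsets)
    while i < n:
        if not qualifying[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and bridged[j] and qualifying[j + 1]:
            j += 1
        best = max(best, j - i + 1)
        i = j + 1
    return best, aligned_nt


def _junctions_bridged(aln: ChainedAlignment, tx: Transcript, tol: int) -> list[bool]:
    offsets = tx.exon_offsets()
    blocks = sorted(aln.blocks)

    def query_to_target(q: int) -> int | None:
        for qs, ts, ln in blocks:
            if qs <= q < qs + ln:
                return ts + (q - qs) if aln.strand == "+" else ts + (qs + ln - 1 - q)
        return None

    def nearest_aligned(q: int, direction: int) -> int | None:
        best = None
        for qs, _, ln in blocks:
            if direction < 0 and qs <= q:
                cand = min(q, qs + ln - 1)
                best = cand if best is None else max(best, cand)
            if direction > 0 and qs + ln - 1 >= q:
                cand = max(q, qs)
                best = cand if best is None else min(best, cand)
        return best

    out = []
    for (estart, _eend), (nstart, nend) in zip(offsets, offsets[1:]):
        qa = nearest_aligned(nstart - 1, -1)
        qb = nearest_aligned(nstart, +1)
        ok = False
        if qa is not None and qb is not None and qa >= estart and qb < nend:
            ta, tb = query_to_target(qa), query_to_target(qb)
            if ta is not None and tb is not None:
                ok = abs(abs(tb - ta) - (qb - qa)) <= tol and (qb - qa) <= tol + 1
        out.append(ok)
    return out


def _merge_overlapping(calls: list[RetrocopyCall]) -> list[RetrocopyCall]:
    """Collapse overlapping candidate loci to the best-supported call.

    Isoforms of one gene hitting one locus, and cross-gene collisions, both
    resolve to the representative with the highest identity x coverage
    (ties: longer alignment, then lexicographic transcript id).
    """
    calls = sorted(calls, key=lambda c: (c.locus.chrom, c.locus.start, c.locus.end))
    merged: list[list[RetrocopyCall]] = []
    for call in calls:
        if merged and merged[-1][0].locus.chrom == call.locus.chrom and call.locus.start < max(
            c.locus.end for c in merged[-1]
        ):
            merged[-1].append(call)
        else:
            merged.append([call])
    out = []
    for group in merged:
        group.sort(key=lambda c: (-c.identity * c.query_coverage, -c.aligned_nt, c.parental_transcript))
        out.append(group[0])
    return sorted(out, key=lambda c: (c.locus.chrom, c.locus.start))


def catalog_summary(calls_by_species: dict[str, list[RetrocopyCall]]) -> pd.DataFrame:
    """Per-species retrocopy and distinct parental-gene counts."""
    rows = [
        {
            "species": sp,
            "n_retrocopies": len(calls),
            "n_parental_genes": len({c.parental_gene for c in calls}),
        }
        for sp, calls in calls_by_species.items()
    ]
    return pd.DataFrame(rows, columns=["species", "n_retrocopies", "n_parental_genes"])


def detect(
    genes: GeneSet,
    genome: dict[str, np.ndarray],
    thresholds: DetectionThresholds = DetectionThresholds(),
    alignments: list[ChainedAlignment] | None = None,
    exclude_genes: set[str] | None = None,
) -> list[RetrocopyCall]:
    """Full detection pass: align (unless alignments supplied), filter, call."""
    if alignments is None:
        alignments = align_transcripts(genes, genome)
    surviving = filter_alignments(alignments, thresholds)
    return call_retrocopies(surviving, genes, thresholds, exclude_genes=exclude_genes)


_CALL_COLUMNS = [
    "chrom",
    "start",
    "end",
    "strand",
    "parental_gene",
    "parental_transcript",
    "identity",
    "query_coverage",
    "aligned_nt",
    "n_exons_bridged",
    "on_x",
    "parent_on_x",
]


def write_calls(path: str | os.PathLike, calls: list[RetrocopyCall], header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        fh.write("\t".join(_CALL_COLUMNS) + "\n")
        for c in calls:
            row = [
                c.locus.chrom, c.locus.start, c.locus.end, c.locus.strand,
                c.parental_gene, c.parental_transcript,
                f"{c.identity:.6f}", f"{c.query_coverage:.6f}",
                c.aligned_nt, c.n_exons_bridged, int(c.on_x), int(c.parent_on_x),
            ]
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_calls(path: str | os.PathLike) -> list[RetrocopyCall]:
    out = []
    with open(path) as fh:
        header = None
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            if header is None:
                header = line.rstrip("\n").split("\t")
                continue
            vals = dict(zip(header, line.rstrip("\n").split("\t")))
            out.append(
                RetrocopyCall(
                    locus=GenomicInterval(vals["chrom"], int(vals["start"]), int(vals["end"]), vals["strand"]),
                    parental_gene=vals["parental_gene"],
                    parental_transcript=vals["parental_transcript"],
                    identity=float(vals["identity"]),
                    query_coverage=float(vals["query_coverage"]),
                    aligned_nt=int(vals["aligned_nt"]),
                    n_exons_bridged=int(vals["n_exons_bridged"]),
                    on_x=vals["on_x"] == "1",
                    parent_on_x=vals["parent_on_x"] == "1",
                )
            )
    return out


def write_bed(path: str | os.PathLike, calls: list[RetrocopyCall]) -> None:
    """BED6 export: name = parental_gene|parental_transcript, score = 1000*identity."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.locus.chrom}\t{c.locus.start}\t{c.locus.end}\t"
                f"{c.parental_gene}|{c.parental_transcript}\t{round(1000 * c.identity)}\t{c.locus.strand}\n"
            )
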