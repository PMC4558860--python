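"""Readers/writers for on-disk formats and the coordinate-convention boundary.

Every coordinate inside the package is 0-based, half-open, on the plus strand
of its sequence. The converters in this module are the only place where the
1-based inclusive conventions of GTF and RepeatMasker ``.out`` files, or the
reversed-query block starts of minus-strand PSL records, are translated.
"""
from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pysam
from Bio import Phylo, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import _seq

__all__ = [
    "GenomicInterval",
    "ChainedAlignment",
    "RepeatAnnotation",
    "Transcript",
    "Gene",
    "GeneSet",
    "SamRead",
    "SpeciesTree",
    "DivergenceTable",
    "read_fasta",
    "write_fasta",
    "read_psl",
    "write_psl",
    "read_gtf",
    "write_gtf",
    "read_repeatmasker",
    "write_repeatmasker",
    "read_sam",
    "write_sam",
    "read_newick",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance(self, other: "GenomicInterval") -> int:
        """Edge-to-edge distance; 0 when overlapping, inf across chromosomes."""
        if self.chrom != other.chrom:
            return int(1e18)
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass
class ChainedAlignment:
    """A gapped, co-linear chain of ungapped blocks (the PSL record shape).

    ``blocks`` holds (query_start, target_start, length) triples with both
    coordinates on the plus strand of their sequence, sorted by query start.
    On the minus strand the target coordinate decreases as the query
    coordinate increases.
    """

    query_name: str
    query_length: int
    target_name: str
    target_length: int
    strand: str
    blocks: list[tuple[int, int, int]]
    matches: int
    mismatches: int

    @property
    def aligned_nt(self) -> int:
        return sum(b[2] for b in self.blocks)

    @property
    def identity(self) -> float:
        denom = self.matches + self.mismatches
        return self.matches / denom if denom else 0.0

    @property
    def query_coverage(self) -> float:
        if self.query_length == 0:
            raise ValueError(f"query {self.query_name} has zero length")
        return self.aligned_nt / self.query_length

    @property
    def target_start(self) -> int:
        return min(t for _, t, _ in self.blocks)

    @property
    def target_end(self) -> int:
        return max(t + ln for _, t, ln in self.blocks)

    @property
    def target_interval(self) -> GenomicInterval:
        return GenomicInterval(self.target_name, self.target_start, self.target_end, self.strand)

    def target_gaps(self) -> list[int]:
        """Gap on the target between consecutive blocks, in target order."""
        spans = sorted((t, t + ln) for _, t, ln in self.blocks)
        return [nxt - end for (_, end), (nxt, _) in zip(spans, spans[1:])]

    def query_gaps(self) -> list[int]:
        spans = sorted((q, q + ln) for q, _, ln in self.blocks)
        return [nxt - end for (_, end), (nxt, _) in zip(spans, spans[1:])]

    def validate(self) -> None:
        if self.matches + self.mismatches > self.aligned_nt:
            raise ValueError("matches+mismatches exceed aligned length")
        qs = sorted((q, q + ln) for q, _, ln in self.blocks)
        if any(b[1] > a[0] for a, b in zip(qs[1:], qs)):
            raise ValueError("query blocks overlap")
        ts = sorted((t, t + ln) for _, t, ln in self.blocks)
        if any(b[1] > a[0] for a, b in zip(ts[1:], ts)):
            raise ValueError("target blocks overlap")


@dataclass(frozen=True)
class RepeatAnnotation:
    interval: GenomicInterval
    repeat_class: str
    subfamily: str


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


@dataclass
class Transcript:
    """One transcript: exons ordered 5'->3' in transcript orientation."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
            self.strand,
        )

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def tss(self) -> int:
        """Transcription start position (0-based) on the genome."""
        return self.span.start if self.strand == "+" else self.span.end - 1

    @property
    def polya_site(self) -> int:
        return self.span.end - 1 if self.strand == "+" else self.span.start

    def exon_offsets(self) -> list[tuple[int, int]]:
        """(start, end) of each exon in transcript (query) coordinates, 5'->3'."""
        out, pos = [], 0
        for e in self.exons:
            out.append((pos, pos + len(e)))
            pos += len(e)
        return out

    def sequence(self, genome: dict[str, np.ndarray]) -> np.ndarray:
        chrom = genome[self.chrom]
        exons = self.exons if self.strand == "+" else list(reversed(self.exons))
        parts = [chrom[e.start : e.end] for e in exons]
        seq = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        return _seq.revcomp(seq) if self.strand == "-" else seq

    def validate(self) -> None:
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise FormatError(
                    f"transcript {self.transcript_id} has overlapping exons"
                )


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    @property
    def span(self) -> GenomicInterval:
        starts = [t.span.start for t in self.transcripts.values()]
        ends = [t.span.end for t in self.transcripts.values()]
        return GenomicInterval(self.chrom, min(starts), max(ends), self.strand)


class GeneSet:
    """Container of genes with transcript lookup."""

    def __init__(self, genes: dict[str, Gene] | None = None):
        self.genes: dict[str, Gene] = genes or {}

    def add_transcript(self, tx: Transcript) -> None:
        gene = self.genes.setdefault(tx.gene_id, Gene(tx.gene_id, tx.chrom, tx.strand))
        gene.transcripts[tx.transcript_id] = tx

    def transcripts(self):
        for gene in self.genes.values():
            yield from gene.transcripts.values()

    def transcript(self, transcript_id: str) -> Transcript:
        for gene in self.genes.values():
            if transcript_id in gene.transcripts:
                return gene.transcripts[transcript_id]
        raise KeyError(transcript_id)

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | os.PathLike) -> dict[str, np.ndarray]:
    """Load a FASTA file into encoded arrays keyed by record id."""
    return {rec.id: _seq.encode(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | os.PathLike, seqs: dict[str, np.ndarray], width: int = 70) -> None:
    records = [
        SeqRecord(Seq(_seq.decode(arr)), id=name, description="") for name, arr in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# PSL
# ---------------------------------------------------------------------------

_PSL_HEADER_TOKENS = ("psLayout", "match", "-----")


def read_psl(path: str | os.PathLike) -> list[ChainedAlignment]:
    """Parse a PSL file (BLAT's tab-separated alignment table).

    Minus-strand query block starts (which PSL stores on the reversed query)
    are normalized to plus-strand query coordinates.
    """
    out: list[ChainedAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or any(
                line.startswith(tok) for tok in _PSL_HEADER_TOKENS
            ):
                continue
            fields = line.split("\t")
            if len(fields) < 21:
                fields = line.split()
            if len(fields) < 21:
                raise FormatError(f"{path}:{lineno}: expected 21 PSL fields")
            try:
                matches, mismatches = int(fields[0]), int(fields[1])
                strand = fields[8]
                qname, qsize = fields[9], int(fields[10])
                tname, tsize = fields[13], int(fields[14])
                nblocks = int(fields[17])
                sizes = [int(x) for x in fields[18].rstrip(",").split(",")]
                qstarts = [int(x) for x in fields[19].rstrip(",").split(",")]
                tstarts = [int(x) for x in fields[20].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if not (len(sizes) == len(qstarts) == len(tstarts) == nblocks):
                raise FormatError(f"{path}:{lineno}: block count mismatch")
            blocks = []
            for ln, qs, ts in zip(sizes, qstarts, tstarts):
                if strand.startswith("-"):
                    qs = qsize - qs - ln  # reversed-query -> plus-strand query
                blocks.append((qs, ts, ln))
            blocks.sort()
            aln = ChainedAlignment(
                query_name=qname,
                query_length=qsize,
                target_name=tname,
                target_length=tsize,
                strand="-" if strand.startswith("-") else "+",
                blocks=blocks,
                matches=matches,
                mismatches=mismatches,
            )
            aln.validate()
            out.append(aln)
    return out


def write_psl(path: str | os.PathLike, alignments: list[ChainedAlignment]) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            # order blocks by target; derive PSL bookkeeping fields
            blocks = sorted(a.blocks, key=lambda b: b[1])
            qspans = sorted((q, q + ln) for q, _, ln in a.blocks)
            q_gaps = [n - e for (_, e), (n, _) in zip(qspans, qspans[1:])]
            t_gaps = a.target_gaps()
            qstart, qend = qspans[0][0], qspans[-1][1]
            sizes = ",".join(str(b[2]) for b in blocks) + ","
            if a.strand == "-":
                qstarts = ",".join(str(a.query_length - q - ln) for q, _, ln in blocks) + ","
            else:
                qstarts = ",".join(str(q) for q, _, _ in blocks) + ","
            tstarts = ",".join(str(t) for _, t, _ in blocks) + ","
            row = [
                a.matches,
                a.mismatches,
                0,
                0,
                sum(1 for g in q_gaps if g > 0),
                sum(g for g in q_gaps if g > 0),
                sum(1 for g in t_gaps if g > 0),
                sum(g for g in t_gaps if g > 0),
                a.strand,
                a.query_name,
                a.query_length,
                qstart,
                qend,
                a.target_name,
                a.target_length,
                a.target_start,
                a.target_end,
                len(blocks),
                sizes,
                qstarts,
                tstarts,
            ]
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------


def _gtf_attributes(raw: str) -> dict[str, str]:
    attrs = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | os.PathLike) -> GeneSet:
    """Parse GTF (1-based inclusive) into 0-based half-open gene models."""
    exons: dict[str, Transcript] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _src, feature, start, end, _score, strand, _frame, raw = fields
            if feature not in ("exon", "CDS"):
                continue
            attrs = _gtf_attributes(raw)
            if "transcript_id" not in attrs:
                raise FormatError(f"{path}:{lineno}: missing transcript_id")
            if "gene_id" not in attrs:
                raise FormatError(f"{path}:{lineno}: missing gene_id")
            tid, gid = attrs["transcript_id"], attrs["gene_id"]
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            tx = exons.setdefault(tid, Transcript(tid, gid, chrom, strand, []))
            if feature == "exon":
                tx.exons.append(iv)
            else:
                tx.cds.append(iv)
    genes = GeneSet()
    for tx in exons.values():
        tx.exons.sort(key=lambda e: e.start, reverse=(tx.strand == "-"))
        tx.cds.sort(key=lambda e: e.start, reverse=(tx.strand == "-"))
        tx.validate()
        genes.add_transcript(tx)
    return genes


def write_gtf(path: str | os.PathLike, genes: GeneSet, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for gene in genes.genes.values():
            span = gene.span
            fh.write(_gtf_line(gene.chrom, "gene", span, gene.strand, gene.gene_id, None))
            for tx in gene.transcripts.values():
                fh.write(
                    _gtf_line(tx.chrom, "transcript", tx.span, tx.strand, gene.gene_id, tx.transcript_id)
                )
                for ex in sorted(tx.exons, key=lambda e: e.start):
                    fh.write(_gtf_line(tx.chrom, "exon", ex, tx.strand, gene.gene_id, tx.transcript_id))
                for cds in sorted(tx.cds, key=lambda e: e.start):
                    fh.write(_gtf_line(tx.chrom, "CDS", cds, tx.strand, gene.gene_id, tx.transcript_id))


def _gtf_line(chrom, feature, iv, strand, gene_id, transcript_id) -> str:
    attrs = f'gene_id "{gene_id}";'
    if transcript_id:
        attrs += f' transcript_id "{transcript_id}";'
    return "\t".join(
        [chrom, "retroscape", feature, str(iv.start + 1), str(iv.end), ".", strand, ".", attrs]
    ) + "\n"


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

_RM_HEADER = (
    "   SW   perc perc perc  query     position in query          matching  repeat        position in repeat\n"
    "score   div. del. ins.  sequence  begin  end      (left)     repeat    class/family  begin end   (left)  ID\n"
    "\n"
)


def read_repeatmasker(path: str | os.PathLike) -> list[RepeatAnnotation]:
    """Parse RepeatMasker ``.out`` (whitespace table, 1-based inclusive)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if len(fields) < 11 or not fields[0].isdigit():
                continue  # 3-line header / blank lines
            try:
                chrom = fields[4]
                start, end = int(fields[5]) - 1, int(fields[6])
                strand = "-" if fields[8] in ("C", "-") else "+"
                subfamily, repclass = fields[9], fields[10]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            out.append(
                RepeatAnnotation(GenomicInterval(chrom, start, end, strand), repclass, subfamily)
            )
    return out


def write_repeatmasker(path: str | os.PathLike, repeats: list[RepeatAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, rep in enumerate(repeats, 1):
            iv = rep.interval
            strand = "+" if iv.strand == "+" else "C"
            fh.write(
                f"  225   1.0  0.0  0.0  {iv.chrom}  {iv.start + 1}  {iv.end}  (0)  "
                f"{strand}  {rep.subfamily}  {rep.repeat_class}  1  {len(iv)}  (0)  {i}\n"
            )


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


@dataclass
class SamRead:
    """A mapped read with its reference placement and CIGAR."""

    name: str
    chrom: str
    start: int  # 0-based leftmost reference position
    mapq: int
    cigar: list[tuple[str, int]]
    strand: str
    seq: str
    flag: int = 0

    _CONSUME_REF = set("MDN=X")
    _KNOWN = set("MIDNSHP=X")

    def blocks(self) -> list[tuple[int, int]]:
        """Reference intervals covered by aligned (M/=/X) stretches."""
        out, pos = [], self.start
        for op, ln in self.cigar:
            if op not in self._KNOWN:
                raise FormatError(f"unknown CIGAR op {op!r} in read {self.name}")
            if op in "M=X":
                out.append((pos, pos + ln))
                pos += ln
            elif op in "DN":
                pos += ln
        # merge abutting blocks split by D ops
        merged: list[tuple[int, int]] = []
        for s, e in out:
            if merged and s == merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        return merged

    def junctions(self) -> list[tuple[int, int]]:
        """(intron_start, intron_end) reference intervals of N operations."""
        out, pos = [], self.start
        for op, ln in self.cigar:
            if op == "N":
                out.append((pos, pos + ln))
            if op in self._CONSUME_REF:
                pos += ln
        return out


def read_sam(path: str | os.PathLike) -> list[SamRead]:
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            cigar = [(op, ln) for op, ln in zip(_cigar_ops(rec), _cigar_lens(rec))]
            reads.append(
                SamRead(
                    name=rec.query_name,
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    mapq=rec.mapping_quality,
                    cigar=cigar,
                    strand="-" if rec.is_reverse else "+",
                    seq=rec.query_sequence or "",
                    flag=rec.flag,
                )
            )
    return reads


_CIGAR_CODES = "MIDNSHP=X"


def _cigar_ops(rec) -> list[str]:
    return [_CIGAR_CODES[op] for op, _ in (rec.cigartuples or [])]


def _cigar_lens(rec) -> list[int]:
    return [ln for _, ln in (rec.cigartuples or [])]


def write_sam(path: str | os.PathLike, reads: list[SamRead], references: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in references.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for r in reads:
            flag = r.flag | (16 if r.strand == "-" else 0)
            cigar = "".join(f"{ln}{op}" for op, ln in r.cigar)
            fh.write(
                f"{r.name}\t{flag}\t{r.chrom}\t{r.start + 1}\t{r.mapq}\t{cigar}\t*\t0\t0\t{r.seq}\t*\n"
            )


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------


class SpeciesTree:
    """A rooted, ultrametric species tree with branch lengths in Myr.

    Edges are keyed by the name of the clade below them; unnamed internal
    clades are assigned deterministic names (``root``, ``n1``, ``n2``, ... in
    preorder). The edge above the root (the stem) carries the root's branch
    length, or 0 when the newick gives none.
    """

    def __init__(self, tree) -> None:
        self._tree = tree
        counter = 0
        for clade in tree.find_clades(order="preorder"):
            if not clade.name:
                if clade is tree.root:
                    clade.name = "root"
                else:
                    counter += 1
                    clade.name = f"n{counter}"
        self._clades = {c.name: c for c in tree.find_clades()}
        self._parent = {}
        for clade in tree.find_clades(order="preorder"):
            for child in clade.clades:
                self._parent[child.name] = clade.name

    @classmethod
    def from_newick(cls, source: str) -> "SpeciesTree":
        handle = io.StringIO(source)
        return cls(Phylo.read(handle, "newick"))

    @property
    def root(self) -> str:
        return self._tree.root.name

    @property
    def leaves(self) -> list[str]:
        return [t.name for t in self._tree.get_terminals()]

    def parent(self, node: str) -> str | None:
        return self._parent.get(node)

    def children(self, node: str) -> list[str]:
        return [c.name for c in self._clades[node].clades]

    def branch_length(self, node: str) -> float:
        """Length (Myr) of the edge above ``node``; stem length for the root."""
        bl = self._clades[node].branch_length
        return float(bl) if bl is not None else 0.0

    def leafset(self, node: str) -> frozenset[str]:
        clade = self._clades[node]
        if clade.is_terminal():
            return frozenset([clade.name])
        return frozenset(t.name for t in clade.get_terminals())

    def edges(self) -> list[str]:
        """All edge names (clade-below names) in preorder, root stem first."""
        return [c.name for c in self._tree.find_clades(order="preorder")]

    def mrca(self, leaves: set[str] | frozenset[str]) -> str:
        leaves = set(leaves)
        if len(leaves) == 1:
            return next(iter(leaves))
        clade = self._tree.common_ancestor([self._clades[x] for x in leaves])
        return clade.name

    def age(self, node: str) -> float:
        """Time from ``node`` to the present (leaves are at age 0)."""
        clade = self._clades[node]
        if clade.is_terminal():
            return 0.0
        leaf = clade.get_terminals()[0]
        return float(self._tree.distance(clade, leaf))

    def node_depth_from_root(self, node: str) -> float:
        return float(self._tree.distance(self._tree.root, self._clades[node]))


def read_newick(path: str | os.PathLike) -> SpeciesTree:
    with open(path) as fh:
        return SpeciesTree.from_newick(fh.read())


# ---------------------------------------------------------------------------
# divergence-time table
# ---------------------------------------------------------------------------


@dataclass
class DivergenceTable:
    """Branch durations (Myr) keyed by branch id, with ordered split ages."""

    durations: dict[str, float]
    split_ages: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.durations.values()):
            raise ValueError("branch durations must be positive")
        if any(b >= a for a, b in zip(self.split_ages[1:], self.split_ages)) and sorted(
            self.split_ages
        ) != self.split_ages:
            raise ValueError("split ages must be increasing")

    @classmethod
    def from_tree(cls, tree: SpeciesTree) -> "DivergenceTable":
        durations = {e: tree.branch_length(e) for e in tree.edges() if tree.branch_length(e) > 0}
        ages = sorted({tree.age(n) for n in tree.edges() if tree.age(n) > 0})
        return cls(durations, ages)

    @classmethod
    def read(cls, path: str | os.PathLike) -> "DivergenceTable":
        durations = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                branch, dur = line.split("\t")[:2]
                if branch == "branch_id":
                    continue
                durations[branch] = float(dur)
        return cls(durations)

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("branch_id\tduration_myr\n")
            for branch, dur in self.durations.items():
                fh.write(f"{branch}\t{dur}\n")
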