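"""Multi-species genome simulator with planted mRNA retrocopies.

The simulator builds an ancestral genome carrying multi-exon protein-coding
genes and annotated repeat intervals, evolves it along a rooted species tree
by point substitution, and on each branch plants the configured number of
retrocopies: the parental transcript's exons concatenated (optionally
5'-truncated), a polyA tail appended, inserted at a random non-genic (or,
optionally, intronic) position. Descendant species inherit insertions at
syntenic positions and keep diverging, which is exactly the signal the
detection and orthology stages consume. Ground truth for every planted copy
(locus, parent, origin branch, truncation, mutation load, expression and
chimera status) is recorded so recovery can be scored.

Deliberately not modelled: realistic base composition, indels, target-site
duplications, segmental duplications and assembly gaps.
"""
from __future__ import annotations

import copy
import math
import os
from dataclasses import dataclass, field

import numpy as np

from . import _seq
from .io_formats import (
    DivergenceTable,
    GeneSet,
    GenomicInterval,
    RepeatAnnotation,
    SamRead,
    SpeciesTree,
    Transcript,
    write_fasta,
    write_gtf,
    write_repeatmasker,
    write_sam,
)

__all__ = [
    "SimulationConfig",
    "PlantedRetrocopy",
    "GroundTruth",
    "SpeciesGenome",
    "SimulationResult",
    "CapacityError",
    "simulate_species",
    "simulate_reads",
]

# sense codons (strings over ACGT) used to fill CDS regions
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

DEFAULT_TISSUES = ("brain", "cerebellum", "heart", "liver", "kidney", "testis")


class CapacityError(RuntimeError):
    """Genome too small to host the requested genes or insertions."""


@dataclass
class SimulationConfig:
    """Study conditions for one simulated clade.

    Defaults describe the standard two-species benchmark: 10-Mb genomes on a
    ``(A:6,B:6):2`` tree, 200 planted retrocopies (100 ancestral, 50 per
    leaf) and a substitution rate that yields roughly 1-2% retrocopy-parent
    divergence.
    """

    seed: int = 0
    species_tree: str = "(A:6,B:6):2;"
    genome_length: int = 10_000_000
    n_genes: int = 120
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_length: tuple[int, int] = (100, 300)
    intron_length: tuple[int, int] = (500, 3000)
    n_retrocopies_per_branch: dict[str, int] = field(
        default_factory=lambda: {"root": 100, "A": 50, "B": 50}
    )
    substitution_rate: float = 0.0015  # substitutions / site / Myr
    truncation_prob: float = 0.35
    max_truncation_fraction: float = 0.4
    polyA_length: tuple[int, int] = (10, 30)
    repeat_fraction: float = 0.15
    repeat_length: tuple[int, int] = (150, 800)
    repeat_subfamily_weights: dict[str, float] = field(
        default_factory=lambda: {
            "L1PA7": 0.20,
            "L1PA5": 0.15,
            "L1PA3": 0.10,
            "L1P3": 0.05,
            "AluY": 0.50,
        }
    )
    x_chromosome_fraction: float = 0.05
    intragenic_prob: float = 0.0
    expressed_fraction: float = 0.3
    chimeric_prob: float = 0.5  # among expressed intragenic copies
    multi_isoform: bool = False
    tissues: tuple[str, ...] = DEFAULT_TISSUES

    def validate(self) -> None:
        for name in (
            "truncation_prob",
            "max_truncation_fraction",
            "repeat_fraction",
            "x_chromosome_fraction",
            "intragenic_prob",
            "expressed_fraction",
            "chimeric_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.substitution_rate < 0:
            raise ValueError("substitution_rate must be >= 0")
        for name in ("exons_per_gene", "exon_length", "intron_length", "polyA_length", "repeat_length"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} range ({lo},{hi}) invalid")
        if self.genome_length <= 0 or self.n_genes < 0:
            raise ValueError("genome_length and n_genes must be positive")


@dataclass
class PlantedRetrocopy:
    """Ground truth for one planted copy in one species."""

    retro_id: str
    species: str
    chrom: str
    start: int
    end: int  # includes the polyA tail
    strand: str
    parental_gene: str
    parental_transcript: str
    origin_branch: str
    truncation_nt: int
    polya_nt: int
    mutation_count: int
    host_gene: str | None = None
    chimeric: bool = False
    expressed_tissues: frozenset = frozenset()

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def on_x(self) -> bool:
        return self.chrom == "chrX"


_TRUTH_COLUMNS = [
    "retro_id",
    "species",
    "chrom",
    "start",
    "end",
    "strand",
    "parental_gene",
    "parental_transcript",
    "origin_branch",
    "truncation_nt",
    "polya_nt",
    "mutation_count",
    "host_gene",
    "chimeric",
    "expressed_tissues",
]


@dataclass
class GroundTruth:
    """Planted-retrocopy records grouped per species."""

    records: dict[str, list[PlantedRetrocopy]]

    def all_records(self) -> list[PlantedRetrocopy]:
        return [r for recs in self.records.values() for r in recs]

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(_TRUTH_COLUMNS) + "\n")
            for rec in self.all_records():
                row = [
                    rec.retro_id,
                    rec.species,
                    rec.chrom,
                    rec.start,
                    rec.end,
                    rec.strand,
                    rec.parental_gene,
                    rec.parental_transcript,
                    rec.origin_branch,
                    rec.truncation_nt,
                    rec.polya_nt,
                    rec.mutation_count,
                    rec.host_gene or ".",
                    int(rec.chimeric),
                    ",".join(sorted(rec.expressed_tissues)) or ".",
                ]
                fh.write("\t".join(str(x) for x in row) + "\n")

    @classmethod
    def read(cls, path: str | os.PathLike) -> "GroundTruth":
        records: dict[str, list[PlantedRetrocopy]] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                vals = dict(zip(header, line.rstrip("\n").split("\t")))
                rec = PlantedRetrocopy(
                    retro_id=vals["retro_id"],
                    species=vals["species"],
                    chrom=vals["chrom"],
                    start=int(vals["start"]),
                    end=int(vals["end"]),
                    strand=vals["strand"],
                    parental_gene=vals["parental_gene"],
                    parental_transcript=vals["parental_transcript"],
                    origin_branch=vals["origin_branch"],
                    truncation_nt=int(vals["truncation_nt"]),
                    polya_nt=int(vals["polya_nt"]),
                    mutation_count=int(vals["mutation_count"]),
                    host_gene=None if vals["host_gene"] == "." else vals["host_gene"],
                    chimeric=vals["chimeric"] == "1",
                    expressed_tissues=frozenset(
                        [] if vals["expressed_tissues"] == "." else vals["expressed_tissues"].split(",")
                    ),
                )
                records.setdefault(rec.species, []).append(rec)
        return cls(records)


@dataclass
class SpeciesGenome:
    name: str
    genome: dict[str, np.ndarray]
    genes: GeneSet
    repeats: list[RepeatAnnotation]


@dataclass
class SimulationResult:
    config: SimulationConfig
    tree: SpeciesTree
    species: dict[str, SpeciesGenome]
    ground_truth: GroundTruth

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        for name, sp in self.species.items():
            write_fasta(os.path.join(outdir, f"{name}.fa"), sp.genome)
            write_gtf(os.path.join(outdir, f"{name}.gtf"), sp.genes)
            write_repeatmasker(os.path.join(outdir, f"{name}.rm.out"), sp.repeats)
        self.ground_truth.write(os.path.join(outdir, "ground_truth.tsv"))
        with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
            fh.write(self.config.species_tree.strip() + "\n")
        DivergenceTable.from_tree(self.tree).write(os.path.join(outdir, "divergence.tsv"))


# ---------------------------------------------------------------------------
# internal mutable annotation state evolved down the tree
# ---------------------------------------------------------------------------


@dataclass
class _SimGene:
    gene_id: str
    transcript_ids: list[str]
    chrom: str
    strand: str
    # per transcript: list of [start, end) exon pairs in genomic order
    exons: dict[str, list[list[int]]]
    cds: dict[str, list[list[int]]]

    @property
    def span(self) -> tuple[int, int]:
        coords = [c for tx in self.exons.values() for pair in tx for c in pair]
        return min(coords), max(coords)

    def transcript_seq(self, genome: dict[str, np.ndarray], tx_id: str) -> np.ndarray:
        pairs = self.exons[tx_id]
        parts = [genome[self.chrom][s:e] for s, e in pairs]
        seq = np.concatenate(parts)
        return _seq.revcomp(seq) if self.strand == "-" else seq


@dataclass
class _State:
    genome: dict[str, np.ndarray]
    genes: list[_SimGene]
    repeats: list[list]  # [chrom, start, end, strand, subfamily, repclass]
    planted: list[PlantedRetrocopy]

    def clone(self) -> "_State":
        return _State(
            genome={c: arr.copy() for c, arr in self.genome.items()},
            genes=copy.deepcopy(self.genes),
            repeats=copy.deepcopy(self.repeats),
            planted=copy.deepcopy(self.planted),
        )


def _shift_coords(state: _State, chrom: str, positions: list[int], lengths: list[int]) -> None:
    """Shift all annotation coordinates on ``chrom`` after batch insertion.

    ``positions`` are pre-insertion coordinates, strictly increasing.
    """
    pos = np.asarray(positions)
    offs = np.asarray(lengths).cumsum()

    def shift(x: int) -> int:
        i = int(np.searchsorted(pos, x, side="right"))
        return x + (int(offs[i - 1]) if i else 0)

    for gene in state.genes:
        if gene.chrom != chrom:
            continue
        for tx in gene.exons.values():
            for pair in tx:
                pair[0], pair[1] = shift(pair[0]), shift(pair[1])
        for tx in gene.cds.values():
            for pair in tx:
                pair[0], pair[1] = shift(pair[0]), shift(pair[1])
    for rep in state.repeats:
        if rep[0] == chrom:
            rep[1], rep[2] = shift(rep[1]), shift(rep[2])
    for rec in state.planted:
        if rec.chrom == chrom:
            rec.start, rec.end = shift(rec.start), shift(rec.end)


def _mutate_state(state: _State, p: float, rng: np.random.Generator) -> None:
    """Point-mutate every chromosome; track hits inside planted loci."""
    for chrom, arr in state.genome.items():
        mutated, positions = _seq.mutate(arr, p, rng)
        state.genome[chrom] = mutated
        if positions.size:
            for rec in state.planted:
                if rec.chrom == chrom:
                    lo, hi = np.searchsorted(positions, [rec.start, rec.end])
                    rec.mutation_count += int(hi - lo)


# ---------------------------------------------------------------------------
# ancestral genome construction
# ---------------------------------------------------------------------------


def _build_ancestor(config: SimulationConfig, rng: np.random.Generator) -> _State:
    xlen = int(round(config.genome_length * config.x_chromosome_fraction))
    chroms: dict[str, int] = {}
    if config.genome_length - xlen > 0:
        chroms["chr1"] = config.genome_length - xlen
    if xlen > 0:
        chroms["chrX"] = xlen
    genome = {c: _seq.random_seq(rng, ln) for c, ln in chroms.items()}

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    genes: list[_SimGene] = []
    names = list(chroms)
    weights = np.array([chroms[c] for c in names], dtype=float)
    weights /= weights.sum()

    for gi in range(config.n_genes):
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        ex_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, size=n_ex)
        in_lens = rng.integers(config.intron_length[0], config.intron_length[1] + 1, size=max(n_ex - 1, 0))
        span = int(ex_lens.sum() + in_lens.sum())
        placed = False
        for _ in range(1000):
            chrom = names[int(rng.choice(len(names), p=weights))]
            limit = chroms[chrom] - span - 200
            if limit <= 200:
                continue
            start = int(rng.integers(200, limit))
            if any(start < e + 2000 and s - 2000 < start + span for s, e in occupied[chrom]):
                continue
            occupied[chrom].append((start, start + span))
            placed = True
            break
        if not placed:
            raise CapacityError(
                f"could not place gene {gi} (span {span} nt) in a {config.genome_length} nt genome"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        exon_pairs, pos = [], start
        for k in range(n_ex):
            exon_pairs.append([pos, pos + int(ex_lens[k])])
            pos += int(ex_lens[k])
            if k < n_ex - 1:
                intron_start = pos
                pos += int(in_lens[k])
                # canonical GT..AG on the gene strand
                arr = genome[chrom]
                if strand == "+":
                    arr[intron_start : intron_start + 2] = _seq.encode("GT")
                    arr[pos - 2 : pos] = _seq.encode("AG")
                else:
                    arr[intron_start : intron_start + 2] = _seq.encode("CT")
                    arr[pos - 2 : pos] = _seq.encode("AC")
        gene_id = f"gene{gi:04d}"
        tx_id = f"{gene_id}.t1"
        gene = _SimGene(gene_id, [tx_id], chrom, strand, {tx_id: exon_pairs}, {})
        _fill_cds(gene, tx_id, genome, rng)
        if config.multi_isoform and n_ex >= 3 and rng.random() < 0.5:
            # second isoform skipping one internal exon
            skip = int(rng.integers(1, n_ex - 1))
            tx2 = f"{gene_id}.t2"
            gene.transcript_ids.append(tx2)
            gene.exons[tx2] = [list(p) for k, p in enumerate(exon_pairs) if k != skip]
            gene.cds[tx2] = []
        genes.append(gene)

    repeats = _place_repeats(config, rng, chroms, occupied)
    return _State(genome=genome, genes=genes, repeats=repeats, planted=[])


def _fill_cds(gene: _SimGene, tx_id: str, genome: dict[str, np.ndarray], rng: np.random.Generator) -> None:
    """Rewrite the transcript's exonic bases as sense codons and record CDS."""
    pairs = gene.exons[tx_id]
    tx_len = sum(e - s for s, e in pairs)
    n_codons = tx_len // 3
    codons = rng.choice(len(_SENSE_CODONS), size=n_codons)
    cds_seq = _seq.encode("".join(_SENSE_CODONS[i] for i in codons))
    mrna = np.concatenate([cds_seq, _seq.random_seq(rng, tx_len - 3 * n_codons)])
    if gene.strand == "-":
        genomic = _seq.revcomp(mrna)
        order = pairs
    else:
        genomic = mrna
        order = pairs
    pos = 0
    for s, e in order:
        genome[gene.chrom][s:e] = genomic[pos : pos + (e - s)]
        pos += e - s
    # CDS in genomic coordinates: whole exons trimmed to codon multiple at 3' end
    cds_left = 3 * n_codons
    cds_pairs: list[list[int]] = []
    tx_order = pairs if gene.strand == "+" else list(reversed(pairs))
    for s, e in tx_order:
        take = min(e - s, cds_left)
        if take <= 0:
            break
        if gene.strand == "+":
            cds_pairs.append([s, s + take])
        else:
            cds_pairs.append([e - take, e])
        cds_left -= take
    gene.cds[tx_id] = sorted(cds_pairs)


def _place_repeats(config, rng, chroms, occupied) -> list[list]:
    repeats: list[list] = []
    if config.repeat_fraction <= 0 or not config.repeat_subfamily_weights:
        return repeats
    total_target = config.repeat_fraction * sum(chroms.values())
    subfams = sorted(config.repeat_subfamily_weights)
    w = np.array([config.repeat_subfamily_weights[s] for s in subfams], dtype=float)
    w /= w.sum()
    names = list(chroms)
    cw = np.array([chroms[c] for c in names], dtype=float)
    cw /= cw.sum()
    placed_nt, tries = 0, 0
    intervals: dict[str, list[tuple[int, int]]] = {c: list(occupied[c]) for c in chroms}
    while placed_nt < total_target and tries < 200_000:
        tries += 1
        chrom = names[int(rng.choice(len(names), p=cw))]
        ln = int(rng.integers(config.repeat_length[0], config.repeat_length[1] + 1))
        if chroms[chrom] <= ln + 2:
            continue
        start = int(rng.integers(0, chroms[chrom] - ln))
        if any(start < e and s < start + ln for s, e in intervals[chrom]):
            continue
        intervals[chrom].append((start, start + ln))
        sub = subfams[int(rng.choice(len(subfams), p=w))]
        repclass = "LINE/L1" if sub.startswith("L1") else "SINE/Alu"
        strand = "+" if rng.random() < 0.5 else "-"
        repeats.append([chrom, start, start + ln, strand, sub, repclass])
        placed_nt += ln
    repeats.sort(key=lambda r: (r[0], r[1]))
    return repeats


# ---------------------------------------------------------------------------
# planting retrocopies
# ---------------------------------------------------------------------------


def _plant_on_edge(
    state: _State,
    edge: str,
    n: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    counter: list[int],
) -> None:
    if n <= 0:
        return
    pending: dict[str, list[tuple[int, np.ndarray, PlantedRetrocopy]]] = {}
    plus_genes = [g for g in state.genes if g.strand == "+"]
    for _ in range(n):
        gene = state.genes[int(rng.integers(len(state.genes)))]
        tx_id = gene.transcript_ids[0]
        seq = gene.transcript_seq(state.genome, tx_id)
        trunc = 0
        if rng.random() < config.truncation_prob:
            trunc = int(rng.random() * config.max_truncation_fraction * seq.size)
            seq = seq[trunc:]
        polya = int(rng.integers(config.polyA_length[0], config.polyA_length[1] + 1))
        insert_seq = np.concatenate([seq, np.zeros(polya, dtype=np.uint8)])  # 0 == A
        strand = "+" if rng.random() < 0.5 else "-"
        intragenic = rng.random() < config.intragenic_prob
        expressed = rng.random() < config.expressed_fraction
        chimeric = bool(intragenic and expressed and rng.random() < config.chimeric_prob)
        if chimeric:
            strand = "+"  # chimeras splice the host exon onto the copy's 5' side
        if strand == "-":
            insert_seq = _seq.revcomp(insert_seq)
        host_gene = None
        chrom = pos = None
        if intragenic:
            pool = plus_genes if chimeric else state.genes
            pool = [g for g in pool if g.gene_id != gene.gene_id and len(g.exons[g.transcript_ids[0]]) >= 2]
            if not pool:
                raise CapacityError("no gene can host an intragenic insertion")
            for _try in range(200):
                host = pool[int(rng.integers(len(pool)))]
                pairs = host.exons[host.transcript_ids[0]]
                k = int(rng.integers(len(pairs) - 1))
                lo, hi = pairs[k][1] + 50, pairs[k + 1][0] - 50
                if hi - lo < 10:
                    continue
                chrom, pos, host_gene = host.chrom, int(rng.integers(lo, hi)), host.gene_id
                if chimeric:
                    # canonical donor at the upstream exon boundary, acceptor
                    # immediately before the insertion point
                    arr = state.genome[chrom]
                    arr[pairs[k][1] : pairs[k][1] + 2] = _seq.encode("GT")
                    arr[pos - 2 : pos] = _seq.encode("AG")
                break
            else:
                raise CapacityError("no intron can host the requested intragenic insertion")
        else:
            names = list(state.genome)
            lens = np.array([state.genome[c].size for c in names], dtype=float)
            for _try in range(1000):
                chrom = names[int(rng.choice(len(names), p=lens / lens.sum()))]
                pos = int(rng.integers(100, state.genome[chrom].size - 100))
                bad = any(
                    g.chrom == chrom and g.span[0] <= pos < g.span[1] for g in state.genes
                ) or any(
                    r.chrom == chrom and r.start <= pos < r.end for r in state.planted
                )
                if not bad:
                    break
            else:
                raise CapacityError(
                    f"no non-genic position found for insertion on edge {edge}"
                )

        tissues: frozenset[str] = frozenset()
        if expressed:
            extra = [t for t in config.tissues if t != "testis" and rng.random() < 0.3]
            tissues = frozenset(["testis"] + extra)
        counter[0] += 1
        rec = PlantedRetrocopy(
            retro_id=f"retro{counter[0]:05d}",
            species="",  # filled at the leaves
            chrom=chrom,
            start=pos,
            end=pos + insert_seq.size,
            strand=strand,
            parental_gene=gene.gene_id,
            parental_transcript=tx_id,
            origin_branch=edge,
            truncation_nt=trunc,
            polya_nt=polya,
            mutation_count=0,
            host_gene=host_gene,
            chimeric=chimeric,
            expressed_tissues=tissues,
        )
        pending.setdefault(chrom, []).append((pos, insert_seq, rec))

    for chrom, items in pending.items():
        items.sort(key=lambda it: it[0])
        positions = [it[0] for it in items]
        lengths = [it[1].size for it in items]
        # rebuild the chromosome with all insertions in one pass
        arr = state.genome[chrom]
        parts, prev = [], 0
        for p, seqarr, _rec in items:
            parts.append(arr[prev:p])
            parts.append(seqarr)
            prev = p
        parts.append(arr[prev:])
        state.genome[chrom] = np.concatenate(parts)
        _shift_coords(state, chrom, positions, lengths)
        offset = 0
        for p, seqarr, rec in items:
            rec.start = p + offset
            rec.end = rec.start + seqarr.size
            offset += seqarr.size
            state.planted.append(rec)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def simulate_species(config: SimulationConfig) -> SimulationResult:
    """Run the full multi-species simulation described by ``config``."""
    config.validate()
    tree = SpeciesTree.from_newick(config.species_tree)
    if len(tree.leaves) < 2:
        raise ValueError("species tree must have at least 2 leaves")
    known = set(tree.edges())
    unknown = set(config.n_retrocopies_per_branch) - known
    if unknown:
        raise ValueError(f"n_retrocopies_per_branch names unknown branches: {sorted(unknown)}")

    rng = np.random.default_rng(config.seed)
    ancestor = _build_ancestor(config, rng)
    counter = [0]

    species: dict[str, SpeciesGenome] = {}
    truth: dict[str, list[PlantedRetrocopy]] = {}

    def descend(node: str, state: _State) -> None:
        # branch above `node`: new insertions are planted at the branch
        # midpoint, so a copy diverges from its parent over half the branch
        # plus the whole path below it
        blen = tree.branch_length(node)
        if blen > 0:
            _mutate_state(state, config.substitution_rate * blen / 2, rng)
        _plant_on_edge(state, node, config.n_retrocopies_per_branch.get(node, 0), config, rng, counter)
        if blen > 0:
            _mutate_state(state, config.substitution_rate * blen / 2, rng)
        children = tree.children(node)
        if not children:
            species[node] = _finalize(node, state)
            recs = copy.deepcopy(state.planted)
            for r in recs:
                r.species = node
            truth[node] = recs
            return
        for child in children[:-1]:
            descend(child, state.clone())
        descend(children[-1], state)

    descend(tree.root, ancestor)
    ordered = {leaf: truth[leaf] for leaf in tree.leaves}
    return SimulationResult(config, tree, species, GroundTruth(ordered))


def _finalize(name: str, state: _State) -> SpeciesGenome:
    genes = GeneSet()
    for g in state.genes:
        for tx_id in g.transcript_ids:
            exons = [
                GenomicInterval(g.chrom, s, e, g.strand) for s, e in sorted(g.exons[tx_id])
            ]
            cds = [
                GenomicInterval(g.chrom, s, e, g.strand) for s, e in sorted(g.cds.get(tx_id, []))
            ]
            if g.strand == "-":
                exons = list(reversed(exons))
                cds = list(reversed(cds))
            genes.add_transcript(Transcript(tx_id, g.gene_id, g.chrom, g.strand, exons, cds))
    repeats = [
        RepeatAnnotation(GenomicInterval(c, s, e, st), rc, sub)
        for c, s, e, st, sub, rc in state.repeats
    ]
    return SpeciesGenome(name, state.genome, genes, repeats)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def simulate_reads(
    species: SpeciesGenome,
    ground_truth: GroundTruth,
    tissues: list[str],
    depth: float,
    seed: int,
    read_length: int = 100,
    chimeric_support: int = 8,
    gene_depth_factor: float = 0.05,
    known_tissues: tuple[str, ...] = DEFAULT_TISSUES,
) -> dict[str, list[SamRead]]:
    """Generate genome-aligned reads per tissue for one species.

    Reads cover expressed retrocopy loci uniformly at the requested depth;
    host/parental transcripts get spliced (N-CIGAR) reads at a reduced depth
    so junction logic and expression correlations have material to work on;
    chimeric ground-truth events get ``chimeric_support`` junction reads each.
    Unexpressed loci receive no dedicated reads.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    for t in tissues:
        if t not in known_tissues:
            raise ValueError(f"unknown tissue {t!r}")
    rng = np.random.default_rng(seed)
    recs = ground_truth.records.get(species.name, [])
    genome = species.genome
    out: dict[str, list[SamRead]] = {t: [] for t in tissues}

    # per-gene per-tissue expression levels (relative depth multipliers)
    gene_levels: dict[str, dict[str, float]] = {}
    for gene in species.genes.genes.values():
        gene_levels[gene.gene_id] = {
            t: float(rng.lognormal(0.0, 0.5)) for t in tissues
        }

    def emit_uniform(tissue: str, chrom: str, start: int, end: int, n: int, prefix: str) -> None:
        if end - start <= read_length:
            return
        starts = rng.integers(start, end - read_length, size=n)
        for i, s in enumerate(sorted(int(x) for x in starts)):
            seq = _seq.decode(genome[chrom][s : s + read_length])
            out[tissue].append(
                SamRead(f"{prefix}_{tissue}_{i}", chrom, s, 60, [("M", read_length)], "+", seq)
            )

    for tissue in tissues:
        for rec in recs:
            if tissue in rec.expressed_tissues:
                n = max(2, int(math.ceil(depth * (rec.end - rec.start) / read_length)))
                emit_uniform(tissue, rec.chrom, rec.start, rec.end, n, rec.retro_id)
                if rec.chimeric and rec.host_gene is not None:
                    _emit_chimeric_reads(
                        out[tissue], rec, species, chimeric_support, read_length, rng
                    )
        for gene in species.genes.genes.values():
            tx = next(iter(gene.transcripts.values()))
            level = gene_levels[gene.gene_id][tissue]
            n = int(math.ceil(depth * gene_depth_factor * level * tx.length / read_length))
            _emit_transcript_reads(out[tissue], tx, genome, n, read_length, rng, tissue)
    return out


def _emit_transcript_reads(sink, tx, genome, n, read_length, rng, tissue) -> None:
    if tx.length <= read_length or n <= 0:
        return
    exons = sorted(tx.exons, key=lambda e: e.start)
    offsets = np.cumsum([0] + [len(e) for e in exons])
    starts = rng.integers(0, tx.length - read_length, size=n)
    for i, q in enumerate(sorted(int(x) for x in starts)):
        # map transcript-plus coords through the genomic exon chain
        cigar: list[tuple[str, int]] = []
        remaining, qpos = read_length, q
        ref_start = None
        k = int(np.searchsorted(offsets, qpos, side="right")) - 1
        while remaining > 0 and k < len(exons):
            off_in_exon = qpos - int(offsets[k])
            avail = len(exons[k]) - off_in_exon
            take = min(avail, remaining)
            if ref_start is None:
                ref_start = exons[k].start + off_in_exon
            cigar.append(("M", take))
            remaining -= take
            qpos += take
            if remaining > 0 and k + 1 < len(exons):
                cigar.append(("N", exons[k + 1].start - exons[k].end))
            k += 1
        if remaining > 0:
            continue
        seq_parts = []
        pos = ref_start
        for op, ln in cigar:
            if op == "M":
                seq_parts.append(genome[tx.chrom][pos : pos + ln])
            pos += ln
        seq = _seq.decode(np.concatenate(seq_parts))
        sink.append(
            SamRead(f"{tx.transcript_id}_{tissue}_{i}", tx.chrom, ref_start, 60, _merge_cigar(cigar), "+", seq)
        )


def _merge_cigar(cigar: list[tuple[str, int]]) -> list[tuple[str, int]]:
    merged: list[tuple[str, int]] = []
    for op, ln in cigar:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return merged


def _emit_chimeric_reads(sink, rec, species, n_reads, read_length, rng) -> None:
    """Junction reads joining the host exon upstream of the insertion to the
    retrocopy start (the reference carries GT..AG between them)."""
    host = species.genes.genes.get(rec.host_gene)
    if host is None:
        return
    tx = next(iter(host.transcripts.values()))
    upstream = [e for e in tx.exons if e.end <= rec.start]
    if not upstream:
        return
    donor_exon = max(upstream, key=lambda e: e.end)
    half = read_length // 2
    if donor_exon.end - donor_exon.start < half or rec.end - rec.start < half:
        return
    gap = rec.start - donor_exon.end
    if gap < 4:
        return
    genome = species.genome
    left = genome[rec.chrom][donor_exon.end - half : donor_exon.end]
    right = genome[rec.chrom][rec.start : rec.start + half]
    seq = _seq.decode(np.concatenate([left, right]))
    for i in range(n_reads):
        sink.append(
            SamRead(
                f"{rec.retro_id}_chim_{i}",
                rec.chrom,
                donor_exon.end - half,
                60,
                [("M", half), ("N", gap), ("M", half)],
                "+",
                seq,
            )
        )


def write_reads(
    reads_by_tissue: dict[str, list[SamRead]],
    species: SpeciesGenome,
    outdir: str | os.PathLike,
    prefix: str = "",
) -> dict[str, str]:
    """Write one SAM per tissue; returns tissue -> path."""
    os.makedirs(str(outdir), exist_ok=True)
    refs = {c: arr.size for c, arr in species.genome.items()}
    paths = {}
    for tissue, reads in reads_by_tissue.items():
        path = os.path.join(str(outdir), f"{prefix}{tissue}.sam")
        write_sam(path, reads, refs)
        paths[tissue] = path
    return paths
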