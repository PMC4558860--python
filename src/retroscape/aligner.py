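"""Seed-and-extend nucleotide aligner producing chained local alignments.

Exact k-mer seeds (default k=12) against a sorted-array index over all
reference sequences at once, hits grouped by diagonal, ungapped
maximal-scoring extension per diagonal, and a small colinear-chaining DP
that joins exon-sized segments across intron-sized target gaps. Output is
the same shape a PSL parser yields, so detection can consume either.
Substitution-only divergence is handled well; indels break a diagonal and
are outside this aligner's remit (externally produced PSL covers that case).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _seq
from .io_formats import ChainedAlignment

__all__ = ["GenomeIndex", "align_query", "align_transcripts", "best_local_segment"]

MATCH_SCORE = 1
MISMATCH_SCORE = -3


@dataclass
class _Segment:
    qstart: int
    tstart: int  # local coordinate within its sequence
    length: int
    matches: int
    mismatches: int


class GenomeIndex:
    """Sorted k-mer index over a set of named sequences.

    All sequences share one sorted code array; k-mer positions are stored in
    a global coordinate space (per-sequence offset + local position), so one
    binary search serves every reference at once.
    """

    def __init__(self, genome: dict[str, np.ndarray], k: int = 12):
        self.k = k
        self.names = sorted(genome)
        self.seqs = {n: np.ascontiguousarray(genome[n], dtype=np.uint8) for n in self.names}
        offsets = []
        pos_parts, code_parts = [], []
        offset = 0
        for name in self.names:
            arr = self.seqs[name]
            offsets.append(offset)
            codes = _seq.kmer_codes(arr, k)
            if codes.size:
                code_parts.append(codes)
                pos_parts.append(np.arange(codes.size, dtype=np.int64) + offset)
            offset += arr.size
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.total = offset
        if code_parts:
            codes = np.concatenate(code_parts)
            positions = np.concatenate(pos_parts)
            order = np.argsort(codes, kind="stable")
            self._codes = codes[order]
            self._positions = positions[order]
        else:
            self._codes = np.empty(0, dtype=np.int64)
            self._positions = np.empty(0, dtype=np.int64)

    def seed_hits(self, query_codes: np.ndarray, max_hits_per_kmer: int = 50):
        """(query_pos, global_target_pos) arrays of exact k-mer matches."""
        lo = np.searchsorted(self._codes, query_codes, side="left")
        hi = np.searchsorted(self._codes, query_codes, side="right")
        counts = hi - lo
        counts[counts > max_hits_per_kmer] = 0  # skip repetitive seeds
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qpos = np.repeat(np.arange(query_codes.size), counts)
        starts = np.repeat(lo, counts)
        within = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        tpos = self._positions[starts + within]
        return qpos, tpos

    def locate(self, global_pos: int) -> int:
        """Index (into ``names``) of the sequence containing a global position."""
        return int(np.searchsorted(self.offsets, global_pos, side="right")) - 1


def best_local_segment(query: np.ndarray, target: np.ndarray) -> _Segment | None:
    """Maximal-scoring ungapped local alignment of two equal-offset arrays.

    Compares ``query[i]`` to ``target[i]`` (caller aligns the diagonal) and
    returns the best-scoring run under +1/-3 match/mismatch scoring.
    """
    n = min(query.size, target.size)
    if n == 0:
        return None
    eq = query[:n] == target[:n]
    scores = np.where(eq, MATCH_SCORE, MISMATCH_SCORE).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(scores)])
    running_min = np.minimum.accumulate(cum[:-1])
    gains = cum[1:] - running_min
    end = int(np.argmax(gains))
    if gains[end] <= 0:
        return None
    start = int(np.argmin(cum[: end + 1]))
    m = int(eq[start : end + 1].sum())
    length = end + 1 - start
    return _Segment(start, start, length, m, length - m)


def _chain_segments(
    segments: list[_Segment], max_chain_gap: int, min_chain_matches: int
) -> list[list[_Segment]]:
    """Cluster by target proximity, then extract colinear chains (DP).

    Chains are extracted iteratively so that two loci falling into one
    cluster (e.g. a retrocopy inserted near its parental gene) both survive;
    later chains whose target span overlaps an earlier one are alternative
    explanations of the same locus and are dropped.
    """
    chains: list[list[_Segment]] = []
    segments = sorted(segments, key=lambda s: s.tstart)
    cluster: list[_Segment] = []

    def flush(cluster: list[_Segment]) -> None:
        taken: list[tuple[int, int]] = []
        remaining = list(cluster)
        while remaining:
            chain = _best_chain(remaining)
            matches = sum(s.matches for s in chain)
            if matches < min_chain_matches:
                break
            span = (chain[0].tstart, max(s.tstart + s.length for s in chain))
            ids = {id(s) for s in chain}
            remaining = [s for s in remaining if id(s) not in ids]
            if any(span[0] < e and s < span[1] for s, e in taken):
                continue
            taken.append(span)
            chains.append(chain)

    for seg in segments:
        if cluster and seg.tstart - (cluster[-1].tstart + cluster[-1].length) > max_chain_gap:
            flush(cluster)
            cluster = []
        cluster.append(seg)
    if cluster:
        flush(cluster)
    return chains


def _best_chain(cluster: list[_Segment]) -> list[_Segment]:
    cluster = sorted(cluster, key=lambda s: (s.qstart, s.tstart))
    n = len(cluster)
    best = [s.matches for s in cluster]
    prev = [-1] * n
    for j in range(n):
        for i in range(j):
            a, b = cluster[i], cluster[j]
            if a.qstart + a.length <= b.qstart and a.tstart + a.length <= b.tstart:
                cand = best[i] + b.matches
                if cand > best[j]:
                    best[j], prev[j] = cand, i
    j = int(np.argmax(best))
    chain = []
    while j >= 0:
        chain.append(cluster[j])
        j = prev[j]
    return list(reversed(chain))


def _strand_segments(
    index: GenomeIndex, qarr: np.ndarray, min_seeds: int, min_segment: int
) -> dict[str, list[_Segment]]:
    """Diagonal segments per reference sequence for one query orientation."""
    qcodes = _seq.kmer_codes(qarr, index.k)
    if qcodes.size == 0:
        return {}
    qpos, tpos = index.seed_hits(qcodes)
    if qpos.size == 0:
        return {}
    diags = tpos - qpos
    seq_idx = np.searchsorted(index.offsets, tpos, side="right") - 1
    # diagonals are keyed per sequence so equal global diagonals in
    # different references never merge
    nseq = len(index.names)
    keys = (diags + qarr.size) * nseq + seq_idx
    uniq, first, counts = np.unique(keys, return_index=True, return_counts=True)
    by_seq: dict[str, list[_Segment]] = {}
    for key, fi, c in zip(uniq.tolist(), first.tolist(), counts.tolist()):
        if c < min_seeds:
            continue
        d = key // nseq - qarr.size
        si = key % nseq
        name = index.names[si]
        off = int(index.offsets[si])
        target = index.seqs[name]
        # query range that projects onto this sequence along diagonal d
        q0 = max(0, off - d)
        q1 = min(qarr.size, off + target.size - d)
        if q1 - q0 < min_segment:
            continue
        seg = best_local_segment(qarr[q0:q1], target[q0 + d - off : q1 + d - off])
        if seg is None or seg.length < min_segment:
            continue
        by_seq.setdefault(name, []).append(
            _Segment(q0 + seg.qstart, q0 + seg.tstart + d - off, seg.length, seg.matches, seg.mismatches)
        )
    return by_seq


def align_query(
    index: GenomeIndex,
    name: str,
    query: np.ndarray,
    min_seeds: int = 2,
    max_chain_gap: int = 15_000,
    min_segment: int = 20,
    min_chain_matches: int = 40,
) -> list[ChainedAlignment]:
    """Align one query (both strands) against every indexed sequence."""
    out: list[ChainedAlignment] = []
    qlen = query.size
    for strand, qarr in (("+", query), ("-", _seq.revcomp(query))):
        by_seq = _strand_segments(index, qarr, min_seeds, min_segment)
        for chrom in sorted(by_seq):
            target = index.seqs[chrom]
            for chain in _chain_segments(by_seq[chrom], max_chain_gap, min_chain_matches):
                matches = sum(s.matches for s in chain)
                blocks = []
                for s in chain:
                    if strand == "+":
                        blocks.append((s.qstart, s.tstart, s.length))
                    else:
                        blocks.append((qlen - s.qstart - s.length, s.tstart, s.length))
                blocks.sort()
                aln = ChainedAlignment(
                    query_name=name,
                    query_length=qlen,
                    target_name=chrom,
                    target_length=target.size,
                    strand=strand,
                    blocks=blocks,
                    matches=matches,
                    mismatches=sum(s.mismatches for s in chain),
                )
                aln.validate()
                out.append(aln)
    return out


def align_transcripts(
    transcripts: dict[str, np.ndarray],
    genome: dict[str, np.ndarray],
    k: int = 12,
    min_seeds: int = 2,
    max_chain_gap: int = 15_000,
) -> list[ChainedAlignment]:
    """Align every transcript to the genome; empty list when nothing hits."""
    if not transcripts or not genome:
        raise ValueError("transcripts and genome must be non-empty")
    index = GenomeIndex(genome, k=k)
    out: list[ChainedAlignment] = []
    for name in sorted(transcripts):
        out.extend(align_query(index, name, np.asarray(transcripts[name], dtype=np.uint8),
                               min_seeds=min_seeds, max_chain_gap=max_chain_gap))
    return out
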