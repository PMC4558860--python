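"""Ka/Ks for retrocopy-parent pairs: Nei-Gojobori (1986) site counting with
the Jukes-Cantor multiple-hit correction.

Synonymous site fractions are computed per codon position as the share of
the three possible substitutions that preserve the amino acid (standard
genetic code; substitutions creating a stop count as nonsynonymous sites),
averaged between the two sequences. Codons differing at several positions
average synonymous/nonsynonymous difference counts over all shortest
substitution pathways, excluding pathways that pass through a stop codon.
Jukes-Cantor: d = -(3/4) ln(1 - (4/3) p), undefined (saturated) at p >= 3/4.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

from . import _seq, aligner
from .io_formats import GeneSet
from .retrofind import RetrocopyCall

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "extract_cds_pair",
    "nei_gojobori",
    "jukes_cantor",
    "compare_to_random",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
_AA = dict(_TABLE.forward_table)
_BASES = "ACGT"


def _translate(codon: str) -> str | None:
    """Amino acid, or None for a stop codon."""
    return _AA.get(codon)


@dataclass
class CodonAlignment:
    """Gap-free codon-wise pairing of a retrocopy CDS region and parent CDS."""

    codons_parent: list[str]
    codons_retro: list[str]
    n_dropped_gap_codons: int = 0
    n_dropped_stop_codons: int = 0

    def __post_init__(self) -> None:
        if len(self.codons_parent) != len(self.codons_retro):
            raise ValueError("codon lists differ in length")
        for c in itertools.chain(self.codons_parent, self.codons_retro):
            if len(c) != 3 or any(b not in _BASES for b in c):
                raise ValueError(f"invalid codon {c!r}")

    def __len__(self) -> int:
        return len(self.codons_parent)


@dataclass
class KaKsResult:
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ks: float | None
    ka: float | None
    ratio: float | None
    saturated: bool
    n_codons: int = 0
    n_dropped_stop_codons: int = 0


def jukes_cantor(p: float) -> float | None:
    """JC69 distance; None when the observed proportion is saturated."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


# ---------------------------------------------------------------------------
# site and difference counting
# ---------------------------------------------------------------------------


def _syn_sites(codon: str) -> float:
    """Synonymous-site count of one codon (sum over 3 positions of the
    fraction of substitutions preserving the amino acid)."""
    aa = _translate(codon)
    total = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if _translate(alt) is not None and _translate(alt) == aa:
                syn += 1
        total += syn / 3.0
    return total


def _pathway_counts(a: str, b: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) step counts over all shortest
    substitution pathways between two codons, skipping pathways through
    stops. Falls back to splitting the raw difference count by the codon's
    site proportions when every pathway is blocked."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    syn_tot = non_tot = 0.0
    n_valid = 0
    for order in itertools.permutations(diff):
        cur = a
        syn = non = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if _translate(nxt) is None:  # intermediate stop codon
                blocked = True
                break
            syn += _translate(cur) == _translate(nxt)
            non += _translate(cur) != _translate(nxt)
            cur = nxt
        if not blocked:
            syn_tot += syn
            non_tot += non
            n_valid += 1
    if n_valid:
        return syn_tot / n_valid, non_tot / n_valid
    s_frac = (_syn_sites(a) + _syn_sites(b)) / 6.0  # per-position syn fraction
    return len(diff) * s_frac, len(diff) * (1.0 - s_frac)


def nei_gojobori(aln: CodonAlignment) -> KaKsResult:
    """NG86 Ka/Ks with Jukes-Cantor correction for one codon alignment."""
    if len(aln) == 0:
        raise ValueError("empty codon alignment")
    s_a = sum(_syn_sites(c) for c in aln.codons_parent)
    s_b = sum(_syn_sites(c) for c in aln.codons_retro)
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * len(aln) - s_sites
    sd = nd = 0.0
    for ca, cb in zip(aln.codons_parent, aln.codons_retro):
        syn, non = _pathway_counts(ca, cb)
        sd += syn
        nd += non
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    saturated = ks is None or ka is None
    if saturated or ks == 0:
        ratio = None
    else:
        ratio = ka / ks
    return KaKsResult(
        s_sites=s_sites,
        n_sites=n_sites,
        sd=sd,
        nd=nd,
        ps=ps,
        pn=pn,
        ks=ks,
        ka=ka,
        ratio=ratio,
        saturated=saturated,
        n_codons=len(aln),
        n_dropped_stop_codons=aln.n_dropped_stop_codons,
    )


# ---------------------------------------------------------------------------
# CDS projection
# ---------------------------------------------------------------------------


def extract_cds_pair(
    call: RetrocopyCall,
    genes: GeneSet,
    genome: dict[str, np.ndarray],
    window: int = 200,
) -> CodonAlignment | None:
    """Pair the retrocopy's bases with the parent CDS, codon-wise.

    The parent CDS is projected onto the retrocopy through a fresh local
    alignment of the parent transcript against the called locus. Codons not
    fully covered by the alignment are dropped (the gap-removal rule), as
    are codon columns containing a stop in either sequence; a trailing
    partial codon never arises because pairing is per whole codon. Returns
    None when the retrocopy covers no complete parent codon.
    """
    tx = genes.transcript(call.parental_transcript)
    if not tx.cds:
        return None
    txseq = tx.sequence(genome)
    # CDS interval in transcript coordinates
    offsets = tx.exon_offsets()
    exons = tx.exons
    cds_tx_positions: list[int] = []
    for cds_iv in tx.cds:
        for (estart, eend), exon in zip(offsets, exons):
            if exon.overlaps(cds_iv):
                lo = max(exon.start, cds_iv.start)
                hi = min(exon.end, cds_iv.end)
                if tx.strand == "+":
                    for g in range(lo, hi):
                        cds_tx_positions.append(estart + (g - exon.start))
                else:
                    for g in range(hi - 1, lo - 1, -1):
                        cds_tx_positions.append(estart + (exon.end - 1 - g))
    cds_tx_positions.sort()
    if not cds_tx_positions:
        return None
    cds_start, cds_len = cds_tx_positions[0], len(cds_tx_positions)
    cds_len -= cds_len % 3
    if cds_len < 3:
        return None

    lo = max(0, call.locus.start - window)
    hi = min(genome[call.locus.chrom].size, call.locus.end + window)
    target = genome[call.locus.chrom][lo:hi]
    index = aligner.GenomeIndex({"w": target}, k=12)
    alns = aligner.align_query(index, call.parental_transcript, txseq, min_seeds=1)
    if not alns:
        return None
    best = max(alns, key=lambda a: a.matches)

    # retro base (or -1) for every transcript position of the CDS
    paired = np.full(cds_len, -1, dtype=np.int16)
    for q, t, ln in best.blocks:
        for i in range(ln):
            qpos = q + i
            j = qpos - cds_start
            if 0 <= j < cds_len:
                if best.strand == "+":
                    paired[j] = target[t + i]
                else:
                    paired[j] = _seq._COMP[target[t + ln - 1 - i]]
    codons_parent, codons_retro = [], []
    dropped_gap = dropped_stop = 0
    for c in range(cds_len // 3):
        j = cds_start + 3 * c
        retro = paired[3 * c : 3 * c + 3]
        if (retro < 0).any():
            dropped_gap += 1
            continue
        par_codon = _seq.decode(txseq[j : j + 3])
        ret_codon = _seq.decode(retro.astype(np.uint8))
        if par_codon in _STOPS or ret_codon in _STOPS:
            dropped_stop += 1
            continue
        codons_parent.append(par_codon)
        codons_retro.append(ret_codon)
    if not codons_parent:
        return None
    return CodonAlignment(codons_parent, codons_retro, dropped_gap, dropped_stop)


# ---------------------------------------------------------------------------
# random-set comparison
# ---------------------------------------------------------------------------


def compare_to_random(
    target_ratios: list[float],
    all_ratios: list[float],
    set_size: int,
    n_sets: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Compare a target Ka/Ks set against random same-size draws.

    Draws ``n_sets`` subsets of ``all_ratios`` without replacement, reports
    the target median, the median of the per-set medians, and a two-sample
    Mann-Whitney U p-value (normal approximation, tie-corrected) between the
    target ratios and the first random draw.
    """
    pop = np.asarray(all_ratios, dtype=float)
    target = np.asarray(target_ratios, dtype=float)
    if set_size > pop.size:
        raise ValueError("set_size exceeds the population size")
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    medians = np.empty(n_sets)
    first_draw = None
    for i in range(n_sets):
        draw = rng.choice(pop, size=set_size, replace=False)
        if first_draw is None:
            first_draw = draw
        medians[i] = np.median(draw)
    p = stats.mannwhitneyu(target, first_draw, alternative="two-sided", method="asymptotic").pvalue
    return {
        "median_target": float(np.median(target)),
        "median_random": float(np.median(medians)),
        "p_value": float(p),
    }
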