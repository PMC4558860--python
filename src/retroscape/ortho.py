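"""Cross-species retrocopy orthology from flanking-sequence synteny.

Two retrocopies in different species descend from one ancestral insertion
exactly when they carry the same parental gene at the same genomic
neighbourhood. Because independent insertions essentially never hit the same
point of a multi-gigabase genome, shared non-repetitive flanking sequence is
a fingerprint of shared origin. Calls are paired across species by aligning
their flank blocks, grouped into connected components, dated by placing each
group on the edge above the most recent common ancestor of the species that
carry it (gains only; losses are not modelled), and converted to per-branch
origination/fixation rates.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import _seq, aligner
from .io_formats import GenomicInterval, RepeatAnnotation, SpeciesTree
from .retrofind import RetrocopyCall

__all__ = [
    "FlankSignature",
    "OrthologyGroup",
    "extract_flanks",
    "match_orthologs",
    "build_groups",
    "branch_rate",
    "x_flux_test",
]


@dataclass
class FlankSignature:
    """Non-repetitive sequence blocks flanking one retrocopy locus.

    Sides are in genome orientation: ``upstream`` means lower coordinates.
    Each block is at least ``min_block`` nt of repeat-free sequence; per side
    at most ``flank_total`` nt are collected, nearest blocks first.
    """

    retro_id: str
    upstream_blocks: list[tuple[GenomicInterval, np.ndarray]]
    downstream_blocks: list[tuple[GenomicInterval, np.ndarray]]
    search_offset: int = 0
    upstream_empty: bool = False
    downstream_empty: bool = False

    def side_nt(self, side: str) -> int:
        blocks = self.upstream_blocks if side == "up" else self.downstream_blocks
        return sum(len(iv) for iv, _ in blocks)

    def side_seq(self, side: str) -> np.ndarray:
        blocks = self.upstream_blocks if side == "up" else self.downstream_blocks
        if not blocks:
            return np.empty(0, dtype=np.uint8)
        return np.concatenate([seq for _, seq in blocks])


def _merged_repeat_arrays(repeats: list[RepeatAnnotation], chrom: str) -> tuple[np.ndarray, np.ndarray]:
    ivs = sorted((r.interval.start, r.interval.end) for r in repeats if r.interval.chrom == chrom)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    if not merged:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    arr = np.asarray(merged, dtype=np.int64)
    return arr[:, 0], arr[:, 1]


def extract_flanks(
    call: RetrocopyCall,
    genome: dict[str, np.ndarray],
    repeats: list[RepeatAnnotation],
    flank_total: int = 3000,
    min_block: int = 150,
    search_offset: int = 0,
    retro_id: str | None = None,
    _repeat_cache: dict | None = None,
) -> FlankSignature:
    """Collect repeat-free flank blocks on both sides of a call.

    The scan starts ``search_offset`` nt beyond each locus edge, plus a guard
    band equal to the call's unaligned query remainder, so possibly
    under-annotated retrocopy sequence (an unaligned 5' stub, the polyA tail)
    is never swept into the fingerprint.
    """
    chrom = call.locus.chrom
    seq = genome[chrom]
    if _repeat_cache is not None:
        key = chrom
        if key not in _repeat_cache:
            _repeat_cache[key] = _merged_repeat_arrays(repeats, chrom)
        rep_s, rep_e = _repeat_cache[key]
    else:
        rep_s, rep_e = _merged_repeat_arrays(repeats, chrom)

    if call.query_coverage > 0:
        query_len = int(round(call.aligned_nt / call.query_coverage))
    else:
        query_len = call.aligned_nt
    guard = max(0, query_len - call.aligned_nt)
    offset = search_offset + guard

    # repeat-free runs over the whole chromosome (complement of merged repeats)
    n = seq.size
    bounds = [0]
    for s, e in zip(rep_s.tolist(), rep_e.tolist()):
        bounds.extend([s, e])
    bounds.append(n)
    runs = [(bounds[i], bounds[i + 1]) for i in range(0, len(bounds), 2) if bounds[i] < bounds[i + 1]]

    def collect(edge: int, direction: int) -> list[tuple[GenomicInterval, np.ndarray]]:
        """Walk outward from ``edge`` (exclusive) in ``direction`` (+-1)."""
        blocks: list[tuple[GenomicInterval, np.ndarray]] = []
        remaining = flank_total
        if direction < 0:
            limit = edge - offset
            for rs, re_ in reversed(runs):
                if remaining <= 0 or re_ <= 0:
                    break
                rs, re_ = rs, min(re_, limit)
                if re_ - rs < min_block:
                    continue
                take = min(re_ - rs, remaining)
                s, e = re_ - take, re_
                blocks.append((GenomicInterval(chrom, s, e), seq[s:e].copy()))
                remaining -= take
        else:
            limit = edge + offset
            for rs, re_ in runs:
                if remaining <= 0:
                    break
                rs = max(rs, limit)
                if re_ - rs < min_block:
                    continue
                take = min(re_ - rs, remaining)
                s, e = rs, rs + take
                blocks.append((GenomicInterval(chrom, s, e), seq[s:e].copy()))
                remaining -= take
        return blocks

    up = collect(call.locus.start, -1)
    down = collect(call.locus.end, +1)
    return FlankSignature(
        retro_id=retro_id or call.call_id,
        upstream_blocks=up,
        downstream_blocks=down,
        search_offset=search_offset,
        upstream_empty=not up,
        downstream_empty=not down,
    )


def _side_match(a: FlankSignature, b: FlankSignature, side: str, min_identity: float, k: int = 12):
    """Fraction of a's flank nt on one side that aligns to b's same side."""
    a_total = a.side_nt(side)
    bseq = b.side_seq(side)
    if a_total == 0 or bseq.size < k:
        return 0.0, 0.0
    index = aligner.GenomeIndex({"f": bseq}, k=k)
    covered = matched = mism = 0
    blocks = a.upstream_blocks if side == "up" else a.downstream_blocks
    for _, qseq in blocks:
        for aln in aligner.align_query(index, "q", qseq, min_seeds=1, min_chain_matches=20):
            if aln.identity >= min_identity:
                covered += aln.aligned_nt
                matched += aln.matches
                mism += aln.mismatches
    cov = min(1.0, covered / a_total)
    ident = matched / (matched + mism) if matched + mism else 0.0
    return cov, ident


@dataclass
class OrthologPair:
    species_a: str
    species_b: str
    call_a: RetrocopyCall
    call_b: RetrocopyCall
    flank_coverage: float
    flank_identity: float


def match_orthologs(
    calls_a: list[RetrocopyCall],
    calls_b: list[RetrocopyCall],
    flanks_a: dict[str, FlankSignature],
    flanks_b: dict[str, FlankSignature],
    species_a: str = "A",
    species_b: str = "B",
    min_flank_fraction: float = 0.5,
    min_flank_identity: float = 0.7,
) -> list[OrthologPair]:
    """Pair calls across two species by shared parental gene + shared flanks.

    Flank support is evaluated in both directions and the better one kept,
    so the pairing is symmetric in its two species. Pairing is 1-to-1:
    best flank coverage wins, ties broken by identity.
    """
    by_gene: dict[str, list[RetrocopyCall]] = {}
    for c in calls_b:
        by_gene.setdefault(c.parental_gene, []).append(c)
    candidates: list[OrthologPair] = []
    for ca in calls_a:
        fa = flanks_a[ca.call_id]
        for cb in by_gene.get(ca.parental_gene, []):
            fb = flanks_b[cb.call_id]
            best_cov = best_id = 0.0
            for side in ("up", "down"):
                for x, y in ((fa, fb), (fb, fa)):
                    cov, ident = _side_match(x, y, side, min_flank_identity)
                    if cov > best_cov or (cov == best_cov and ident > best_id):
                        best_cov, best_id = cov, ident
            if best_cov >= min_flank_fraction:
                candidates.append(
                    OrthologPair(species_a, species_b, ca, cb, best_cov, best_id)
                )
    candidates.sort(key=lambda p: (-p.flank_coverage, -p.flank_identity,
                                   p.call_a.call_id, p.call_b.call_id))
    used_a: set[str] = set()
    used_b: set[str] = set()
    out = []
    for pair in candidates:
        if pair.call_a.call_id in used_a or pair.call_b.call_id in used_b:
            continue
        used_a.add(pair.call_a.call_id)
        used_b.add(pair.call_b.call_id)
        out.append(pair)
    return out


@dataclass
class OrthologyGroup:
    """Calls across species attributed to one ancestral insertion."""

    group_id: str
    members: dict[str, RetrocopyCall]
    parental_gene: str
    origin_branch: str
    presence_pattern: frozenset[str]
    discordant: bool = False


def build_groups(
    pairs: list[OrthologPair],
    tree: SpeciesTree,
    calls_by_species: dict[str, list[RetrocopyCall]],
) -> tuple[list[OrthologyGroup], dict[str, list[RetrocopyCall]]]:
    """Connected components of the match graph -> dated orthology groups.

    A call matched to no other species is species-specific. The origin
    branch of a group is the edge above the MRCA of its presence pattern;
    patterns smaller than that MRCA's full leaf set (an implied loss) are
    kept but flagged discordant. Components mixing parental genes are split
    per gene.
    """
    parent_of: dict[tuple[str, str], tuple[str, str]] = {}

    def find(x):
        while parent_of.get(x, x) != x:
            parent_of[x] = parent_of.get(parent_of[x], parent_of[x])
            x = parent_of[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent_of[max(rx, ry)] = min(rx, ry)

    nodes: dict[tuple[str, str], RetrocopyCall] = {}
    for sp, calls in calls_by_species.items():
        for c in calls:
            nodes[(sp, c.call_id)] = c
    for p in pairs:
        union((p.species_a, p.call_a.call_id), (p.species_b, p.call_b.call_id))

    components: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for key in nodes:
        components.setdefault(find(key), []).append(key)

    groups: list[OrthologyGroup] = []
    specific: dict[str, list[RetrocopyCall]] = {sp: [] for sp in calls_by_species}
    gidx = 0
    for root_key in sorted(components):
        comp = components[root_key]
        by_gene: dict[str, list[tuple[str, str]]] = {}
        for key in comp:
            by_gene.setdefault(nodes[key].parental_gene, []).append(key)
        for gene in sorted(by_gene):
            keys = by_gene[gene]
            species = {sp for sp, _ in keys}
            if len(species) == 1 and len(keys) == 1:
                sp, _ = keys[0]
                specific[sp].append(nodes[keys[0]])
                continue
            mrca = tree.mrca(species)
            gidx += 1
            members = {}
            for key in sorted(keys):
                sp, _ = key
                if sp not in members:  # keep the first (deterministic) per species
                    members[sp] = nodes[key]
            groups.append(
                OrthologyGroup(
                    group_id=f"og{gidx:05d}",
                    members=members,
                    parental_gene=gene,
                    origin_branch=mrca,
                    presence_pattern=frozenset(species),
                    discordant=frozenset(species) != tree.leafset(mrca),
                )
            )
    return groups, specific


def branch_rate(n_retrocopies: int, duration_myr: float) -> float:
    """Retrocopies fixed per million years on one branch."""
    if duration_myr <= 0:
        raise ValueError("duration_myr must be positive")
    return n_retrocopies / duration_myr


def x_flux_test(
    subset: list[RetrocopyCall], background: list[RetrocopyCall]
) -> dict[str, float]:
    """Out-of-X / into-X migration excess in a designated call subset.

    Expected counts come from the background proportion of X-origin
    (parent on X, copy autosomal) and X-bound (parent autosomal, copy on X)
    calls among calls outside the subset; significance is a one-sided
    binomial test of the observed subset counts against those proportions.
    """
    if not subset:
        raise ValueError("subset must be non-empty")
    subset_ids = {c.call_id for c in subset}
    rest = [c for c in background if c.call_id not in subset_ids]
    if not rest:
        raise ValueError("background (outside the subset) must be non-empty")

    def frac_out(calls):
        return sum(1 for c in calls if c.parent_on_x and not c.on_x) / len(calls)

    def frac_into(calls):
        return sum(1 for c in calls if c.on_x and not c.parent_on_x) / len(calls)

    n = len(subset)
    obs_out = sum(1 for c in subset if c.parent_on_x and not c.on_x)
    obs_into = sum(1 for c in subset if c.on_x and not c.parent_on_x)
    p_bg_out = frac_out(rest)
    p_bg_into = frac_into(rest)
    p_out = stats.binomtest(obs_out, n, p_bg_out, alternative="greater").pvalue if p_bg_out > 0 else (
        1.0 if obs_out == 0 else 0.0
    )
    p_into = stats.binomtest(obs_into, n, p_bg_into, alternative="greater").pvalue if p_bg_into > 0 else (
        1.0 if obs_into == 0 else 0.0
    )
    return {
        "n_out_of_x": obs_out,
        "n_into_x": obs_into,
        "expected_out": p_bg_out * n,
        "expected_into": p_bg_into * n,
        "p_out": float(p_out),
        "p_into": float(p_into),
    }


def extract_all_flanks(
    calls: list[RetrocopyCall],
    genome: dict[str, np.ndarray],
    repeats: list[RepeatAnnotation],
    **kwargs,
) -> dict[str, FlankSignature]:
    """Flank signatures for a whole call set, keyed by call id."""
    cache: dict = {}
    return {
        c.call_id: extract_flanks(c, genome, repeats, _repeat_cache=cache, **kwargs)
        for c in calls
    }
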