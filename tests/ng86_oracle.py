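"""Independent brute-force oracle for NG86 site/difference counting.

Kept deliberately separate from the package: amino acids come from
Biopython's translator and multi-hit codons are resolved by explicit
recursive enumeration of substitution orders, so agreement with the
package's implementation is a genuine two-route check.
"""
import itertools

import numpy as np
from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}
SENSE = [c for c in ("".join(p) for p in itertools.product("ACGT", repeat=3)) if c not in STOPS]


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_syn_sites(codon: str) -> float:
    total = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if _aa(alt) != "*" and _aa(alt) == _aa(codon):
                total += 1 / 3
    return total


def oracle_codon_diffs(a: str, b: str) -> tuple[float, float]:
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    results = []

    def walk(cur, remaining, syn, non):
        if not remaining:
            results.append((syn, non))
            return
        for pos in remaining:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if _aa(nxt) == "*":
                continue
            step_syn = _aa(cur) == _aa(nxt)
            walk(nxt, [p for p in remaining if p != pos], syn + step_syn, non + (not step_syn))

    walk(a, diff, 0, 0)
    if not results:
        frac = (oracle_syn_sites(a) + oracle_syn_sites(b)) / 6
        return len(diff) * frac, len(diff) * (1 - frac)
    s = sum(r[0] for r in results) / len(results)
    n = sum(r[1] for r in results) / len(results)
    return s, n


def oracle_ng86(codons_a, codons_b):
    s_sites = (sum(map(oracle_syn_sites, codons_a)) + sum(map(oracle_syn_sites, codons_b))) / 2
    n_sites = 3 * len(codons_a) - s_sites
    sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        s, n = oracle_codon_diffs(ca, cb)
        sd += s
        nd += n
    return s_sites, n_sites, sd, nd


def random_codon_pair(rng: np.random.Generator, n_codons=30, max_diffs=3):
    a, b = [], []
    for _ in range(n_codons):
        ca = SENSE[rng.integers(len(SENSE))]
        cb = ca
        for _try in range(20):
            cand = list(ca)
            for pos in rng.choice(3, size=rng.integers(0, max_diffs + 1), replace=False):
                cand[pos] = "ACGT"[rng.integers(4)]
            cand = "".join(cand)
            if cand not in STOPS:
                cb = cand
                break
        a.append(ca)
        b.append(cb)
    return a, b
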