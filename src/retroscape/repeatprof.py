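"""LINE-1 subfamily composition and cross-clade enrichment.

Counts L1 elements per subfamily from repeat annotations, drops rare
subfamilies below a membership floor, and compares one subfamily's share
between two compositions with a standard 2x2 Pearson chi-squared test and
odds ratio.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats

from .io_formats import RepeatAnnotation

__all__ = ["SubfamilyComposition", "composition", "enrichment_test"]


@dataclass
class SubfamilyComposition:
    species: str
    counts: dict[str, int] = field(default_factory=dict)
    fractions: dict[str, float] = field(default_factory=dict)
    min_members: int = 10_000

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def composition(
    repeats: list[RepeatAnnotation] | dict[str, list[RepeatAnnotation]],
    min_members: int = 10_000,
    species: str = "pooled",
) -> SubfamilyComposition:
    """L1 subfamily counts and fractions of the retained L1 total.

    When several species' annotations are given, the membership floor is
    applied to the pooled multi-species count.
    """
    if isinstance(repeats, dict):
        pooled = [r for recs in repeats.values() for r in recs]
    else:
        pooled = repeats
    counts: dict[str, int] = {}
    for rep in pooled:
        if rep.repeat_class.startswith("LINE/L1") or rep.repeat_class == "L1":
            counts[rep.subfamily] = counts.get(rep.subfamily, 0) + 1
    kept = {sub: n for sub, n in counts.items() if n > min_members}
    total = sum(kept.values())
    fractions = {sub: n / total for sub, n in kept.items()} if total else {}
    return SubfamilyComposition(species, kept, fractions, min_members)


def enrichment_test(
    comp_a: SubfamilyComposition, comp_b: SubfamilyComposition, subfamily: str
) -> dict[str, float]:
    """2x2 (subfamily vs rest, group A vs B) Pearson chi-squared + odds ratio."""
    a = comp_a.counts.get(subfamily, 0)
    b = comp_a.total - a
    c = comp_b.counts.get(subfamily, 0)
    d = comp_b.total - c
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("2x2 table has a zero marginal")
    chi2, p, _dof, _exp = stats.chi2_contingency([[a, b], [c, d]], correction=False)
    odds = (a * d) / (b * c) if b * c else float("inf")
    return {"odds_ratio": float(odds), "chi2": float(chi2), "p": float(p)}
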