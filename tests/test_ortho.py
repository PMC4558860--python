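import numpy as np
import pytest

from retroscape import _seq, ortho, retrofind
from retroscape.io_formats import GenomicInterval, RepeatAnnotation, SpeciesTree
from retroscape.ortho import branch_rate, build_groups, extract_flanks, match_orthologs, x_flux_test
from retroscape.retrofind import RetrocopyCall


def _call(chrom="chr1", start=50_000, end=51_000, gene="g1", tx="t1", **kw):
    defaults = dict(identity=0.95, query_coverage=1.0, aligned_nt=end - start, n_exons_bridged=3)
    defaults.update(kw)
    return RetrocopyCall(GenomicInterval(chrom, start, end), gene, tx, **defaults)


class TestExtractFlanks:
    def test_repeat_free_genome_gives_single_3000nt_block_per_side(self):
        rng = np.random.default_rng(0)
        genome = {"chr1": _seq.random_seq(rng, 120_000)}
        sig = extract_flanks(_call(), genome, [])
        assert len(sig.upstream_blocks) == 1 and len(sig.downstream_blocks) == 1
        assert sig.side_nt("up") == 3000 and sig.side_nt("down") == 3000
        up_iv = sig.upstream_blocks[0][0]
        # full-coverage call -> zero guard band: block abuts the locus edge
        assert (up_iv.start, up_iv.end) == (47_000, 50_000)
        assert not sig.upstream_empty

    def test_fully_masked_side_is_empty_and_flagged(self):
        rng = np.random.default_rng(1)
        genome = {"chr1": _seq.random_seq(rng, 120_000)}
        repeats = [RepeatAnnotation(GenomicInterval("chr1", 0, 50_000), "LINE/L1", "L1PA7")]
        sig = extract_flanks(_call(), genome, repeats)
        assert sig.upstream_empty
        assert not sig.downstream_empty

    def test_alternating_repeats_yield_15_blocks_of_200(self):
        rng = np.random.default_rng(2)
        genome = {"chr1": _seq.random_seq(rng, 200_000)}
        # downstream of 51_000: repeat 100 nt then clean 200 nt, repeated
        repeats = []
        pos = 51_000
        while pos < 150_000:
            repeats.append(
                RepeatAnnotation(GenomicInterval("chr1", pos, pos + 100), "SINE/Alu", "AluY")
            )
            pos += 300
        sig = extract_flanks(_call(), genome, repeats)
        assert len(sig.downstream_blocks) == 15
        assert all(len(iv) == 200 for iv, _ in sig.downstream_blocks)
        assert sig.side_nt("down") == 3000

    def test_chromosome_edge_gives_empty_flagged_side(self):
        rng = np.random.default_rng(3)
        genome = {"chr1": _seq.random_seq(rng, 10_000)}
        sig = extract_flanks(_call(start=0, end=1000), genome, [])
        assert sig.upstream_empty

    def test_search_offset_shifts_window(self):
        rng = np.random.default_rng(4)
        genome = {"chr1": _seq.random_seq(rng, 120_000)}
        sig = extract_flanks(_call(), genome, [], search_offset=5000)
        assert sig.upstream_blocks[0][0].end == 45_000
        assert sig.downstream_blocks[0][0].start == 56_000


def _two_species_with_shared_copy(seed=5, shared=True, same_gene=True):
    """Two genomes sharing backbone; a copy planted at syntenic or disjoint loci."""
    rng = np.random.default_rng(seed)
    backbone = _seq.random_seq(rng, 200_000)
    ga = {"chr1": backbone.copy()}
    pos_a = 80_000
    pos_b = 80_000 if shared else 140_000
    gb = {"chr1": _seq.mutate(backbone, 0.01, rng)[0]}
    call_a = _call(start=pos_a, end=pos_a + 1000, gene="g1", tx="t1")
    call_b = _call(start=pos_b, end=pos_b + 1000, gene="g1" if same_gene else "g2", tx="t9")
    fa = {call_a.call_id: extract_flanks(call_a, ga, [])}
    fb = {call_b.call_id: extract_flanks(call_b, gb, [])}
    return call_a, call_b, fa, fb


class TestMatchOrthologs:
    def test_shared_insertion_is_paired(self):
        ca, cb, fa, fb = _two_species_with_shared_copy(shared=True)
        pairs = match_orthologs([ca], [cb], fa, fb, "A", "B")
        assert len(pairs) == 1
        assert pairs[0].flank_coverage >= 0.5

    def test_independent_insertions_of_same_gene_not_paired(self):
        ca, cb, fa, fb = _two_species_with_shared_copy(shared=False)
        assert match_orthologs([ca], [cb], fa, fb, "A", "B") == []

    def test_same_locus_different_parental_genes_not_paired(self):
        ca, cb, fa, fb = _two_species_with_shared_copy(shared=True, same_gene=False)
        assert match_orthologs([ca], [cb], fa, fb, "A", "B") == []

    def test_pairing_symmetric_in_species_order(self):
        ca, cb, fa, fb = _two_species_with_shared_copy()
        ab = match_orthologs([ca], [cb], fa, fb, "A", "B")
        ba = match_orthologs([cb], [ca], fb, fa, "B", "A")
        assert len(ab) == len(ba) == 1
        assert ab[0].call_a.call_id == ba[0].call_b.call_id


class TestBuildGroups:
    TREE = "((human:6,chimpanzee:6)HC:2,gorilla:8)root:10;"

    def _groups(self, presence):
        tree = SpeciesTree.from_newick(self.TREE)
        calls = {sp: [] for sp in tree.leaves}
        pairs = []
        members = {}
        for sp in presence:
            c = _call(gene="g1", tx="t1")
            calls[sp].append(c)
            members[sp] = c
        sps = sorted(presence)
        for i in range(len(sps) - 1):
            a, b = sps[i], sps[i + 1]
            pairs.append(ortho.OrthologPair(a, b, members[a], members[b], 1.0, 1.0))
        return build_groups(pairs, tree, calls)

    def test_human_chimp_pair_dates_to_their_ancestor_edge(self):
        groups, specific = self._groups({"human", "chimpanzee"})
        assert len(groups) == 1
        assert groups[0].origin_branch == "HC"
        assert not groups[0].discordant
        assert all(not v for v in specific.values())

    def test_full_presence_dates_to_root(self):
        groups, _ = self._groups({"human", "chimpanzee", "gorilla"})
        assert groups[0].origin_branch == "root"

    def test_discordant_pattern_flagged_not_dropped(self):
        groups, _ = self._groups({"human", "gorilla"})
        assert groups[0].origin_branch == "root"
        assert groups[0].discordant

    def test_unmatched_call_is_species_specific(self):
        tree = SpeciesTree.from_newick(self.TREE)
        lone = _call()
        groups, specific = build_groups([], tree, {"human": [lone], "chimpanzee": [], "gorilla": []})
        assert groups == []
        assert specific["human"] == [lone]

    def test_every_call_partitioned_exactly_once(self, small_sim):
        calls = {
            sp: retrofind.detect(small_sim.species[sp].genes, small_sim.species[sp].genome)
            for sp in small_sim.species
        }
        flanks = {
            sp: ortho.extract_all_flanks(
                calls[sp], small_sim.species[sp].genome, small_sim.species[sp].repeats
            )
            for sp in calls
        }
        pairs = ortho.match_orthologs(calls["A"], calls["B"], flanks["A"], flanks["B"], "A", "B")
        groups, specific = build_groups(pairs, small_sim.tree, calls)
        seen = set()
        for g in groups:
            for sp, c in g.members.items():
                key = (sp, c.call_id)
                assert key not in seen
                seen.add(key)
        for sp, cs in specific.items():
            for c in cs:
                key = (sp, c.call_id)
                assert key not in seen
                seen.add(key)
        total = sum(len(v) for v in calls.values())
        assert len(seen) == total

    def test_rate_additivity_over_branches(self, small_sim):
        calls = {
            sp: retrofind.detect(small_sim.species[sp].genes, small_sim.species[sp].genome)
            for sp in small_sim.species
        }
        flanks = {
            sp: ortho.extract_all_flanks(
                calls[sp], small_sim.species[sp].genome, small_sim.species[sp].repeats
            )
            for sp in calls
        }
        pairs = ortho.match_orthologs(calls["A"], calls["B"], flanks["A"], flanks["B"], "A", "B")
        groups, specific = build_groups(pairs, small_sim.tree, calls)
        per_branch = {}
        for g in groups:
            per_branch[g.origin_branch] = per_branch.get(g.origin_branch, 0) + 1
        assert sum(per_branch.values()) == len(groups)


class TestBranchRate:
    @pytest.mark.parametrize(
        "n,dur,expected",
        [(1707, 12, 142), (6734, 42, 160), (0, 10, 0)],
    )
    def test_rates_round_to_published_values(self, n, dur, expected):
        assert round(branch_rate(n, dur)) == expected

    def test_nonpositive_duration_raises(self):
        with pytest.raises(ValueError):
            branch_rate(10, 0)


class TestXFluxTest:
    def test_all_x_parents_autosomal_copies_count_full_subset(self):
        subset = [_call(gene=f"g{i}", parent_on_x=True, on_x=False) for i in range(10)]
        background = subset + [
            _call(chrom="chr1", start=i * 2000, end=i * 2000 + 500, gene=f"h{i}")
            for i in range(100)
        ]
        res = x_flux_test(subset, background)
        assert res["n_out_of_x"] == 10

    def test_strong_excess_has_tiny_binomial_tail(self):
        # background proportion 1%, subset of 63 with 13 observed
        subset = [
            _call(gene=f"g{i}", start=i * 2000, end=i * 2000 + 500,
                  parent_on_x=i < 13, on_x=False)
            for i in range(63)
        ]
        bg = [
            _call(chrom="chr2", gene=f"b{i}", start=i * 2000, end=i * 2000 + 500,
                  parent_on_x=i < 10, on_x=False)
            for i in range(1000)
        ]
        res = x_flux_test(subset, subset + bg)
        assert res["p_out"] < 0.001

    def test_empty_subset_raises(self):
        with pytest.raises(ValueError):
            x_flux_test([], [_call()])

    def test_null_pvalues_not_systematically_small(self):
        # subset drawn from the same process as the background: the one-sided
        # binomial p should not concentrate near zero
        rng = np.random.default_rng(8)
        pvals = []
        for rep in range(50):
            calls = [
                _call(chrom="chr1", gene=f"g{i}", start=i * 2000, end=i * 2000 + 500,
                      parent_on_x=bool(rng.random() < 0.05), on_x=False)
                for i in range(400)
            ]
            idx = rng.choice(400, size=63, replace=False)
            subset = [calls[i] for i in idx]
            pvals.append(x_flux_test(subset, calls)["p_out"])
        assert np.mean(np.asarray(pvals) < 0.05) < 0.2
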