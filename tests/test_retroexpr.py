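import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retroscape import _seq, retroexpr, retrofind
from retroscape.io_formats import GeneSet, GenomicInterval, SamRead, Transcript
from retroscape.retrofind import RetrocopyCall
from retroscape.retroexpr import (
    ExpressionThresholds,
    align_to_decoy,
    build_decoy_reference,
    call_expressed,
    classify_context,
    detect_chimeric,
    expression_correlations,
    permutation_context_test,
    tau,
)
from retroscape.synthio import simulate_reads


def _call(chrom="chr1", start=5000, end=6000, gene="gP", tx="tP", strand="+", **kw):
    defaults = dict(identity=0.95, query_coverage=1.0, aligned_nt=end - start, n_exons_bridged=2)
    defaults.update(kw)
    return RetrocopyCall(GenomicInterval(chrom, start, end, strand), gene, tx, **defaults)


def _chimera_scene():
    """Host gene with the retrocopy in its first intron, GT..AG junction."""
    rng = np.random.default_rng(0)
    genome = {"chr1": _seq.random_seq(rng, 20_000)}
    # host exons [1000,1500) and [9000,9500); intron starts GT
    genome["chr1"][1500:1502] = _seq.encode("GT")
    genome["chr1"][9000 - 2 : 9000] = _seq.encode("AG")  # not used; gene acceptor
    genome["chr1"][4998:5000] = _seq.encode("AG")  # acceptor before the retro
    genes = GeneSet()
    genes.add_transcript(
        Transcript("tH", "gH", "chr1", "+",
                   [GenomicInterval("chr1", 1000, 1500), GenomicInterval("chr1", 9000, 9500)])
    )
    call = _call()
    return genome, genes, call


def _junction_reads(n, mapq=60, js=1500, je=5000):
    reads = []
    for i in range(n):
        reads.append(
            SamRead(f"jr{i}", "chr1", js - 50, mapq, [("M", 50), ("N", je - js), ("M", 50)], "+", "A" * 100)
        )
    return reads


class TestDetectChimeric:
    def test_five_reads_accept_four_reject(self):
        genome, genes, call = _chimera_scene()
        ev5 = detect_chimeric(_junction_reads(5), genes, [call], genome)
        assert len(ev5) == 1
        assert ev5[0].n_reads == 5
        assert ev5[0].host_gene == "gH"
        ev4 = detect_chimeric(_junction_reads(4), genes, [call], genome)
        assert ev4 == []

    def test_noncanonical_splice_site_rejected(self):
        genome, genes, call = _chimera_scene()
        genome["chr1"][1500:1502] = _seq.encode("GC")  # GC..AG junction
        assert detect_chimeric(_junction_reads(5), genes, [call], genome) == []

    def test_low_mapq_reads_do_not_support_events(self):
        genome, genes, call = _chimera_scene()
        assert detect_chimeric(_junction_reads(5, mapq=40), genes, [call], genome) == []

    def test_unknown_contig_raises(self):
        genome, genes, call = _chimera_scene()
        bad = [SamRead("r", "chrZ", 0, 60, [("M", 50), ("N", 100), ("M", 50)], "+", "A" * 100)]
        with pytest.raises(KeyError, match="chrZ"):
            detect_chimeric(bad, genes, [call], genome)

    def test_simulated_chimeras_recovered_exactly(self, expression_sim):
        sp = expression_sim.species["A"]
        truth = expression_sim.ground_truth.records["A"]
        calls = retrofind.detect(sp.genes, sp.genome)
        reads = simulate_reads(sp, expression_sim.ground_truth, ["testis"], 20, 11)
        events = detect_chimeric(reads["testis"], sp.genes, calls, sp.genome)
        got = {e.retro_id for e in events}
        expected = 0
        for rec in truth:
            if not (rec.chimeric and "testis" in rec.expressed_tissues):
                continue
            expected += 1
            assert any(
                c.call_id in got
                and rec.chrom == c.locus.chrom
                and rec.start < c.locus.end
                and c.locus.start < rec.end
                for c in calls
            )
        assert expected > 0
        assert len(got) == expected


class TestDecoyStrategy:
    def test_zero_calls_leaves_parent_transcripts_only(self, small_sim):
        sp = small_sim.species["A"]
        decoy = build_decoy_reference([], sp.genome, sp.genes)
        assert decoy.sequences == {}

    def test_identical_retrocopy_reads_are_ambiguous(self):
        rng = np.random.default_rng(1)
        genome = {"chr1": _seq.random_seq(rng, 30_000)}
        # retro locus identical to the parent mRNA
        parent = genome["chr1"][1000:2000].copy()
        genome["chr1"][10_000:11_000] = parent
        genes = GeneSet()
        genes.add_transcript(
            Transcript("tP", "gP", "chr1", "+",
                       [GenomicInterval("chr1", 1000, 1500), GenomicInterval("chr1", 1500, 2000)])
        )
        call = _call(start=10_000, end=11_000)
        decoy = build_decoy_reference([call], genome, genes)
        reads = [
            SamRead(f"r{i}", "chr1", 10_000 + i * 50, 60, [("M", 100)], "+",
                    _seq.decode(genome["chr1"][10_000 + i * 50 : 10_100 + i * 50]))
            for i in range(10)
        ]
        alns = align_to_decoy(reads, decoy)
        profiles = call_expressed({"testis": alns}, [call], decoy)
        assert not profiles[call.call_id].expressed

    def test_diverged_retrocopy_called_expressed(self):
        rng = np.random.default_rng(2)
        genome = {"chr1": _seq.random_seq(rng, 30_000)}
        parent = genome["chr1"][1000:2000].copy()
        diverged, _ = _seq.mutate(parent, 0.05, rng)
        genome["chr1"][10_000:11_000] = diverged
        genes = GeneSet()
        genes.add_transcript(
            Transcript("tP", "gP", "chr1", "+",
                       [GenomicInterval("chr1", 1000, 1500), GenomicInterval("chr1", 1500, 2000)])
        )
        call = _call(start=10_000, end=11_000)
        decoy = build_decoy_reference([call], genome, genes)
        reads = [
            SamRead(f"r{i}", "chr1", 10_000 + i * 45, 60, [("M", 100)], "+",
                    _seq.decode(genome["chr1"][10_000 + i * 45 : 10_100 + i * 45]))
            for i in range(20)
        ]
        alns = align_to_decoy(reads, decoy)
        profiles = call_expressed({"testis": alns}, [call], decoy)
        assert profiles[call.call_id].expressed

    def test_flank_only_reads_do_not_count(self):
        rng = np.random.default_rng(3)
        genome = {"chr1": _seq.random_seq(rng, 30_000)}
        call = _call(start=10_000, end=11_000)
        genes = GeneSet()
        genes.add_transcript(
            Transcript("tP", "gP", "chr1", "+",
                       [GenomicInterval("chr1", 1000, 1400), GenomicInterval("chr1", 1600, 2000)])
        )
        decoy = build_decoy_reference([call], genome, genes)
        # reads entirely inside the upstream 300-nt flank
        reads = [
            SamRead(f"r{i}", "chr1", 9700 + i * 10, 60, [("M", 100)], "+",
                    _seq.decode(genome["chr1"][9700 + i * 10 : 9800 + i * 10]))
            for i in range(10)
        ]
        alns = align_to_decoy(reads, decoy)
        profiles = call_expressed({"testis": alns}, [call], decoy)
        assert not profiles[call.call_id].expressed

    def test_min_unique_reads_boundary(self):
        rng = np.random.default_rng(4)
        genome = {"chr1": _seq.random_seq(rng, 30_000)}
        call = _call(start=10_000, end=11_000)
        genes = GeneSet()
        decoy = build_decoy_reference([call], genome, genes)

        def profile_with(n):
            reads = [
                SamRead(f"r{i}", "chr1", 10_200 + i * 30, 60, [("M", 100)], "+",
                        _seq.decode(genome["chr1"][10_200 + i * 30 : 10_300 + i * 30]))
                for i in range(n)
            ]
            alns = align_to_decoy(reads, decoy)
            return call_expressed({"testis": alns}, [call], decoy)[call.call_id]

        assert profile_with(2).expressed
        assert not profile_with(1).expressed

    def test_expression_ground_truth_recovered(self, expression_sim):
        sp = expression_sim.species["A"]
        truth = expression_sim.ground_truth.records["A"]
        calls = retrofind.detect(sp.genes, sp.genome)
        tissues = ["testis", "liver"]
        reads = simulate_reads(sp, expression_sim.ground_truth, tissues, 30, 21)
        decoy = build_decoy_reference(calls, sp.genome, sp.genes)
        alns = {t: align_to_decoy(rs, decoy) for t, rs in reads.items()}
        profiles = call_expressed(alns, calls, decoy)
        truth_by_call = {}
        for c in calls:
            for r in truth:
                if (r.chrom == c.locus.chrom and r.start < c.locus.end
                        and c.locus.start < r.end):
                    truth_by_call[c.call_id] = r
        expressed_truth = [
            cid for cid, r in truth_by_call.items()
            if r.expressed_tissues & set(tissues)
        ]
        assert expressed_truth
        recovered = sum(1 for cid in expressed_truth if profiles[cid].expressed)
        assert recovered / len(expressed_truth) >= 0.95
        silent = [cid for cid, r in truth_by_call.items() if not r.expressed_tissues]
        false_pos = sum(1 for cid in silent if profiles[cid].expressed)
        assert false_pos == 0


class TestTau:
    def test_uniform_vector_gives_zero(self):
        assert tau([3.0, 3.0, 3.0, 3.0]) == 0.0

    def test_single_tissue_gives_one(self):
        assert tau([0, 0, 5.0, 0, 0, 0]) == 1.0

    def test_closed_form_example(self):
        assert tau([1.0, 0.5, 0.0]) == pytest.approx(0.75)

    def test_all_zero_vector_undefined(self):
        with pytest.raises(ValueError):
            tau([0.0, 0.0])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1e6), min_size=2, max_size=8).filter(
            lambda v: max(v) > 0
        ),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounded_and_scale_invariant(self, vec, scale):
        t = tau(vec)
        assert 0.0 <= t <= 1.0
        assert tau([scale * v for v in vec]) == pytest.approx(t, abs=1e-9)


class TestClassifyContext:
    def _genes(self):
        genes = GeneSet()
        genes.add_transcript(
            Transcript("tH", "gH", "chr1", "+",
                       [GenomicInterval("chr1", 100_000, 100_500),
                        GenomicInterval("chr1", 140_000, 140_500)])
        )
        return genes

    def test_intronic_without_chimera_is_intragenic(self):
        call = _call(start=120_000, end=121_000)
        assert classify_context(call, self._genes(), []) == "intragenic"

    def test_tss_proximity_boundary_is_exclusive(self):
        genes = self._genes()
        # TSS at 100_000; retrocopy wholly upstream of the gene
        near = _call(start=85_002, end=86_000)   # gap 100_000 - 85_999 = 14_001
        far = _call(start=84_000, end=85_000)    # gap 15_001
        boundary = _call(start=84_001, end=85_001)  # last base 85_000 -> gap 15_000
        just_in = _call(start=84_002, end=85_002)   # gap 14_999
        assert classify_context(near, genes, []) == "near_TSS_same"
        assert classify_context(just_in, genes, []) == "near_TSS_same"
        assert classify_context(boundary, genes, []) == "distant"
        assert classify_context(far, genes, []) == "distant"

    def test_opposite_strand_chimera_class(self):
        call = _call(start=120_000, end=121_000, strand="-")
        ev = retroexpr.ChimericEvent("gH", call.call_id, (110_000, 120_000), 6, "+")
        assert classify_context(call, self._genes(), [ev]) == "intragenic_opposite_chimeric"

    def test_polya_proximity_and_strandedness(self):
        genes = self._genes()
        call = _call(start=150_000, end=151_000, strand="-")  # 9.5 kb past polyA at 140_499
        assert classify_context(call, genes, []) == "near_polyA_opposite"

    def test_every_call_gets_exactly_one_class(self, small_sim):
        sp = small_sim.species["A"]
        calls = retrofind.detect(sp.genes, sp.genome)
        for c in calls:
            cls = classify_context(c, sp.genes, [])
            assert cls in retroexpr.CONTEXT_CLASSES


class TestPermutationContextTest:
    def test_all_intragenic_in_gene_sparse_genome_gives_minimal_p(self):
        genes = GeneSet()
        genes.add_transcript(
            Transcript("tH", "gH", "chr1", "+",
                       [GenomicInterval("chr1", 0, 500), GenomicInterval("chr1", 9_500, 10_000)])
        )
        calls = [_call(start=1000 + i * 800, end=1600 + i * 800, gene=f"g{i}") for i in range(5)]
        thr = ExpressionThresholds(n_permutations=199)
        obs, null, p = permutation_context_test(calls, {"chr1": 10_000_000}, genes, thr, seed=0)
        assert obs == 1.0
        assert p == pytest.approx(1 / 200)

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_context_test(
                [_call()], {"chr1": 100_000}, GeneSet(), ExpressionThresholds(n_permutations=0)
            )

    def test_no_expressed_calls_rejected(self):
        with pytest.raises(ValueError):
            permutation_context_test([], {"chr1": 100_000}, GeneSet())


class TestExpressionCorrelations:
    def test_identical_and_reversed_vectors(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = expression_correlations({"parental": (x, x), "neighbor": (x, x[::-1])})
        by = {r["pair_type"]: r for r in res}
        assert by["parental"]["rho"] == pytest.approx(1.0)
        assert by["neighbor"]["rho"] == pytest.approx(-1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(7)
        x = rng.random(500).tolist()
        y = rng.random(500).tolist()
        [res] = expression_correlations({"parental": (x, y)})
        assert abs(res["rho"]) < 0.1

    def test_too_few_pairs_flagged_undefined(self):
        [res] = expression_correlations({"parental": ([1.0, 2.0], [1.0, 2.0])})
        assert not res["defined"]
        assert res["rho"] is None
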