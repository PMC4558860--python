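import numpy as np
import pytest

from retroscape import _seq, aligner, retrofind
from retroscape.io_formats import ChainedAlignment, GeneSet, GenomicInterval, Transcript
from retroscape.retrofind import DetectionThresholds, call_retrocopies, catalog_summary, filter_alignments


def _aln(matches, mismatches, qlen, blocks, strand="+", qname="t1", tname="chr1"):
    return ChainedAlignment(qname, qlen, tname, 10_000_000, strand, blocks, matches, mismatches)


class TestAligner:
    def test_exact_substring_full_identity(self):
        rng = np.random.default_rng(0)
        genome = {"chr1": _seq.random_seq(rng, 20_000)}
        tx = genome["chr1"][5000:5800].copy()
        [aln] = aligner.align_transcripts({"t": tx}, genome)
        assert aln.identity == 1.0
        assert aln.query_coverage == 1.0
        assert aln.target_start == 5000

    def test_absent_query_gives_empty_list(self):
        rng = np.random.default_rng(1)
        genome = {"chr1": _seq.random_seq(rng, 20_000)}
        foreign = _seq.random_seq(rng, 500)
        assert aligner.align_transcripts({"t": foreign}, genome) == []

    def test_two_percent_divergence_recovered_above_95_identity(self):
        rng = np.random.default_rng(2)
        genome = {"chr1": _seq.random_seq(rng, 50_000)}
        tx, _ = _seq.mutate(genome["chr1"][10_000:11_000], 0.02, rng)
        alns = aligner.align_transcripts({"t": tx}, genome)
        best = max(alns, key=lambda a: a.matches)
        assert best.identity >= 0.95
        assert best.aligned_nt >= 950

    def test_reverse_complement_query_found_on_minus_strand(self):
        rng = np.random.default_rng(3)
        genome = {"chr1": _seq.random_seq(rng, 30_000)}
        tx = _seq.revcomp(genome["chr1"][8000:8600])
        [aln] = aligner.align_transcripts({"t": tx}, genome)
        assert aln.strand == "-"
        assert aln.target_start == 8000


class TestFilterAlignments:
    def test_identity_below_threshold_rejected(self):
        # identity 0.70 < 0.75
        aln = _aln(matches=700, mismatches=300, qlen=1000, blocks=[(0, 0, 1000)])
        assert filter_alignments([aln]) == []

    def test_low_coverage_rescued_by_absolute_aligned_length(self):
        # identity 0.90, coverage 0.30, aligned 120 nt -> second disjunct keeps it
        aln = _aln(matches=108, mismatches=12, qlen=400, blocks=[(0, 0, 120)])
        assert filter_alignments([aln]) == [aln]

    def test_aligned_below_both_thresholds_rejected(self):
        aln = _aln(matches=100, mismatches=0, qlen=400, blocks=[(0, 0, 100)])
        assert filter_alignments([aln]) == []

    def test_intron_sized_internal_gap_rejected(self):
        aln = _aln(
            matches=400, mismatches=0, qlen=400,
            blocks=[(0, 0, 200), (200, 20_200, 200)],
        )
        assert filter_alignments([aln]) == []
        ok = _aln(
            matches=400, mismatches=0, qlen=400,
            blocks=[(0, 0, 200), (200, 10_200, 200)],
        )
        assert filter_alignments([ok]) == [ok]

    def test_zero_query_length_raises(self):
        aln = _aln(matches=0, mismatches=0, qlen=0, blocks=[(0, 0, 0)])
        with pytest.raises(ValueError, match="query_length 0"):
            filter_alignments([aln])

    def test_raising_identity_never_increases_survivors(self):
        rng = np.random.default_rng(4)
        alns = []
        for i in range(60):
            m = int(rng.integers(100, 400))
            mm = int(rng.integers(0, 120))
            alns.append(_aln(m, mm, 400, [(0, i * 1000, min(400, m + mm))]))
        prev = None
        for ident in (0.5, 0.65, 0.75, 0.85, 0.95):
            n = len(filter_alignments(alns, DetectionThresholds(min_identity=ident)))
            if prev is not None:
                assert n <= prev
            prev = n


def _three_exon_models():
    genes = GeneSet()
    exons = [GenomicInterval("chr1", 100, 300), GenomicInterval("chr1", 2300, 2500),
             GenomicInterval("chr1", 4500, 4700)]
    genes.add_transcript(Transcript("t1", "g1", "chr1", "+", exons))
    return genes


class TestCallRetrocopies:
    def test_intron_retaining_alignment_not_called(self):
        genes = _three_exon_models()
        # parental-style alignment far from the gene but with a 2000-nt
        # target gap at each exon junction: intron retained, not a retrocopy
        aln = _aln(
            matches=600, mismatches=0, qlen=600,
            blocks=[(0, 100_000, 200), (200, 102_200, 200), (400, 104_400, 200)],
        )
        assert call_retrocopies([aln], genes) == []

    def test_contiguous_junctions_called_with_all_exons_bridged(self):
        genes = _three_exon_models()
        aln = _aln(matches=600, mismatches=0, qlen=600, blocks=[(0, 100_000, 600)])
        [call] = call_retrocopies([aln], genes)
        assert call.n_exons_bridged == 3
        assert call.parental_gene == "g1"
        assert call.locus.start == 100_000

    def test_parental_locus_overlap_discarded(self):
        genes = _three_exon_models()
        aln = _aln(matches=600, mismatches=0, qlen=600, blocks=[(0, 150, 600)])
        assert call_retrocopies([aln], genes) == []

    def test_single_exon_transcript_never_called(self):
        genes = GeneSet()
        genes.add_transcript(
            Transcript("t1", "g1", "chr1", "+", [GenomicInterval("chr1", 100, 700)])
        )
        aln = _aln(matches=600, mismatches=0, qlen=600, blocks=[(0, 100_000, 600)])
        assert call_retrocopies([aln], genes) == []

    def test_two_isoforms_one_locus_merge_to_single_call(self):
        genes = _three_exon_models()
        genes.add_transcript(
            Transcript(
                "t2", "g1", "chr1", "+",
                [GenomicInterval("chr1", 100, 300), GenomicInterval("chr1", 4500, 4700)],
            )
        )
        alns = [
            _aln(matches=600, mismatches=0, qlen=600, blocks=[(0, 100_000, 600)], qname="t1"),
            _aln(matches=380, mismatches=20, qlen=400, blocks=[(0, 100_000, 400)], qname="t2"),
        ]
        calls = call_retrocopies(alns, genes)
        assert len(calls) == 1
        assert calls[0].parental_transcript == "t1"  # higher identity x coverage

    def test_exclusion_list_drops_gene(self):
        genes = _three_exon_models()
        aln = _aln(matches=600, mismatches=0, qlen=600, blocks=[(0, 100_000, 600)])
        assert call_retrocopies([aln], genes, exclude_genes={"g1"}) == []

    def test_missing_gene_model_names_transcript(self):
        genes = _three_exon_models()
        aln = _aln(matches=600, mismatches=0, qlen=600, blocks=[(0, 100_000, 600)], qname="ghost")
        with pytest.raises(KeyError, match="ghost"):
            call_retrocopies([aln], genes)

    def test_junction_gap_above_tolerance_breaks_bridge(self):
        genes = _three_exon_models()
        # junction 1 contiguous, junction 2 with a 40-nt target gap (> 30)
        aln = _aln(
            matches=600, mismatches=0, qlen=600,
            blocks=[(0, 100_000, 400), (400, 100_440, 200)],
        )
        [call] = call_retrocopies([aln], genes)
        assert call.n_exons_bridged == 2


class TestRecovery:
    def test_planted_copies_recovered_without_false_positives(self, small_sim):
        for sp in ("A", "B"):
            data = small_sim.species[sp]
            calls = retrofind.detect(data.genes, data.genome)
            truth = small_sim.ground_truth.records[sp]

            def hits(call):
                return [
                    r
                    for r in truth
                    if r.chrom == call.locus.chrom
                    and r.start < call.locus.end
                    and call.locus.start < r.end
                    and r.parental_gene == call.parental_gene
                ]

            tp = sum(1 for c in calls if hits(c))
            assert tp / len(truth) >= 0.95
            assert (len(calls) - tp) / max(len(calls), 1) <= 0.05

    def test_no_call_overlaps_its_parental_gene_span(self, small_sim):
        data = small_sim.species["A"]
        calls = retrofind.detect(data.genes, data.genome)
        assert calls, "expected calls on the synthetic clade"
        for c in calls:
            span = data.genes.genes[c.parental_gene].span
            assert not c.locus.overlaps(span)


class TestCatalogSummary:
    def test_empty_and_counting(self):
        df = catalog_summary({"human": []})
        assert df.loc[0, "n_retrocopies"] == 0
        assert df.loc[0, "n_parental_genes"] == 0
        calls = [
            retrofind.RetrocopyCall(
                GenomicInterval("chr1", i * 1000, i * 1000 + 500), f"g{i % 3}", f"t{i}",
                0.9, 0.8, 400, 2,
            )
            for i in range(5)
        ]
        df = catalog_summary({"human": calls})
        assert df.loc[0, "n_retrocopies"] == 5
        assert df.loc[0, "n_parental_genes"] == 3

    def test_synthetic_counts_match_ground_truth(self, small_sim):
        calls = {
            sp: retrofind.detect(small_sim.species[sp].genes, small_sim.species[sp].genome)
            for sp in small_sim.species
        }
        df = catalog_summary(calls).set_index("species")
        for sp, recs in small_sim.ground_truth.records.items():
            assert df.loc[sp, "n_retrocopies"] == len(recs)
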