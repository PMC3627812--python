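"""Intergenic sRNA screen, boundary refinement, filters, planted recovery."""

import numpy as np
import pandas as pd
import pytest

import predaseq as pq
from predaseq import srna as S
from predaseq.io import coverage_from_reads


def genes_df(rows):
    return pd.DataFrame(rows, columns=["gene_id", "start", "end", "strand"])


def reads_at(start, n, length=36, strand="+"):
    return pd.DataFrame({"start": [start] * n, "end": [start + length - 1] * n,
                         "strand": [strand] * n})


class TestIntergenicRegions:
    def test_complement(self):
        genes = genes_df([("a", 100, 200, "+"), ("b", 300, 400, "-")])
        regions = pq.intergenic_regions(genes, 500, min_len=1)
        assert regions.values.tolist() == [[1, 99], [201, 299], [401, 500]]

    def test_adjacent_genes_leave_no_gap(self):
        genes = genes_df([("a", 100, 200, "+"), ("b", 201, 300, "+")])
        regions = pq.intergenic_regions(genes, 300, min_len=1)
        assert regions.values.tolist() == [[1, 99]]

    def test_empty_annotation(self):
        regions = pq.intergenic_regions(genes_df([]), 1000, min_len=1)
        assert regions.values.tolist() == [[1, 1000]]

    def test_min_length_filter(self):
        genes = genes_df([("a", 100, 200, "+"), ("b", 220, 400, "+")])
        regions = pq.intergenic_regions(genes, 400, min_len=50)
        assert regions.values.tolist() == [[1, 99]]


class TestScreenRegions:
    def test_fold_and_significance_gates(self):
        regions = pd.DataFrame({"start": [1000, 3000, 5000], "end": [1206, 3206, 5206]})
        ap = pd.concat([reads_at(1050, 800), reads_at(3050, 300)], ignore_index=True)
        gp = pd.concat([reads_at(1050, 50), reads_at(3050, 100)], ignore_index=True)
        out = S.screen_regions(regions, ap, gp, (1100, 1100))  # equal depths
        # region 1: fold 800/50 = 16 > 4 and significant -> retained
        # region 2: fold 3 -> discarded; region 3: no reads -> p = 1, discarded
        assert list(out["start"]) == [1000]
        assert out["fold"].iloc[0] == pytest.approx(16.0)
        assert out["p_adj"].iloc[0] <= 0.05

    def test_fold_floor_with_zero_gp(self):
        fold = S.fold_with_floor(rpkm_ap=5000.0, rpkm_gp=0.0, length=200,
                                 total_gp=100_000)
        eps = 1e9 / (200 * 100_000)
        assert fold == pytest.approx(5000.0 / eps)

    def test_modest_fold_discarded(self):
        regions = pd.DataFrame({"start": [1000], "end": [1299]})
        ap = reads_at(1050, 300)
        gp = reads_at(1050, 100)
        out = S.screen_regions(regions, ap, gp, (300, 100))
        assert len(out) == 0  # equalized RPKM fold = 1 at these totals


class TestUtrReadthrough:
    def setup_method(self):
        self.genes = genes_df([("g", 2000, 3000, "+")])
        self.cand = pd.DataFrame([{"start": 1000, "end": 1500, "strand": "+",
                                   "count_ap": 100}])

    def cov(self, between):
        cov = np.zeros(4001)
        cov[1000:1501] = 100
        cov[1501:2000] = between
        cov[2000:3001] = 200
        return cov

    def test_connected_to_expressed_gene_discarded(self):
        out = S.exclude_utr_readthrough(self.cand, self.cov(80), self.genes, {"g"})
        assert len(out) == 0

    def test_coverage_gap_retains(self):
        out = S.exclude_utr_readthrough(self.cand, self.cov(0), self.genes, {"g"})
        assert len(out) == 1

    def test_opposite_strand_gene_retains(self):
        genes = genes_df([("g", 2000, 3000, "-")])
        out = S.exclude_utr_readthrough(self.cand, self.cov(80), genes, {"g"})
        assert len(out) == 1

    def test_unexpressed_gene_retains(self):
        out = S.exclude_utr_readthrough(self.cand, self.cov(80), self.genes, set())
        assert len(out) == 1


class TestRefineBoundaries:
    def calls(self, pos, strand, support=500):
        return pd.DataFrame([{"position": pos, "strand": strand,
                              "raw_plus": support, "raw_minus": 0,
                              "enrichment": 10.0, "gene_id": None,
                              "distance_to_start": 0}])

    def test_sharp_cliff(self):
        """Uniform coverage with an abrupt 3' cliff ends exactly at the cliff."""
        cov = np.zeros(10_001)
        cov[5000:5445] = 80  # transcript 5000..5444
        cand = pd.Series({"start": 4900, "end": 5600, "count_ap": 100})
        refined = S.refine_boundaries(cand, self.calls(5000, "+"), cov)
        assert refined["start"] == 5000
        assert refined["end"] == 5444
        assert refined["size"] == 445

    def test_minus_strand_refinement(self):
        cov = np.zeros(10_001)
        cov[5000:5445] = 80
        cand = pd.Series({"start": 4900, "end": 5600, "count_ap": 100})
        refined = S.refine_boundaries(cand, self.calls(5444, "-"), cov)
        assert refined["strand"] == "-"
        assert refined["start"] == 5000 and refined["end"] == 5444

    def test_strongest_tss_wins(self):
        cov = np.zeros(10_001)
        cov[5000:5445] = 80
        calls = pd.concat([self.calls(5000, "+", 500), self.calls(5100, "+", 50)],
                          ignore_index=True)
        cand = pd.Series({"start": 4900, "end": 5600, "count_ap": 100})
        refined = S.refine_boundaries(cand, calls, cov)
        assert refined["tss_position"] == 5000

    def test_no_tss_drops_candidate(self):
        cov = np.zeros(10_001)
        cov[5000:5445] = 80
        cand = pd.Series({"start": 4900, "end": 5600, "count_ap": 100})
        assert S.refine_boundaries(cand, self.calls(8000, "+"), cov) is None


class TestOrfFilter:
    def test_planted_orf_flagged(self):
        rng = np.random.default_rng(3)
        body = "".join(rng.choice(["GCA", "GCC", "TGC", "GAC"], 60))  # no stops
        seq = "CCCC" + "ATG" + body + "TAA" + "CCCC"
        assert S.orf_filter(seq, max_orf_aa=50) is True

    def test_atg_without_stop_is_not_an_orf(self):
        seq = "ATG" + "GCA" * 80  # open-ended: no closed ORF
        assert S.orf_filter(seq, max_orf_aa=50) is False

    def test_short_random_sequence_not_flagged(self):
        rng = np.random.default_rng(8)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 150)])
        # a 50-codon closed ORF needs >150 nt: impossible here
        assert S.orf_filter(seq, max_orf_aa=50) is False


@pytest.fixture(scope="module")
def discovered(bundle, expression_table):
    calls = pq.deduplicate(pq.call_tss(
        bundle["tap_plus"], bundle["tap_minus"], None))
    expressed_ap = set(
        expression_table.loc[expression_table["expressed_ap"], "gene_id"])
    totals = (bundle["spec"].library_size_ap, bundle["spec"].library_size_gp)
    return pq.discover_srnas(bundle["genes"], bundle["genome"], bundle["ap"],
                             bundle["gp"], calls, totals, expressed_ap)


class TestPipelineRecovery:
    def test_all_planted_recovered_within_10nt(self, bundle, discovered):
        for t in bundle["truth"].true_srnas.itertuples(index=False):
            match = discovered[(discovered["strand"] == t.strand)
                               & (abs(discovered["start"] - t.start) <= 10)
                               & (abs(discovered["end"] - t.end) <= 10)]
            assert len(match) == 1, f"planted sRNA {t.name} not recovered"

    def test_candidates_lie_in_intergenic_space(self, bundle, discovered):
        genes = bundle["genes"]
        for c in discovered.itertuples(index=False):
            overlap = genes[(genes["start"] <= c.end) & (genes["end"] >= c.start)]
            assert len(overlap) == 0

    def test_rescreen_is_idempotent(self, bundle, discovered):
        """Emitted refined intervals still pass fold > 4 and p_adj <= 0.05."""
        totals = (bundle["spec"].library_size_ap, bundle["spec"].library_size_gp)
        regions = pq.intergenic_regions(bundle["genes"], bundle["spec"].genome_length)
        for c in discovered.itertuples(index=False):
            stats = S.rescreen_interval(c.start, c.end, bundle["ap"], bundle["gp"],
                                        totals, n_tests=len(regions))
            assert stats["fold"] > 4
            assert stats["p_adj"] <= 0.05

    def test_null_simulation_yields_no_candidates(self):
        spec = pq.SimulationSpec(genome_length=40_000, n_genes=30, n_srnas=0,
                                 library_size_ap=30_000, library_size_gp=30_000,
                                 tap_plus_depth=20_000, tap_minus_depth=15_000,
                                 seed=19)
        genome, genes, truth = pq.generate_genome(spec)
        ap, gp = pq.simulate_alignments(genome, truth, spec)
        tap_plus, tap_minus = pq.simulate_5prime_tracks(truth, spec)
        calls = pq.deduplicate(pq.call_tss(tap_plus, tap_minus, None))
        table = pq.build_table(ap, gp, genes)
        expressed_ap = set(table.loc[table["expressed_ap"], "gene_id"])
        out = pq.discover_srnas(genes, genome, ap, gp, calls,
                                (30_000, 30_000), expressed_ap)
        assert len(out) == 0


def test_annotate_promoter_requires_tss(consensus_motif):
    with pytest.raises(ValueError):
        S.annotate_promoter({"tss_position": 100, "strand": "+"},
                            consensus_motif, promoters={})


def test_annotate_promoter_roundtrip(bundle, consensus_motif):
    """Planted sRNA promoters with the element are recognized; others are not."""
    truth, genome = bundle["truth"], bundle["genome"]
    for s in truth.true_srnas.itertuples(index=False):
        tss = s.start if s.strand == "+" else s.end
        calls = pd.DataFrame([{"position": tss, "strand": s.strand}])
        promoters = pq.extract_promoters(calls, genome)
        got = S.annotate_promoter({"tss_position": tss, "strand": s.strand},
                                  consensus_motif, promoters)
        assert got == bool(s.has_motif)
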