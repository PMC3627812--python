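"""TSS calling, deduplication, operon assignment, promoter extraction."""

import numpy as np
import pandas as pd
import pytest

import predaseq as pq
from predaseq.io import reverse_complement

from conftest import make_track, tss_match


def genes_df(rows):
    return pd.DataFrame(rows, columns=["gene_id", "start", "end", "strand"])


GENES = genes_df([("a", 1100, 2000, "+")])
FAR = (30_000, "+", 100)  # depth ballast far away from any gene


class TestCallTss:
    def test_thresholds_with_pseudocount(self):
        """raw 10 vs 2 at equal depth: enrichment 10/3 passes; 9 vs 8 fails."""
        plus = make_track([(1000, "+", 10), (1050, "+", 9), FAR])
        minus = make_track([(1000, "+", 2), (1050, "+", 8),
                            (30_000, "+", 109)], "TAP_minus")
        assert plus.total_reads == minus.total_reads  # equal depths by design
        calls = pq.call_tss(plus, minus, GENES)
        assert list(calls["position"]) == [1000]
        assert calls["enrichment"].iloc[0] == pytest.approx(10 / 3)

    def test_min_read_support(self):
        plus = make_track([(1000, "+", 4), FAR])
        minus = make_track([(30_000, "+", 104)], "TAP_minus")
        assert len(pq.call_tss(plus, minus, GENES)) == 0

    def test_upstream_requirement(self):
        plus = make_track([(500, "+", 50), (1099, "+", 50), (1105, "+", 50),
                           (1200, "+", 50), (1050, "-", 50), FAR])
        minus = make_track([FAR], "TAP_minus")
        calls = pq.call_tss(plus, minus, GENES, max_upstream=300)
        # 500 too far, 1200 beyond 3-codon slack, 1050(-) wrong strand
        assert sorted(calls["position"]) == [1099, 1105]
        assert set(calls["gene_id"]) == {"a"}

    def test_annotation_free_mode(self):
        plus = make_track([(500, "+", 50), FAR])
        minus = make_track([FAR], "TAP_minus")
        calls = pq.call_tss(plus, minus, None)
        assert 500 in set(calls["position"])
        assert calls["gene_id"].isna().all()

    def test_empty_track_is_error(self):
        plus = make_track([(1000, "+", 10)])
        empty = make_track([], "TAP_minus")
        with pytest.raises(ValueError):
            pq.call_tss(plus, empty, GENES)

    def test_emitted_calls_recheck_against_raw_tracks(self, bundle):
        """Every emitted call satisfies the support/enrichment/upstream rules."""
        plus, minus = bundle["tap_plus"], bundle["tap_minus"]
        calls = pq.call_tss(plus, minus, bundle["genes"])
        plus_lu, minus_lu = plus.lookup(), minus.lookup()
        for rec in calls.itertuples(index=False):
            key = (rec.position, rec.strand)
            assert plus_lu[key] >= 5
            enr = (plus_lu[key] / plus.total_reads) / \
                  ((minus_lu.get(key, 0) + 1) / minus.total_reads)
            assert enr >= 3.0
            assert 0 <= rec.distance_to_start <= 300


class TestDeduplicate:
    def base(self, entries):
        rows = [{"position": p, "strand": s, "raw_plus": c, "raw_minus": 0,
                 "enrichment": 10.0, "gene_id": "a", "distance_to_start": 10}
                for p, s, c in entries]
        return pd.DataFrame(rows)

    def test_max_rule(self):
        out = pq.deduplicate(self.base([(100, "+", 50), (103, "+", 8)]))
        assert list(out["position"]) == [100]

    def test_separation(self):
        out = pq.deduplicate(self.base([(100, "+", 50), (120, "+", 8)]))
        assert list(out["position"]) == [100, 120]

    def test_tie_breaks_to_most_5prime(self):
        out = pq.deduplicate(self.base([(100, "+", 8), (102, "+", 8)]))
        assert list(out["position"]) == [100]
        out = pq.deduplicate(self.base([(100, "-", 8), (102, "-", 8)]))
        assert list(out["position"]) == [102]  # 5' on minus = larger coordinate

    def test_output_separated_by_window(self, bundle):
        calls = pq.call_tss(bundle["tap_plus"], bundle["tap_minus"], None)
        out = pq.deduplicate(calls, window=5)
        for _, sub in out.groupby("strand"):
            pos = sub["position"].to_numpy()
            assert (np.diff(np.sort(pos)) > 5).all()


class TestAssignOperons:
    def setup_method(self):
        self.genes = genes_df([
            ("a", 1000, 2000, "+"), ("b", 2021, 3000, "+"),  # gap 20
            ("c", 3500, 4000, "-"),
        ])
        self.calls = pd.DataFrame([{
            "position": 950, "strand": "+", "raw_plus": 50, "raw_minus": 0,
            "enrichment": 10.0, "gene_id": "a", "distance_to_start": 50}])
        self.cov = np.zeros(5001)
        self.cov[1000: 3001] = 100  # continuous over a, gap, b

    def test_small_gap_extends(self):
        ops = pq.assign_operons(self.calls, self.genes, self.cov)
        assert ops[(950, "+")] == ["a", "b"]

    def test_opposite_strand_stops(self):
        genes = self.genes.copy()
        genes.loc[genes["gene_id"] == "b", "strand"] = "-"
        ops = pq.assign_operons(self.calls, genes, self.cov)
        assert ops[(950, "+")] == ["a"]

    def test_own_tss_stops(self):
        calls = pd.concat([self.calls, pd.DataFrame([{
            "position": 2010, "strand": "+", "raw_plus": 30, "raw_minus": 0,
            "enrichment": 8.0, "gene_id": "b", "distance_to_start": 11}])],
            ignore_index=True)
        ops = pq.assign_operons(calls, self.genes, self.cov)
        assert ops[(950, "+")] == ["a"]

    def test_large_gap_needs_connecting_coverage(self):
        genes = genes_df([("a", 1000, 2000, "+"), ("b", 2200, 3000, "+")])  # gap 199
        cov = np.zeros(5001)
        cov[1000: 2001] = 100
        cov[2200: 3001] = 100  # gap uncovered
        ops = pq.assign_operons(self.calls, genes, cov)
        assert ops[(950, "+")] == ["a"]
        cov[2001: 2200] = 40  # 40% of upstream mean connects the gap
        ops = pq.assign_operons(self.calls, genes, cov)
        assert ops[(950, "+")] == ["a", "b"]


class TestExtractPromoters:
    def test_plus_strand_coordinates(self):
        genome = "".join(np.random.default_rng(0).choice(list("ACGT"), 2000))
        calls = pd.DataFrame([{"position": 1000, "strand": "+"}])
        seq = pq.extract_promoters(calls, genome)[(1000, "+")]
        assert seq == genome[949:999]

    def test_minus_strand_is_reverse_complement(self):
        genome = "".join(np.random.default_rng(1).choice(list("ACGT"), 2000))
        calls = pd.DataFrame([{"position": 1000, "strand": "-"}])
        seq = pq.extract_promoters(calls, genome)[(1000, "-")]
        assert seq == reverse_complement(genome[1000:1050])

    def test_edge_calls_skipped_with_warning(self):
        genome = "A" * 200
        calls = pd.DataFrame([{"position": 20, "strand": "+"},
                              {"position": 180, "strand": "-"}])
        with pytest.warns(UserWarning):
            out = pq.extract_promoters(calls, genome)
        assert out == {}

    def test_roundtrip_relocate(self, bundle):
        """Re-locating a promoter on the genome and re-extracting reproduces it."""
        calls = pq.deduplicate(pq.call_tss(
            bundle["tap_plus"], bundle["tap_minus"], bundle["genes"]))
        promoters = pq.extract_promoters(calls, bundle["genome"])
        for (pos, strand), seq in promoters.items():
            assert len(seq) == 50
            again = pq.extract_promoters(
                pd.DataFrame([{"position": pos, "strand": strand}]),
                bundle["genome"])[(pos, strand)]
            assert again == seq


class TestPlantedRecovery:
    def test_sensitivity_and_precision(self, bundle):
        """Enriched positions recover planted TSSs at >= 0.95 / 0.95 (+/-2 nt)."""
        calls = pq.deduplicate(pq.call_tss(
            bundle["tap_plus"], bundle["tap_minus"], None))
        sens, prec = tss_match(calls, bundle["truth"].true_tss)
        assert sens >= 0.95
        assert prec >= 0.95

    def test_gene_assigned_calls_recover_gene_tss(self, bundle):
        calls = pq.deduplicate(pq.call_tss(
            bundle["tap_plus"], bundle["tap_minus"], bundle["genes"]))
        gene_ids = set(bundle["genes"]["gene_id"])
        truth = bundle["truth"].true_tss
        gene_tss = truth[[ids[0] in gene_ids for ids in truth["gene_ids"]]]
        sens, prec = tss_match(calls, gene_tss)
        assert sens >= 0.95
        assert prec >= 0.95
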