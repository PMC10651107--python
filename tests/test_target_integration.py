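import numpy as np
import pandas as pd
import pytest

from sinreg.annotation_io import GeneModel, GenomeAnnotation
from sinreg.target_integration import (
    ACTIVATED, KNOCKDOWN, NOT_SIGNIFICANT, OVEREXPRESSION, REPRESSED,
    DirectTargetTable, Peak, PerturbationConfig, annotate_enhancer_overlap,
    assign_peaks_to_genes, build_direct_targets, classify_direction,
    overlap_summary, read_peaks, write_narrowpeak,
)


def brute_force_assignment(peaks, annotation, upstream=1000, past_tes=100):
    """All-pairs overlap oracle for peak-to-gene assignment."""
    out = {}
    for gene in annotation:
        if gene.strand == "+":
            lo, hi = gene.start - upstream, gene.end + past_tes
        else:
            lo, hi = gene.start - past_tes, gene.end + upstream
        lo = max(0, lo)
        for p in peaks:
            if p.chrom == gene.chrom and p.start < hi and p.end > lo:
                out.setdefault(gene.gene_id, []).append(p)
    return out


class TestAssignPeaksToGenes:
    @pytest.fixture
    def plus_gene(self):
        ann = GenomeAnnotation()
        ann.add(GeneModel("g1", "chr1", 5000, 8000, "+"))
        return ann

    def test_peak_within_upstream_kb_assigned(self, plus_gene):
        assigned = assign_peaks_to_genes([Peak("chr1", 4200, 4300)], plus_gene)
        assert set(assigned) == {"g1"}

    def test_peak_past_tes_plus_100_not_assigned(self, plus_gene):
        assigned = assign_peaks_to_genes([Peak("chr1", 8150, 8200)], plus_gene)
        assert assigned == {}

    def test_minus_strand_upstream_is_genomically_downstream(self):
        ann = GenomeAnnotation()
        ann.add(GeneModel("g1", "chr1", 5000, 8000, "-"))
        # upstream of the - strand TSS at 7999
        assert set(assign_peaks_to_genes([Peak("chr1", 8500, 8600)], ann)) == {"g1"}
        # past the - strand TES + 100
        assert assign_peaks_to_genes([Peak("chr1", 4700, 4850)], ann) == {}

    def test_peak_may_hit_multiple_overlapping_genes(self):
        ann = GenomeAnnotation()
        ann.add(GeneModel("g1", "chr1", 5000, 8000, "+"))
        ann.add(GeneModel("g2", "chr1", 6000, 9000, "-"))
        assigned = assign_peaks_to_genes([Peak("chr1", 6500, 6600)], ann)
        assert set(assigned) == {"g1", "g2"}

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            ann = GenomeAnnotation()
            n_genes = int(rng.integers(5, 40))
            for i in range(n_genes):
                start = int(rng.integers(0, 200_000))
                end = start + int(rng.integers(500, 20_000))
                strand = "+" if rng.random() < 0.5 else "-"
                ann.add(GeneModel(f"g{i}", f"chr{int(rng.integers(1, 3))}", start, end, strand))
            peaks = [
                Peak(f"chr{int(rng.integers(1, 3))}",
                     s := int(rng.integers(0, 220_000)), s + int(rng.integers(50, 2_000)))
                for _ in range(int(rng.integers(5, 60)))
            ]
            got = assign_peaks_to_genes(peaks, ann)
            expected = brute_force_assignment(peaks, ann)
            assert {g: sorted((p.start, p.end) for p in ps) for g, ps in got.items()} == \
                   {g: sorted((p.start, p.end) for p in ps) for g, ps in expected.items()}


class TestClassifyDirection:
    CFG_KD = PerturbationConfig(KNOCKDOWN, 0.05, 0.05)
    CFG_OE = PerturbationConfig(OVEREXPRESSION, 0.05, 0.05)

    def test_up_under_knockdown_is_repressed(self):
        assert classify_direction(1.2, 0.001, 0.01, self.CFG_KD) == REPRESSED

    def test_up_under_overexpression_is_activated(self):
        assert classify_direction(1.2, 0.001, 0.01, self.CFG_OE) == ACTIVATED

    def test_failing_fdr_is_not_significant(self):
        assert classify_direction(-3.0, 0.001, 0.2, self.CFG_KD) == NOT_SIGNIFICANT

    def test_failing_p_is_not_significant(self):
        assert classify_direction(-3.0, 0.2, 0.001, self.CFG_KD) == NOT_SIGNIFICANT

    def test_zero_log2fc_has_no_direction(self):
        assert classify_direction(0.0, 0.001, 0.001, self.CFG_KD) == NOT_SIGNIFICANT

    def test_partition_and_polarity_swap(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            lfc = float(rng.normal(0, 2)) if rng.random() > 0.05 else 0.0
            p, fdr = float(rng.random()), float(rng.random())
            kd = classify_direction(lfc, p, fdr, self.CFG_KD)
            oe = classify_direction(lfc, p, fdr, self.CFG_OE)
            assert kd in (REPRESSED, ACTIVATED, NOT_SIGNIFICANT)
            if kd == NOT_SIGNIFICANT:
                assert oe == NOT_SIGNIFICANT
            else:
                assert {kd, oe} == {REPRESSED, ACTIVATED}


class TestBuildDirectTargets:
    def setup_method(self):
        self.ann = GenomeAnnotation()
        self.ann.add(GeneModel("bound_up", "chr1", 5000, 8000, "+"))
        self.ann.add(GeneModel("unbound_up", "chr1", 50_000, 55_000, "+"))
        self.ann.add(GeneModel("bound_null", "chr1", 100_000, 104_000, "+"))
        self.peaks = [Peak("chr1", 4900, 5200), Peak("chr1", 99_900, 100_200)]
        self.de = pd.DataFrame({
            "gene_id": ["bound_up", "unbound_up", "bound_null", "not_in_annotation"],
            "log2fc": [1.5, 2.0, 0.4, 1.0],
            "pvalue": [0.001, 0.001, 0.5, 0.001],
            "fdr": [0.01, 0.01, 0.9, 0.01],
        })

    def test_bound_and_significant_becomes_target(self):
        table = build_direct_targets(self.peaks, self.ann, self.de, PerturbationConfig())
        assert table.gene_ids == {"bound_up"}
        row = table.frame.iloc[0]
        assert row["direction"] == REPRESSED and row["n_peaks"] == 1

    def test_significant_but_unbound_excluded(self):
        table = build_direct_targets(self.peaks, self.ann, self.de, PerturbationConfig())
        assert "unbound_up" not in table.gene_ids

    def test_empty_intersection_is_valid(self):
        table = build_direct_targets([], self.ann, self.de, PerturbationConfig())
        assert len(table) == 0

    def test_table_invariant_rejects_not_significant_rows(self):
        frame = pd.DataFrame([{"gene_id": "x", "bound": True, "n_peaks": 1,
                               "direction": NOT_SIGNIFICANT, "log2fc": 1.0, "fdr": 0.01}])
        with pytest.raises(ValueError):
            DirectTargetTable(frame)


class TestOverlapSummary:
    @staticmethod
    def table_from_ids(ids, label):
        frame = pd.DataFrame({"gene_id": list(ids), "bound": True, "n_peaks": 1,
                              "direction": REPRESSED, "log2fc": 1.0, "fdr": 0.01})
        return DirectTargetTable(frame[DirectTargetTable.COLUMNS], label=label)

    def test_isoform_sharing_percentages(self):
        # 405 and 859 targets sharing 335 genes
        a = self.table_from_ids([f"s{i}" for i in range(335)] + [f"a{i}" for i in range(70)], "220")
        b = self.table_from_ids([f"s{i}" for i in range(335)] + [f"b{i}" for i in range(524)], "187")
        s = overlap_summary(a, b)
        assert s["shared"] == 335
        assert s["shared_of_a"] == {"pct": 82.7, "pct_int": 83}
        assert s["unique_of_b"] == {"pct": 61.0, "pct_int": 61}

    def test_identical_tables_fully_shared(self):
        a = self.table_from_ids(["x", "y"], "a")
        s = overlap_summary(a, a)
        assert (s["only_a"], s["only_b"], s["shared"]) == (0, 0, 2)
        assert s["shared_of_a"]["pct"] == 100.0

    def test_disjoint_tables_share_nothing(self):
        a = self.table_from_ids(["x"], "a")
        b = self.table_from_ids(["y"], "b")
        assert overlap_summary(a, b)["shared"] == 0

    def test_count_identities_on_random_sets(self):
        rng = np.random.default_rng(9)
        universe = [f"g{i}" for i in range(200)]
        for _ in range(20):
            a_ids = list(rng.choice(universe, size=int(rng.integers(1, 150)), replace=False))
            b_ids = list(rng.choice(universe, size=int(rng.integers(1, 150)), replace=False))
            s = overlap_summary(self.table_from_ids(a_ids, "a"), self.table_from_ids(b_ids, "b"))
            assert s["only_a"] + s["shared"] == s["n_a"] == len(a_ids)
            assert s["only_b"] + s["shared"] == s["n_b"] == len(b_ids)


class TestEnhancerOverlap:
    def test_single_bp_overlap_counts(self):
        flags, counts = annotate_enhancer_overlap([Peak("chr1", 100, 200)], [("chr1", 150, 160)])
        assert flags == [True]
        assert counts == {"enhancer_peaks": 1, "non_enhancer_peaks": 0}

    def test_no_enhancers_all_negative(self):
        peaks = [Peak("chr1", 0, 10), Peak("chr2", 5, 50)]
        flags, counts = annotate_enhancer_overlap(peaks, [])
        assert flags == [False, False]
        assert counts["non_enhancer_peaks"] == 2

    def test_counts_match_quadratic_oracle(self):
        rng = np.random.default_rng(31)
        peaks = [Peak("chr1", s := int(rng.integers(0, 1_000_000)), s + int(rng.integers(50, 1000)))
                 for _ in range(1000)]
        enhancers = [("chr1", s := int(rng.integers(0, 1_000_000)), s + int(rng.integers(100, 2000)))
                     for _ in range(1000)]
        flags, counts = annotate_enhancer_overlap(peaks, enhancers)
        expected = [any(p.start < e and p.end > s for _, s, e in enhancers) for p in peaks]
        assert flags == expected
        assert counts["enhancer_peaks"] == sum(expected)


class TestPeakIO:
    def test_narrowpeak_round_trip(self, tmp_path):
        peaks = [Peak("chr1", 100, 500, score=250.0, summit=200),
                 Peak("chr2", 900, 1300, score=10.0, summit=None)]
        p = tmp_path / "p.narrowPeak"
        write_narrowpeak(peaks, p)
        back = read_peaks(p)
        assert [(q.chrom, q.start, q.end, q.summit) for q in back] == \
               [(q.chrom, q.start, q.end, q.summit) for q in peaks]

    def test_bed3_accepted(self, tmp_path):
        p = tmp_path / "p.bed"
        p.write_text("chr1\t10\t90\n")
        peaks = read_peaks(p)
        assert (peaks[0].start, peaks[0].end, peaks[0].summit) == (10, 90, None)

    def test_summit_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="summit"):
            Peak("chr1", 0, 100, summit=100)
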