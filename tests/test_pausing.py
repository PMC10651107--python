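import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from conftest import random_track
from sinreg.annotation_io import GeneModel, GenomeAnnotation, oriented_window
from sinreg.pausing import (
    STATUS_OK, STATUS_SHORT, STATUS_ZERO_BODY,
    compare_pausing, mann_whitney_u, pausing_index, pausing_table,
)
from sinreg.signal_tracks import SignalTrack, window_values


class TestPausingIndex:
    def test_uniform_track_gives_unit_ratio(self):
        track = SignalTrack.from_intervals([("chr1", 0, 20_000, 2.0)])
        gene = GeneModel("g", "chr1", 5000, 10_000, "+")
        res = pausing_index(track, gene)
        assert res.status == STATUS_OK
        assert res.pi == pytest.approx(1.0)

    def test_promoter_enrichment_ratio(self):
        # promoter mean 10 vs body mean 2 on a piecewise-constant track
        gene = GeneModel("g", "chr1", 5000, 10_000, "+")
        track = SignalTrack.from_intervals([
            ("chr1", 4950, 5050, 10.0),   # [TSS-50, TSS+50)
            ("chr1", 5300, 9900, 2.0),    # [TSS+300, TES-100)
        ])
        res = pausing_index(track, gene)
        assert (res.promoter_mean, res.body_mean) == (10.0, 2.0)
        assert res.pi == pytest.approx(5.0)

    def test_minus_strand_windows_are_mirrored(self):
        gene = GeneModel("g", "chr1", 5000, 10_000, "-")
        track = SignalTrack.from_intervals([
            ("chr1", 9950, 10_050, 10.0),  # promoter straddles the - strand TSS at 9999
            ("chr1", 5100, 9700, 2.0),     # body [start+100, end-300)
        ])
        res = pausing_index(track, gene)
        assert res.pi == pytest.approx(5.0)

    def test_short_gene_excluded(self):
        track = SignalTrack.from_intervals([("chr1", 0, 10_000, 1.0)])
        gene = GeneModel("g", "chr1", 5000, 5350, "+")
        res = pausing_index(track, gene)
        assert res.status == STATUS_SHORT
        assert res.pi is None

    def test_zero_body_signal_excluded_not_infinite(self):
        gene = GeneModel("g", "chr1", 5000, 10_000, "+")
        track = SignalTrack.from_intervals([("chr1", 4950, 5050, 4.0)])
        res = pausing_index(track, gene)
        assert res.status == STATUS_ZERO_BODY
        assert res.pi is None

    def test_matches_dense_oracle_on_random_tracks(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            track, dense = random_track(rng)
            start = int(rng.integers(500, 3000))
            length = int(rng.integers(500, 6000))
            strand = "+" if rng.random() < 0.5 else "-"
            gene = GeneModel("g", "chr1", start, min(start + length, 9500), strand)
            res = pausing_index(track, gene)
            p_lo, p_hi = oriented_window(gene.tss, -50, 50, strand)
            exp_prom = dense[p_lo:p_hi].mean()
            b_lo, b_hi = oriented_window(gene.tss, 300, gene.length - 100, strand)
            exp_body = dense[b_lo:b_hi].mean()
            assert res.promoter_mean == pytest.approx(exp_prom)
            if exp_body == 0:
                assert res.status == STATUS_ZERO_BODY
            else:
                assert res.pi == pytest.approx(exp_prom / exp_body)

    def test_track_scaling_leaves_pi_invariant(self):
        rng = np.random.default_rng(43)
        track, dense = random_track(rng)
        scaled = SignalTrack.from_dense({"chr1": dense * 7.3})
        gene = GeneModel("g", "chr1", 2000, 8000, "+")
        a, b = pausing_index(track, gene), pausing_index(scaled, gene)
        if a.status == STATUS_OK:
            assert b.pi == pytest.approx(a.pi)


class TestMannWhitneyU:
    def test_separated_samples_exact_enumeration(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0
        assert res.p_two_sided == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments
        assert res.method == "exact"

    def test_all_tied_is_symmetric(self):
        res = mann_whitney_u([5, 5], [5, 5])
        assert res.u_statistic == 2.0  # n_a * n_b / 2
        assert res.p_two_sided == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_u_bounded_by_group_size_product(self):
        rng = np.random.default_rng(44)
        for _ in range(50):
            a = rng.normal(size=int(rng.integers(2, 20)))
            b = rng.normal(size=int(rng.integers(2, 20)))
            res = mann_whitney_u(a, b)
            assert 0 <= res.u_statistic <= a.size * b.size

    def test_matches_reference_on_tie_free_samples(self):
        rng = np.random.default_rng(45)
        for _ in range(30):
            a = rng.normal(size=30)
            b = rng.normal(0.4, 1.2, size=30)
            mine = mann_whitney_u(a, b)
            ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            assert mine.p_two_sided == pytest.approx(ref.pvalue, abs=1e-6)

    def test_matches_reference_with_ties(self):
        rng = np.random.default_rng(46)
        for _ in range(20):
            a = rng.integers(0, 6, size=25).astype(float)
            b = rng.integers(1, 7, size=30).astype(float)
            mine = mann_whitney_u(a, b)
            ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            assert mine.p_two_sided == pytest.approx(ref.pvalue, abs=1e-6)

    def test_exact_close_to_normal_approximation(self):
        # sanity band: exact enumeration vs forced normal path at n=5+5
        rng = np.random.default_rng(47)
        for _ in range(10):
            a, b = rng.normal(size=5), rng.normal(size=5)
            exact = mann_whitney_u(a, b)
            assert exact.method == "exact"
            ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            assert exact.p_two_sided == pytest.approx(ref.pvalue, abs=0.05)

    def test_shift_monotonicity_of_u(self):
        rng = np.random.default_rng(48)
        a = rng.normal(size=15)
        b = rng.normal(size=15)
        base = mann_whitney_u(a, b)
        shifted = mann_whitney_u(a + 100.0, b)  # a now strictly above b
        assert shifted.u_statistic <= base.u_statistic


class TestComparePausing:
    @staticmethod
    def build(n_per_group=20, ratio_a=5.0, ratio_b=1.5, seed=0):
        rng = np.random.default_rng(seed)
        ann = GenomeAnnotation()
        intervals = []
        pos = 2000
        groups = {"a": [], "b": []}
        for label, ratio in (("a", ratio_a), ("b", ratio_b)):
            for i in range(n_per_group):
                gid = f"{label}{i}"
                length = int(rng.integers(2000, 6000))
                gene = GeneModel(gid, "chr1", pos, pos + length, "+")
                ann.add(gene)
                groups[label].append(gid)
                b_level = float(rng.uniform(0.5, 3.0))
                jitter = float(rng.uniform(0.9, 1.1))
                intervals.append(("chr1", pos - 50, pos + 50, ratio * b_level * jitter))
                intervals.append(("chr1", pos + 300, pos + length - 100, b_level))
                pos += length + 1000
        return SignalTrack.from_intervals(intervals), ann, groups

    def test_planted_ratio_difference_detected(self):
        track, ann, groups = self.build()
        res = compare_pausing(track, ann, groups["a"], groups["b"])
        assert res["median"]["repressed"] > res["median"]["activated"]
        assert res["comparison"].p_two_sided < 0.01
        assert res["higher_pausing"] == "repressed"

    def test_identical_groups_give_p_near_one(self):
        track, ann, groups = self.build(ratio_a=2.0, ratio_b=2.0)
        res = compare_pausing(track, ann, groups["a"], groups["a"],
                              check_disjoint=False)
        assert res["comparison"].p_two_sided == pytest.approx(1.0)

    def test_overlapping_groups_rejected_by_default(self):
        track, ann, groups = self.build(n_per_group=3)
        with pytest.raises(ValueError, match="disjoint"):
            compare_pausing(track, ann, groups["a"], groups["a"])

    def test_fully_excluded_group_is_informative_error(self):
        ann = GenomeAnnotation()
        ann.add(GeneModel("short1", "chr1", 1000, 1300, "+"))
        ann.add(GeneModel("long1", "chr1", 5000, 10_000, "+"))
        track = SignalTrack.from_intervals([("chr1", 0, 20_000, 1.0)])
        with pytest.raises(ValueError, match="no genes with a computable"):
            compare_pausing(track, ann, ["short1"], ["long1"])

    def test_exclusions_are_tallied(self):
        ann = GenomeAnnotation()
        ann.add(GeneModel("ok1", "chr1", 1000, 5000, "+"))
        ann.add(GeneModel("short1", "chr1", 8000, 8350, "+"))
        ann.add(GeneModel("ok2", "chr1", 20_000, 26_000, "+"))
        track = SignalTrack.from_intervals([("chr1", 0, 30_000, 1.0)])
        res = compare_pausing(track, ann, ["ok1", "short1"], ["ok2"], label_a="a", label_b="b")
        assert res["excluded"]["a"] == {STATUS_SHORT: 1}
        assert res["n_tested"] == {"a": 1, "b": 1}

    def test_scaling_track_leaves_p_unchanged(self):
        track, ann, groups = self.build(n_per_group=10)
        res1 = compare_pausing(track, ann, groups["a"], groups["b"])
        dense_like = [(c, int(s), int(e), 3.0 * v) for c, s, e, v in track.iter_intervals()]
        res2 = compare_pausing(SignalTrack.from_intervals(dense_like), ann,
                               groups["a"], groups["b"])
        assert res2.get("comparison").p_two_sided == pytest.approx(res1["comparison"].p_two_sided)
        assert res2["comparison"].u_statistic == res1["comparison"].u_statistic


def test_pausing_table_reports_all_statuses():
    ann = GenomeAnnotation()
    ann.add(GeneModel("ok", "chr1", 1000, 5000, "+"))
    ann.add(GeneModel("short", "chr1", 8000, 8350, "+"))
    ann.add(GeneModel("silent", "chr1", 20_000, 26_000, "+"))
    track = SignalTrack.from_intervals([("chr1", 0, 10_000, 1.0)])
    tab = pausing_table(track, ann)
    assert tab.set_index("gene_id")["status"].to_dict() == {
        "ok": STATUS_OK, "short": STATUS_SHORT, "silent": STATUS_ZERO_BODY,
    }
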