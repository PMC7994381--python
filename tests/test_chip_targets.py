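import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nbscreen import chip_targets as ct
from nbscreen import diffexpr
from nbscreen.io_formats import GeneModel, GenomicInterval, PeakRecord


def gene(gene_id, start, end, strand="+", chrom="chrT"):
    return GeneModel(gene_id, GenomicInterval(chrom, start, end, strand))


def peak(start, end, fe=10.0, chrom="chrT", name="p"):
    return PeakRecord(GenomicInterval(chrom, start, end), name, fe)


class TestPromoterWindows:
    def test_plus_strand_window(self):
        (w,) = ct.promoter_windows([gene("A", 5000, 7000, "+")])
        assert (w.interval.start, w.interval.end) == (4000, 5100)

    def test_minus_strand_window_flipped(self):
        # TSS at end-1 = 4999; upstream extends to larger coordinates
        (w,) = ct.promoter_windows([gene("A", 3000, 5000, "-")])
        assert (w.interval.start, w.interval.end) == (4899, 5999)

    def test_clipped_at_chromosome_start(self):
        (w,) = ct.promoter_windows([gene("A", 300, 2300, "+")])
        assert (w.interval.start, w.interval.end) == (0, 400)

    def test_window_width_is_1100(self):
        for strand in "+-":
            (w,) = ct.promoter_windows([gene("A", 50_000, 52_000, strand)])
            assert len(w.interval) == 1100


class TestAssignPeaks:
    WINDOWS = ct.promoter_windows([gene("A", 5000, 7000, "+")])

    def test_overlapping_peak_assigned(self):
        asn = ct.assign_peaks([peak(4500, 4600)], self.WINDOWS)
        assert len(asn["A"]) == 1

    def test_half_open_abutment_not_assigned(self):
        asn = ct.assign_peaks([peak(5100, 5200)], self.WINDOWS)
        assert asn["A"] == []

    def test_peak_spanning_two_promoters_assigned_to_both(self):
        windows = ct.promoter_windows(
            [gene("A", 5000, 7000, "+"), gene("B", 6000, 8000, "+")]
        )
        asn = ct.assign_peaks([peak(4900, 5300)], windows)
        assert len(asn["A"]) == 1 and len(asn["B"]) == 1

    def test_chromosome_name_mismatch_rejected(self):
        with pytest.raises(ValueError, match="chromosome names"):
            ct.assign_peaks([peak(4500, 4600, chrom="17")], self.WINDOWS)

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(0)
        genes = [
            gene(f"G{i}", s, s + 2000, "+-"[i % 2])
            for i, s in enumerate(sorted(rng.integers(2000, 5_000_000, size=200)))
        ]
        windows = ct.promoter_windows(genes)
        peaks = [
            peak(int(s), int(s + rng.integers(50, 3000)), name=f"p{j}")
            for j, s in enumerate(rng.integers(0, 5_000_000, size=1000))
        ]
        asn = ct.assign_peaks(peaks, windows)
        for w in windows:
            expected = [
                p
                for p in peaks
                if p.interval.start < w.interval.end and w.interval.start < p.interval.end
            ]
            assert asn[w.gene_id] == expected


class TestOccupancyMatrix:
    @staticmethod
    def assignments(**overrides):
        base = {m: {"A": [peak(4500, 4800)]} for m in ct.MARKS}
        base["alyref"] = {"A": [peak(4500, 4800, fe=7.0)]}
        base.update(overrides)
        return base

    def test_full_row_all_true(self):
        mat = ct.occupancy_matrix(self.assignments())
        assert mat.loc["A", list(ct.MARKS)].all()
        assert mat.loc["A", "alyref_fe"] == 7.0

    def test_missing_mark_false(self):
        mat = ct.occupancy_matrix(self.assignments(h3k4me3={"A": []}))
        assert not mat.loc["A", "h3k4me3"]

    def test_max_fe_over_assigned_peaks(self):
        asn = self.assignments(
            alyref={"A": [peak(4500, 4800, fe=3.0), peak(4900, 5000, fe=7.0)]}
        )
        assert ct.occupancy_matrix(asn).loc["A", "alyref_fe"] == 7.0

    def test_missing_mark_file_rejected(self):
        asn = self.assignments()
        del asn["mycn"]
        with pytest.raises(ValueError, match="mycn"):
            ct.occupancy_matrix(asn)


class TestFEFilter:
    @staticmethod
    def matrix(fe_values):
        genes = [f"g{i}" for i in range(len(fe_values))]
        df = pd.DataFrame(
            {m: True for m in ct.MARKS},
            index=pd.Index(genes, name="gene_id"),
        )
        df["alyref_fe"] = fe_values
        return df

    def test_boundary_exactly_five_fails(self):
        ranked = ct.fe_filter(self.matrix([5.0, 6.15987]))
        assert "g0" not in ranked.index and "g1" in ranked.index

    def test_rank_by_descending_fe(self):
        fe = [9.0, 8.0, 7.0, 6.2, 6.1, 6.15987]
        ranked = ct.fe_filter(self.matrix(fe))
        assert ranked.index.tolist() == ["g0", "g1", "g2", "g3", "g5", "g4"]
        assert ranked.loc["g5", "fe_rank"] == 5

    def test_inserting_lower_fe_preserves_relative_order(self):
        a = ct.fe_filter(self.matrix([9.0, 7.0, 8.0]))
        b = ct.fe_filter(self.matrix([9.0, 7.0, 8.0, 5.5]))
        order_a = [g for g in a.index]
        order_b = [g for g in b.index if g != "g3"]
        assert order_a == order_b

    def test_ties_broken_by_gene_id(self):
        ranked = ct.fe_filter(self.matrix([6.0, 6.0]))
        assert ranked.index.tolist() == ["g0", "g1"]


class TestEboxScan:
    def test_canonical_hit(self):
        hits = ct.ebox_scan("CACGTG")
        assert len(hits) == 1 and hits[0].kind == "canonical" and hits[0].position == 0

    def test_non_canonical_hits(self):
        for word in ("CAGCTG", "CACCTG"):
            hits = ct.ebox_scan(word)
            assert len(hits) == 1 and hits[0].kind == "non_canonical"

    def test_n_windows_never_match(self):
        assert ct.ebox_scan("CANNTG") == []

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError):
            ct.ebox_scan("CACGTQ")

    def test_constructed_sequence_counts(self):
        seq = "CACGTG" + "AAAA" + "CAGCTG" + "TTTT" + "CACGTG" + "CATATG" + "CAAATG"
        hits = ct.ebox_scan(seq)
        kinds = [h.kind for h in hits]
        assert kinds.count("canonical") == 2
        assert kinds.count("non_canonical") == 3

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_exhaustive_window_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGTN"), size=200, p=[0.3, 0.3, 0.2, 0.15, 0.05]))
        hits = {(h.position, h.kind) for h in ct.ebox_scan(seq)}
        expected = set()
        for i in range(len(seq) - 5):
            w = seq[i : i + 6]
            if w[:2] == "CA" and w[4:] == "TG" and "N" not in w:
                expected.add((i, "canonical" if w == "CACGTG" else "non_canonical"))
        assert hits == expected


class TestChipTargetScreen:
    def test_planted_target_is_sole_final_candidate(self, chip_fixture):
        fx = chip_fixture
        windows = ct.promoter_windows(fx.genes)
        asn = {m: ct.assign_peaks(fx.peaks[m], windows) for m in ct.MARKS}
        mat = ct.occupancy_matrix(asn)
        expr = diffexpr.log2_normalized(fx.counts)
        res = ct.chip_target_screen(mat, expr, fx.clinical, fx.gene_set)
        final = res.index[res["final_pass"]].tolist()
        assert final == [fx.truth.chip_target]

    def test_gene_absent_from_gene_set_fails(self, chip_fixture):
        fx = chip_fixture
        windows = ct.promoter_windows(fx.genes)
        asn = {m: ct.assign_peaks(fx.peaks[m], windows) for m in ct.MARKS}
        mat = ct.occupancy_matrix(asn)
        expr = diffexpr.log2_normalized(fx.counts)
        res = ct.chip_target_screen(
            mat, expr, fx.clinical, [g for g in fx.gene_set if g != fx.truth.chip_target]
        )
        row = res.loc[fx.truth.chip_target]
        assert (
            row[["co_occupancy", "fe_pass", "survival_pass", "mycn_corr_pass"]].all()
            and not row["in_gene_set"]
            and not row["final_pass"]
        )

    def test_empty_gene_set_warns_and_yields_empty_list(self, chip_fixture):
        fx = chip_fixture
        windows = ct.promoter_windows(fx.genes[:20])
        asn = {m: ct.assign_peaks(fx.peaks[m], windows) for m in ct.MARKS}
        mat = ct.occupancy_matrix(asn)
        expr = diffexpr.log2_normalized(fx.counts)
        with pytest.warns(UserWarning, match="empty gene set"):
            res = ct.chip_target_screen(mat, expr, fx.clinical, [])
        assert not res["final_pass"].any()
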