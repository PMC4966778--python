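"""Tests of peak input, strand counting, classification and output."""
import numpy as np
import pytest
from scipy.stats import chi2_contingency

from dismiss.alignment_io import FirstMateAlignment
from dismiss.genomic_features import GenomicInterval, Strand
from dismiss.peak_processing import (
    classify_all,
    count_strands,
    read_peaks,
    width_bias_test,
    write_stranded_tracks,
)
from dismiss.strand_model import StrandClass, StrandedPeakCount

from _oracles import pearson_chi2


def fm(seqname, start, end, strand=Strand.PLUS):
    return FirstMateAlignment(seqname, start, end, strand, mapq=60)


class TestReadPeaks:
    def test_narrowpeak_line(self, tmp_path):
        f = tmp_path / "p.narrowPeak"
        f.write_text("chr1\t100\t500\tp1\t0\t.\t5.2\t10.1\t8.3\t200\n")
        (peak,) = read_peaks(f)
        assert peak.name == "p1"
        assert (peak.interval.start, peak.interval.end) == (100, 500)
        assert peak.interval.strand is Strand.BOTH

    def test_bed3_autonames(self, tmp_path):
        f = tmp_path / "p.bed"
        f.write_text("scaf1\t0\t250\nscaf1\t300\t400\n")
        peaks = read_peaks(f)
        assert [p.name for p in peaks] == ["peak_1", "peak_2"]

    def test_empty_interval_reports_line(self, tmp_path):
        f = tmp_path / "bad.bed"
        f.write_text("chr1\t10\t20\nchr1\t30\t30\n")
        with pytest.raises(ValueError, match="line 2"):
            read_peaks(f)


class TestCountStrands:
    def _peak(self, name, start, end, seqname="chr1"):
        from dismiss.peak_processing import PeakRegion

        return PeakRegion(GenomicInterval(seqname, start, end), name)

    def test_direct_tally(self):
        peaks = [self._peak("p", 100, 200)]
        records = [fm("chr1", 150, 190)] * 3 + [
            fm("chr1", 120, 180, Strand.MINUS)
        ] * 2
        (c,) = count_strands(peaks, records)
        assert (c.y_plus, c.y_minus) == (3, 2)

    def test_no_reads_gives_zero(self):
        (c,) = count_strands([self._peak("p", 0, 100)], [])
        assert (c.y_plus, c.y_minus) == (0, 0)

    def test_matches_naive_all_pairs_scan(self):
        rng = np.random.default_rng(3)
        peaks = []
        for i in range(50):
            s = int(rng.integers(0, 9000))
            peaks.append(self._peak(f"p{i}", s, s + int(rng.integers(50, 500))))
        records = []
        for _ in range(5000):
            s = int(rng.integers(0, 9500))
            strand = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
            records.append(fm("chr1", s, s + 50, strand))
        counts = count_strands(peaks, records)
        for peak, c in zip(peaks, counts):
            iv = peak.interval
            naive_p = sum(
                1
                for r in records
                if r.strand is Strand.PLUS and r.start < iv.end and iv.start < r.end
            )
            naive_m = sum(
                1
                for r in records
                if r.strand is Strand.MINUS and r.start < iv.end and iv.start < r.end
            )
            assert (c.y_plus, c.y_minus) == (naive_p, naive_m)

    def test_counting_invariant_to_record_order(self):
        peaks = [self._peak("p", 100, 300)]
        records = [fm("chr1", 100 + 10 * i, 200 + 10 * i) for i in range(10)]
        a = count_strands(peaks, records)
        b = count_strands(peaks, records[::-1])
        assert (a[0].y_plus, a[0].y_minus) == (b[0].y_plus, b[0].y_minus)

    def test_strand_swap_flips_tallies(self):
        peaks = [self._peak("p", 0, 1000)]
        records = [fm("chr1", 10, 60)] * 7 + [fm("chr1", 10, 60, Strand.MINUS)] * 3
        swapped = [
            FirstMateAlignment(r.seqname, r.start, r.end, r.strand.opposite, r.mapq)
            for r in records
        ]
        (a,) = count_strands(peaks, records)
        (b,) = count_strands(peaks, swapped)
        assert (a.y_plus, a.y_minus) == (b.y_minus, b.y_plus)

    def test_missing_seqname_warns_and_zeroes(self, sim_bundle):
        _, bundle = sim_bundle
        peaks = [self._peak("p", 0, 100, seqname="chrZ")]
        with pytest.warns(UserWarning, match="chrZ"):
            (c,) = count_strands(peaks, str(bundle.alignments_bam))
        assert (c.y_plus, c.y_minus) == (0, 0)

    def test_bam_route_matches_record_route(self, sim_bundle):
        from dismiss.alignment_io import load_first_mates

        _, bundle = sim_bundle
        peaks = read_peaks(bundle.peaks_bed)[:30]
        via_bam = count_strands(peaks, str(bundle.alignments_bam))
        via_records = count_strands(peaks, list(load_first_mates(bundle.alignments_bam)))
        for a, b in zip(via_bam, via_records):
            assert (a.y_plus, a.y_minus) == (b.y_plus, b.y_minus)


class TestClassifyAll:
    def test_class_partition_and_worked_example(self):
        counts = [
            StrandedPeakCount("a", 60, 40),
            StrandedPeakCount("b", 100, 10),
            StrandedPeakCount("c", 0, 0),
            StrandedPeakCount("d", 5, 80),
        ]
        summary = classify_all(counts)
        assert summary.peaks[0].result.strand_class is StrandClass.BOTH
        total = (
            summary.n_plus + summary.n_minus + summary.n_both + summary.n_unclassified
        )
        assert total == len(counts)
        assert summary.n_unclassified == 1
        assert summary.single_stranded_fraction == pytest.approx(2 / 3)

    def test_all_zero_counts_unclassified(self):
        summary = classify_all([StrandedPeakCount(f"p{i}", 0, 0) for i in range(5)])
        assert summary.n_unclassified == 5

    def test_recovers_planted_single_strand_fraction(self):
        rng = np.random.default_rng(9)
        counts = []
        for i in range(300):
            if i < 240:  # 80 % asymmetric at high depth
                rep = int(rng.poisson(60))
                off = int(rng.poisson(1))
                a, b = (rep, off) if i % 2 == 0 else (off, rep)
            else:
                a, b = int(rng.poisson(60)), int(rng.poisson(60))
            counts.append(StrandedPeakCount(f"p{i}", a, b))
        summary = classify_all(counts)
        assert summary.single_stranded_fraction == pytest.approx(0.8, abs=0.05)


class TestWidthBias:
    def _classified(self, widths_classes):
        counts_map = {"PLUS": (50, 0), "MINUS": (0, 50), "BOTH": (30, 30)}
        out = []
        for i, (w, cls) in enumerate(widths_classes):
            c = StrandedPeakCount(
                f"p{i}",
                *counts_map[cls],
                interval=GenomicInterval("chr1", 1000 * i, 1000 * i + w),
            )
            out.extend(classify_all([c]).peaks)
        return out

    def test_identical_proportions_give_p_near_one(self):
        rows = []
        for w in (100, 500, 900):
            rows += [(w + i, "PLUS") for i in range(10)]
            rows += [(w + i, "MINUS") for i in range(10)]
            rows += [(w + i, "BOTH") for i in range(10)]
        res = width_bias_test(self._classified(rows), quantile_bounds=(1 / 3, 2 / 3))
        assert res.p_value > 0.9

    def test_statistic_matches_textbook_formula(self):
        table = [[20, 30, 10], [15, 25, 20], [5, 10, 15]]
        stat, _, _, _ = chi2_contingency(np.array(table), correction=False)
        assert stat == pytest.approx(pearson_chi2(table))

    def test_single_class_degenerates_to_zero(self):
        rows = [(100 + i, "PLUS") for i in range(30)]
        res = width_bias_test(self._classified(rows))
        assert res.statistic == 0.0 and res.p_value == 1.0


class TestWriteTracks:
    def _classified_with_reads(self):
        # p2 gets 15 minus reads and none plus: LS sets {0..2} vs {9..15}
        # are disjoint, so the peak is MINUS (0 vs 5 would still intersect)
        records = (
            [fm("chr1", 120, 170)] * 2
            + [fm("chr1", 150, 200)] * 1
            + [fm("chr1", 400, 450, Strand.MINUS)] * 15
        )
        from dismiss.peak_processing import PeakRegion

        peaks = [
            PeakRegion(GenomicInterval("chr1", 100, 250), "p1"),
            PeakRegion(GenomicInterval("chr1", 380, 470), "p2"),
        ]
        counts = count_strands(peaks, records)
        return classify_all(counts, peaks=peaks).peaks, records

    def test_bed_round_trip_and_strand_chars(self, tmp_path):
        classified, records = self._classified_with_reads()
        paths = write_stranded_tracks(classified, tmp_path / "out", alignments=records)
        reread = read_peaks(paths["peaks_bed"])
        assert [(p.interval.start, p.interval.end) for p in reread] == [
            (100, 250),
            (380, 470),
        ]
        lines = paths["peaks_bed"].read_text().splitlines()
        assert lines[1].split("\t")[5] == "-"  # MINUS-class peak

    def test_bedgraph_matches_per_base_pileup(self, tmp_path):
        classified, records = self._classified_with_reads()
        paths = write_stranded_tracks(classified, tmp_path / "out", alignments=records)
        depth = np.zeros(1000, dtype=int)
        for r in records:
            if r.strand is Strand.PLUS:
                depth[r.start : r.end] += 1
        from_track = np.zeros(1000, dtype=int)
        for line in paths["plus_bedgraph"].read_text().splitlines():
            seq, start, end, value = line.split("\t")
            from_track[int(start) : int(end)] = int(value)
        assert np.array_equal(depth, from_track)

    def test_empty_input_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_stranded_tracks([], tmp_path / "out")
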