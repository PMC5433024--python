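"""Window aggregation, Poisson statistics, Watson/Crick merging and the
peak-level filters, checked against exhaustive/brute-force oracles."""

import math
import random

import numpy as np
import pytest

from guidepeak.ingest import UniqueCleavageEvent
from guidepeak.peakcall import (MergedPeak, PeakCallConfig, StrandPeak,
                                aggregate_windows, call_strand_peaks,
                                filter_library_support, merge_watson_crick,
                                peak_statistics, subtract_control_peaks)


def ev(pos, strand="+", library="forward", chrom="c"):
    return UniqueCleavageEvent(chrom=chrom, integration_pos=pos, strand=strand,
                               library=library, support=1)


def events_at(pos, n, strand="+", chrom="c"):
    return [ev(pos, strand, "forward" if i % 2 == 0 else "reverse", chrom)
            for i in range(n)]


CFG = PeakCallConfig()


class TestAggregateWindows:
    def test_five_colocated_events_make_one_peak(self):
        peaks = aggregate_windows(events_at(500, 5), "c", "+", CFG)
        assert len(peaks) == 1
        assert peaks[0].height == 5
        assert peaks[0].window_start <= 500 < peaks[0].window_end

    def test_four_events_below_threshold_no_peak(self):
        assert aggregate_windows(events_at(500, 4), "c", "+", CFG) == []

    def test_no_events_no_peaks(self):
        assert aggregate_windows([], "c", "+", CFG) == []

    def test_run_reduction_keeps_leftmost_max_window(self):
        # 5 events at 100 and 5 at 105: one run, best window covers all 10
        evs = events_at(100, 5) + events_at(105, 5)
        peaks = aggregate_windows(evs, "c", "+", CFG)
        assert len(peaks) == 1
        assert peaks[0].height == 10

    def test_matches_exhaustive_all_window_scanner(self):
        """Random event tracks agree with a scan over every window start."""
        rng = random.Random(20)
        for trial in range(10):
            positions = sorted(rng.randrange(0, 2000) for _ in
                               range(rng.randint(0, 120)))
            evs = [ev(p) for p in positions]
            got = aggregate_windows(evs, "c", "+", CFG)
            w, t = CFG.window_size, CFG.min_reads
            pos = np.array(positions)
            qual = []
            for s in range(-w, 2001):
                h = int(((pos >= s) & (pos < s + w)).sum())
                if h >= t:
                    qual.append((s, h))
            expected = []
            i = 0
            while i < len(qual):
                j = i
                while j + 1 < len(qual) and qual[j + 1][0] < qual[j][0] + w:
                    j += 1
                run = qual[i:j + 1]
                best = max(run, key=lambda x: x[1])
                first_best = next(x for x in run if x[1] == best[1])
                expected.append(first_best)
                i = j + 1
            assert [(p.window_start, p.height) for p in got] == expected

    def test_libraries_unioned_over_window(self):
        evs = [ev(100, library="forward")] * 3 + [ev(101, library="reverse")] * 2
        peaks = aggregate_windows(evs, "c", "+", CFG)
        assert peaks[0].libraries == {"forward", "reverse"}


class TestPeakStatistics:
    def _peak(self, height, summit=500):
        w = CFG.window_size
        return StrandPeak(chrom="c", window_start=summit - w // 2 + 1,
                          window_end=summit - w // 2 + 1 + w, summit=summit,
                          strand="+", height=height)

    def test_tail_matches_direct_pmf_summation(self):
        """P(X >= h) from scipy agrees with explicit pmf summation."""
        for lam in (0.02, 0.5, 5.0, 50.0):
            for h in (1, 3, 10, 100):
                peak = self._peak(h)
                evs = events_at(500, h) + events_at(900, max(0, int(lam * 250) - h))
                p, _ = peak_statistics(peak, evs, CFG)
                b = len(evs)
                lam_eff = b * CFG.window_size / CFG.background_window
                direct = 1.0 - sum(math.exp(-lam_eff) * lam_eff ** i / math.factorial(i)
                                   for i in range(h))
                assert p == pytest.approx(max(direct, 0.0), abs=1e-12)

    def test_zero_height_pvalue_one(self):
        p, _ = peak_statistics(self._peak(0), [], CFG)
        assert p == 1.0

    def test_doubling_background_window_weakly_decreases_pvalue(self):
        evs = events_at(500, 5) + events_at(1500, 10)
        peak = self._peak(5)
        p1, _ = peak_statistics(peak, evs, CFG)
        cfg2 = PeakCallConfig(background_window=10_000)
        p2, _ = peak_statistics(peak, evs, cfg2)
        assert p2 <= p1 + 1e-15

    def test_snratio_uses_floor_on_lambda(self):
        # isolated peak: b = height, lambda small but SNratio capped by w/B floor
        evs = events_at(500, 5)
        _, sn = peak_statistics(self._peak(5), evs, CFG)
        lam = 5 * CFG.window_size / CFG.background_window
        assert sn == pytest.approx(5 / max(lam, CFG.window_size / CFG.background_window))

    def test_background_smaller_than_window_rejected(self):
        with pytest.raises(ValueError):
            PeakCallConfig(background_window=10)


class TestMergeWatsonCrick:
    def _speak(self, summit, strand, height=5, chrom="c"):
        w = CFG.window_size
        return StrandPeak(chrom=chrom, window_start=summit - (w - 1) // 2,
                          window_end=summit - (w - 1) // 2 + w, summit=summit,
                          strand=strand, height=height, p_value=1e-9, sn_ratio=99,
                          libraries=frozenset({"forward", "reverse"}))

    def test_correct_polarity_within_distance_merges(self):
        merged = merge_watson_crick([self._speak(100, "-"), self._speak(120, "+")], CFG)
        assert len(merged) == 1
        assert merged[0].score == 10

    def test_wrong_polarity_not_merged(self):
        merged = merge_watson_crick([self._speak(100, "+"), self._speak(120, "-")], CFG)
        assert merged == []

    def test_distance_beyond_threshold_not_merged(self):
        merged = merge_watson_crick([self._speak(100, "-"), self._speak(180, "+")], CFG)
        assert merged == []

    def test_exact_threshold_distance_merges(self):
        merged = merge_watson_crick([self._speak(100, "-"), self._speak(140, "+")], CFG)
        assert len(merged) == 1

    def test_each_peak_used_once_greedy(self):
        peaks = [self._speak(100, "-"), self._speak(110, "-"), self._speak(120, "+")]
        merged = merge_watson_crick(peaks, CFG)
        assert len(merged) == 1
        assert merged[0].minus_peak.summit == 100  # leftmost Crick takes it

    def test_score_conserves_strand_heights(self):
        rng = random.Random(21)
        peaks = []
        for i in range(20):
            s = 1000 * i
            peaks.append(self._speak(s, "-", rng.randint(5, 30)))
            peaks.append(self._speak(s + rng.randint(1, 40), "+", rng.randint(5, 30)))
        for m in merge_watson_crick(peaks, CFG):
            assert m.score == m.minus_peak.height + m.plus_peak.height

    def test_require_pair_false_emits_singletons(self):
        cfg = PeakCallConfig(require_pair=False)
        merged = merge_watson_crick([self._speak(100, "+")], cfg)
        assert len(merged) == 1 and merged[0].minus_peak is None


class TestFilters:
    def _merged(self, libs, start=100, end=140, chrom="c"):
        return MergedPeak(chrom=chrom, start=start, end=end, minus_peak=None,
                          plus_peak=None, score=10, libraries=frozenset(libs))

    def test_single_library_peak_dropped(self):
        both = self._merged({"forward", "reverse"})
        fwd_only = self._merged({"forward"}, start=500, end=540)
        kept = filter_library_support([both, fwd_only], CFG,
                                      libraries_present={"forward", "reverse"})
        assert kept == [both]

    def test_single_library_run_passes_through(self):
        fwd_only = self._merged({"forward"})
        with pytest.warns(UserWarning):
            kept = filter_library_support([fwd_only], CFG,
                                          libraries_present={"forward"})
        assert kept == [fwd_only]

    def test_control_subtraction_overlap_and_disjoint(self):
        sample = [self._merged({"forward", "reverse"}, 100, 140)]
        kept, removed = subtract_control_peaks(sample, [self._merged({"forward"}, 130, 160)])
        assert kept == [] and removed == sample
        kept, removed = subtract_control_peaks(sample, [self._merged({"forward"}, 150, 160)])
        assert kept == sample and removed == []
        kept, removed = subtract_control_peaks(sample, [])
        assert kept == sample

    def test_tightening_filters_never_increases_peak_count(self):
        rng = random.Random(22)
        evs = []
        for i in range(12):
            base = 2000 * i
            evs += events_at(base, rng.randint(3, 9), "-")
            evs += events_at(base + rng.randint(5, 30), rng.randint(3, 9), "+")
        base_cfg = PeakCallConfig()
        n_base = len(call_strand_peaks(evs, base_cfg))
        assert len(call_strand_peaks(evs, PeakCallConfig(min_reads=7))) <= n_base
        assert len(call_strand_peaks(evs, PeakCallConfig(p_cutoff=1e-12))) <= n_base
        assert len(call_strand_peaks(evs, PeakCallConfig(snratio_cutoff=1e6))) <= n_base
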