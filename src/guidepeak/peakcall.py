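"""Strand-specific peak calling on unique cleavage events.

Unique dsODN integration events from both libraries are aggregated per
strand with a sliding window (default 20 bp, step 1). Windows holding at
least ``min_reads`` events qualify; each maximal run of overlapping
qualifying windows is reduced to its best window (largest event sum,
leftmost on ties), whose centre is the peak summit. Each peak gets a
Poisson tail p-value and a signal-to-noise ratio against a local
background (default 5 kb around the summit, the peak's own window
included). Because of how the two libraries prime off the integrated
dsODN, a genuine cut shows a minus-strand (Crick) peak just upstream of
a plus-strand (Watson) peak; peaks with that polarity whose summits lie
within ``merge_distance`` (default 40 bp) are merged, the merged score
being the sum of the strand heights. Merged peaks supported by only one
library, or overlapping a nuclease-free control, can then be filtered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import poisson

from .ingest import UniqueCleavageEvent


@dataclass(frozen=True)
class PeakCallConfig:
    window_size: int = 20
    min_reads: int = 5
    background_window: int = 5000
    p_cutoff: float = 0.05
    snratio_cutoff: float | None = None
    merge_distance: int = 40
    require_both_libraries: bool = True
    require_pair: bool = True
    adjust_p: bool = False            # optional Benjamini-Hochberg across strand peaks
    background_excludes_peak: bool = False

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.background_window < self.window_size:
            raise ValueError("background_window must be >= window_size")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if self.merge_distance < 0:
            raise ValueError("merge_distance must be >= 0")


@dataclass(frozen=True)
class StrandPeak:
    chrom: str
    window_start: int
    window_end: int
    summit: int
    strand: str
    height: int
    p_value: float = float("nan")
    sn_ratio: float = float("nan")
    libraries: frozenset = frozenset()


@dataclass(frozen=True)
class MergedPeak:
    chrom: str
    start: int
    end: int
    minus_peak: StrandPeak | None
    plus_peak: StrandPeak | None
    score: int
    libraries: frozenset


def aggregate_windows(events: Sequence[UniqueCleavageEvent], chrom: str, strand: str,
                      cfg: PeakCallConfig) -> list[StrandPeak]:
    """Candidate strand peaks for one chromosome/strand.

    Slides a ``window_size`` window at step 1 over the event positions;
    qualifying windows (event sum >= ``min_reads``) are chained into
    maximal overlapping runs and each run yields the single window with
    the largest sum (leftmost on ties). Summit = floor((start+end-1)/2).
    """
    w = cfg.window_size
    sel = [e for e in events if e.chrom == chrom and e.strand == strand]
    if not sel:
        return []
    pos = np.array(sorted(e.integration_pos for e in sel))
    # only window starts that cover at least one event can qualify
    starts = np.unique(np.concatenate([pos - k for k in range(w)]))
    counts = np.searchsorted(pos, starts + w, side="left") - np.searchsorted(pos, starts, side="left")
    qual = starts[counts >= cfg.min_reads]
    qcounts = counts[counts >= cfg.min_reads]
    if qual.size == 0:
        return []

    peaks: list[StrandPeak] = []
    run_start = 0
    for i in range(1, qual.size + 1):
        if i == qual.size or qual[i] >= qual[i - 1] + w:
            seg_starts = qual[run_start:i]
            seg_counts = qcounts[run_start:i]
            best = int(np.argmax(seg_counts))  # argmax returns first (leftmost) max
            s = int(seg_starts[best])
            h = int(seg_counts[best])
            summit = (2 * s + w - 1) // 2
            libs = frozenset(e.library for e in sel
                             if s <= e.integration_pos < s + w)
            peaks.append(StrandPeak(chrom=chrom, window_start=s, window_end=s + w,
                                    summit=summit, strand=strand, height=h,
                                    libraries=libs))
            run_start = i
    return peaks


def peak_statistics(peak: StrandPeak, strand_events: Sequence[UniqueCleavageEvent],
                    cfg: PeakCallConfig) -> tuple[float, float]:
    """Poisson tail p-value and SNratio for one strand peak.

    Background count b = same-strand events within +/- B/2 of the summit
    (the peak's own window included unless configured otherwise);
    expected height under noise lambda = b*w/B; p = P(X >= height) for
    X ~ Poisson(lambda); SNratio = height / max(lambda, w/B).
    """
    w, B = cfg.window_size, cfg.background_window
    pos = np.array(sorted(e.integration_pos for e in strand_events
                          if e.chrom == peak.chrom and e.strand == peak.strand))
    lo, hi = peak.summit - B // 2, peak.summit + B // 2
    b = int(np.searchsorted(pos, hi, side="right") - np.searchsorted(pos, lo, side="left"))
    if cfg.background_excludes_peak:
        inside = int(np.searchsorted(pos, peak.window_end, side="left")
                     - np.searchsorted(pos, peak.window_start, side="left"))
        lam = (b - inside) * w / max(B - w, 1)
    else:
        lam = b * w / B
    p_value = float(poisson.sf(peak.height - 1, lam)) if peak.height > 0 else 1.0
    sn_ratio = peak.height / max(lam, w / B)
    return p_value, sn_ratio


def call_strand_peaks(events: Sequence[UniqueCleavageEvent], cfg: PeakCallConfig,
                      ) -> list[StrandPeak]:
    """Aggregate + statistics + p/SN filters, over all chromosomes/strands."""
    keys = sorted({(e.chrom, e.strand) for e in events})
    peaks: list[StrandPeak] = []
    for chrom, strand in keys:
        for pk in aggregate_windows(events, chrom, strand, cfg):
            p, sn = peak_statistics(pk, events, cfg)
            peaks.append(replace(pk, p_value=p, sn_ratio=sn))
    if cfg.adjust_p and peaks:
        peaks = _bh_adjust(peaks)
    kept = [p for p in peaks if p.p_value <= cfg.p_cutoff]
    if cfg.snratio_cutoff is not None:
        kept = [p for p in kept if p.sn_ratio >= cfg.snratio_cutoff]
    return kept


def _bh_adjust(peaks: list[StrandPeak]) -> list[StrandPeak]:
    m = len(peaks)
    order = np.argsort([p.p_value for p in peaks])
    adj = np.empty(m)
    running = 1.0
    for rank_rev, idx in enumerate(order[::-1]):
        rank = m - rank_rev
        running = min(running, peaks[idx].p_value * m / rank)
        adj[idx] = running
    return [replace(p, p_value=float(adj[i])) for i, p in enumerate(peaks)]


def merge_watson_crick(strand_peaks: Sequence[StrandPeak], cfg: PeakCallConfig,
                       ) -> list[MergedPeak]:
    """Pair Crick (minus) peaks with downstream Watson (plus) peaks.

    Greedy left-to-right: each minus peak takes the nearest unused plus
    peak strictly downstream (plus summit > minus summit) within
    ``merge_distance``. With ``require_pair`` unpaired peaks are dropped,
    otherwise they are emitted as single-strand merged peaks.
    """
    minus = sorted((p for p in strand_peaks if p.strand == "-"),
                   key=lambda p: (p.chrom, p.summit))
    plus = sorted((p for p in strand_peaks if p.strand == "+"),
                  key=lambda p: (p.chrom, p.summit))
    used_plus: set[int] = set()
    merged: list[MergedPeak] = []
    for mp in minus:
        best = None
        for j, pp in enumerate(plus):
            if j in used_plus or pp.chrom != mp.chrom:
                continue
            d = pp.summit - mp.summit
            if 0 < d <= cfg.merge_distance:
                if best is None or d < plus[best].summit - mp.summit:
                    best = j
        if best is not None:
            used_plus.add(best)
            pp = plus[best]
            merged.append(MergedPeak(
                chrom=mp.chrom, start=min(mp.window_start, pp.window_start),
                end=max(mp.window_end, pp.window_end), minus_peak=mp, plus_peak=pp,
                score=mp.height + pp.height, libraries=mp.libraries | pp.libraries))
        elif not cfg.require_pair:
            merged.append(MergedPeak(chrom=mp.chrom, start=mp.window_start,
                                     end=mp.window_end, minus_peak=mp, plus_peak=None,
                                     score=mp.height, libraries=mp.libraries))
    if not cfg.require_pair:
        for j, pp in enumerate(plus):
            if j not in used_plus:
                merged.append(MergedPeak(chrom=pp.chrom, start=pp.window_start,
                                         end=pp.window_end, minus_peak=None,
                                         plus_peak=pp, score=pp.height,
                                         libraries=pp.libraries))
    merged.sort(key=lambda m: (m.chrom, m.start))
    return merged


def filter_library_support(merged: Sequence[MergedPeak], cfg: PeakCallConfig,
                           libraries_present: set[str] | None = None,
                           ) -> list[MergedPeak]:
    """Drop merged peaks supported by only one of two supplied libraries.

    With a single-library run the filter is vacuous (logged notice).
    """
    if libraries_present is None:
        libraries_present = set()
        for m in merged:
            libraries_present |= m.libraries
    if len(libraries_present) < 2:
        warnings.warn("single-library run: library-support filter not applied")
        return list(merged)
    if not cfg.require_both_libraries:
        return list(merged)
    return [m for m in merged if len(m.libraries) >= 2]


def subtract_control_peaks(sample: Sequence[MergedPeak], control: Sequence[MergedPeak],
                           ) -> tuple[list[MergedPeak], list[MergedPeak]]:
    """Remove sample peaks overlapping (>= 1 bp) any control peak.

    Returns (kept, removed). Used to strip nuclease-independent
    integration hotspots via a nuclease-free treatment group.
    """
    trees: dict[str, IntervalTree] = {}
    for c in control:
        trees.setdefault(c.chrom, IntervalTree()).addi(c.start, c.end)
    kept, removed = [], []
    for m in sample:
        tree = trees.get(m.chrom)
        if tree is not None and tree.overlap(m.start, m.end):
            removed.append(m)
        else:
            kept.append(m)
    return kept, removed


def write_strand_peaks_bed(peaks: Iterable[StrandPeak], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# strand peaks; BED6 + height, p_value, sn_ratio, libraries; "
                 "0-based half-open\n")
        for p in sorted(peaks, key=lambda p: (p.chrom, p.window_start, p.strand)):
            libs = ",".join(sorted(p.libraries))
            fh.write(f"{p.chrom}\t{p.window_start}\t{p.window_end}\tpeak\t{p.height}\t"
                     f"{p.strand}\t{p.height}\t{p.p_value:.4g}\t{p.sn_ratio:.4g}\t{libs}\n")


def write_merged_peaks_bed(peaks: Iterable[MergedPeak], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# merged peaks; BED6 + libraries; score = summed strand heights; "
                 "0-based half-open\n")
        for i, m in enumerate(sorted(peaks, key=lambda m: (m.chrom, m.start)), 1):
            libs = ",".join(sorted(m.libraries))
            fh.write(f"{m.chrom}\t{m.start}\t{m.end}\tmerged_{i}\t{m.score}\t.\t{libs}\n")
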