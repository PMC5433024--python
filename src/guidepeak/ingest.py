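"""Alignment ingestion, pair filtering and UMI-based PCR deduplication.

GUIDE-seq libraries are amplified heavily, so many read pairs are PCR
copies of one ligation event. A unique molecule is identified by the
triple (UMI, genomic adaptor-ligation site, dsODN integration site);
pairs sharing all three within one library collapse to a single
observation. The dsODN integration position itself — the putative
cleavage site — is the 5'-most aligned base of read 2, on read 2's
strand.

Coordinates are 0-based half-open throughout this module.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pysam

TAG_SAM_KEY = "ZT"  # optional per-read int tag: 1 = dsODN tag seen, 0 = not


@dataclass(frozen=True)
class ReadPairRecord:
    read_id: str
    chrom: str          # read-2 chromosome
    r1_chrom: str
    r1_strand: str
    r2_strand: str
    r1_start: int
    r1_end: int
    r2_start: int
    r2_end: int
    r1_mapq: int
    r2_mapq: int
    has_tag: bool
    library: str
    umi: str


@dataclass(frozen=True)
class FilterConfig:
    """Pair-level filters; the names mirror the removal reasons reported.

    Defaults: mapping quality >= 30, each mate's aligned span >= 30 bp,
    mates within 1 kb on the same chromosome, and the dsODN tag required.
    """
    min_mapq: int = 30
    min_aligned_length: int = 30
    max_pair_span: int = 1000
    require_tag: bool = True

    def __post_init__(self) -> None:
        if min(self.min_mapq, self.min_aligned_length, self.max_pair_span) < 0:
            raise ValueError("filter thresholds must be non-negative")


@dataclass(frozen=True)
class UniqueCleavageEvent:
    chrom: str
    integration_pos: int
    strand: str
    library: str
    support: int
    umi: str = ""
    ligation_pos: int = -1


@dataclass
class FilterStats:
    removed: Counter = field(default_factory=Counter)
    n_kept: int = 0

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())


def read_umi_table(path: str) -> dict[str, str]:
    """Two-column TSV (read_id TAB umi) -> dict."""
    table = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rid, umi = line.rstrip("\n").split("\t")[:2]
            table[rid] = umi
    return table


def read_tag_table(path: str) -> dict[str, bool]:
    table = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rid, flag = line.rstrip("\n").split("\t")[:2]
            table[rid] = bool(int(flag))
    return table


def load_read_pairs(alignment_file: str, umi_table: dict[str, str] | str,
                    library: str, *, tag_table: dict[str, bool] | str | None = None,
                    strict: bool = False,
                    ) -> tuple[list[ReadPairRecord], dict[str, int]]:
    """Read primary paired alignments and attach UMIs.

    Works on name- or coordinate-sorted SAM/BAM: mates are re-associated
    by query name in memory. Secondary/supplementary alignments are
    skipped. A pair whose read id is missing from the UMI table is
    dropped with a count (default) or raises in strict mode.
    """
    if isinstance(umi_table, str):
        umi_table = read_umi_table(umi_table)
    if isinstance(tag_table, str):
        tag_table = read_tag_table(tag_table)

    stats = {"pairs": 0, "missing_umi": 0, "unpaired": 0}
    pending: dict[str, pysam.AlignedSegment] = {}
    records: list[ReadPairRecord] = []
    with pysam.AlignmentFile(alignment_file, check_sq=False) as af:
        for aln in af:
            if (aln.is_secondary or aln.is_supplementary or aln.is_unmapped
                    or not aln.is_paired):
                continue
            mate = pending.pop(aln.query_name, None)
            if mate is None:
                pending[aln.query_name] = aln
                continue
            r1, r2 = (aln, mate) if aln.is_read1 else (mate, aln)
            if not (r1.is_read1 and r2.is_read2):
                stats["unpaired"] += 1
                continue
            umi = umi_table.get(r1.query_name)
            if umi is None:
                stats["missing_umi"] += 1
                if strict:
                    raise KeyError(f"read id {r1.query_name!r} absent from UMI table")
                continue
            has_tag = _resolve_tag(r1, r2, tag_table)
            records.append(ReadPairRecord(
                read_id=r1.query_name,
                chrom=r2.reference_name,
                r1_chrom=r1.reference_name,
                r1_strand="-" if r1.is_reverse else "+",
                r2_strand="-" if r2.is_reverse else "+",
                r1_start=r1.reference_start, r1_end=r1.reference_end,
                r2_start=r2.reference_start, r2_end=r2.reference_end,
                r1_mapq=r1.mapping_quality, r2_mapq=r2.mapping_quality,
                has_tag=has_tag, library=library, umi=umi,
            ))
            stats["pairs"] += 1
    stats["unpaired"] += len(pending)
    return records, stats


def _resolve_tag(r1, r2, tag_table) -> bool:
    if tag_table is not None and r1.query_name in tag_table:
        return tag_table[r1.query_name]
    for aln in (r2, r1):
        if aln.has_tag(TAG_SAM_KEY):
            return bool(aln.get_tag(TAG_SAM_KEY))
    return True  # no tag information available: assume trimmed upstream


def filter_pairs(pairs: Iterable[ReadPairRecord], cfg: FilterConfig,
                 ) -> tuple[list[ReadPairRecord], FilterStats]:
    """Apply the pair filters; each removed pair is counted once, under
    the first failing rule (no_tag, mapq, aligned_length, span)."""
    kept: list[ReadPairRecord] = []
    stats = FilterStats()
    for p in pairs:
        if cfg.require_tag and not p.has_tag:
            stats.removed["no_tag"] += 1
        elif min(p.r1_mapq, p.r2_mapq) < cfg.min_mapq:
            stats.removed["mapq"] += 1
        elif (p.r1_end - p.r1_start < cfg.min_aligned_length
              or p.r2_end - p.r2_start < cfg.min_aligned_length):
            stats.removed["aligned_length"] += 1
        elif (p.r1_chrom != p.chrom
              or max(p.r1_end, p.r2_end) - min(p.r1_start, p.r2_start) > cfg.max_pair_span):
            # cross-chromosome mates fall under the span rule
            stats.removed["span"] += 1
        else:
            kept.append(p)
            stats.n_kept += 1
    return kept, stats


def event_coordinates(pair: ReadPairRecord) -> tuple[int, str, int]:
    """(integration_pos, strand, ligation_pos) for a filtered pair.

    The integration position is the 5'-most aligned base of read 2 and
    carries read 2's strand; the ligation position is the outermost
    aligned base of read 1.
    """
    strand = pair.r2_strand
    integration_pos = pair.r2_start if strand == "+" else pair.r2_end - 1
    ligation_pos = pair.r1_end - 1 if pair.r1_strand == "+" else pair.r1_start
    return integration_pos, strand, ligation_pos


def collapse_duplicates(pairs: Iterable[ReadPairRecord]) -> list[UniqueCleavageEvent]:
    """Collapse PCR duplicates into unique cleavage events.

    Duplicate key: (library, chrom, ligation_pos, integration_pos, strand,
    umi), compared exactly. Events come back sorted by
    (chrom, integration_pos, strand).
    """
    groups: Counter = Counter()
    for p in pairs:
        integration_pos, strand, ligation_pos = event_coordinates(p)
        groups[(p.library, p.chrom, ligation_pos, integration_pos, strand, p.umi)] += 1
    events = [
        UniqueCleavageEvent(chrom=chrom, integration_pos=ipos, strand=strand,
                            library=lib, support=n, umi=umi, ligation_pos=lpos)
        for (lib, chrom, lpos, ipos, strand, umi), n in groups.items()
    ]
    events.sort(key=lambda e: (e.chrom, e.integration_pos, e.strand))
    return events


def write_events_bed(events: Iterable[UniqueCleavageEvent], path: str) -> None:
    """BED6 (0-based half-open): name=library, score=support."""
    with open(path, "w") as fh:
        fh.write("# unique cleavage events; BED6, 0-based half-open; "
                 "name=library, score=collapsed duplicate count\n")
        for e in events:
            fh.write(f"{e.chrom}\t{e.integration_pos}\t{e.integration_pos + 1}\t"
                     f"{e.library}\t{e.support}\t{e.strand}\n")
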