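"""Demultiplexing and UMI/dsODN-tag extraction for GUIDE-seq runs.

Raw GUIDE-seq sequencing uses dual indexing: the p7 index read identifies
the sample pool, while the p5 index read carries the sample barcode
followed by the unique molecular index (UMI) ligated with the distal
adaptor. Read 2 begins with a constant fragment of the integrated dsODN
whose presence distinguishes genuine integration junctions from noise.

This module bins reads by (p7, p5) barcode pair, extracts the UMI from
the p5 index read, and detects/trims the library-specific dsODN tag from
read 2. It stops at per-sample FASTQ pairs plus UMI and tag tables;
alignment is delegated to any paired-end aligner.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from typing import IO, Iterator

from Bio import SeqIO

from .dna import hamming, validate_dna


@dataclass(frozen=True)
class SampleEntry:
    sample_name: str
    p7_index: str
    p5_barcode: str
    library: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if self.library not in ("forward", "reverse"):
            raise ValueError(f"library must be forward/reverse, got {self.library!r}")
        validate_dna(self.p7_index, alphabet="ACGT", context="p7_index")
        validate_dna(self.p5_barcode, alphabet="ACGT", context="p5_barcode")


@dataclass
class SampleSheet:
    entries: list[SampleEntry]

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            key = (e.sample_name, e.library)
            if key in seen:
                raise ValueError(f"duplicate (sample, library) pair {key}")
            seen.add(key)
        barcodes = [(e.p7_index, e.p5_barcode) for e in self.entries]
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("duplicate barcode assignment in sample sheet")

    @classmethod
    def from_tsv(cls, path: str) -> "SampleSheet":
        entries = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {c: i for i, c in enumerate(header)}
            for col in ("sample_name", "p7_index", "p5_barcode", "library"):
                if col not in idx:
                    raise ValueError(f"sample sheet missing column {col!r}")
            for line in fh:
                if not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                entries.append(SampleEntry(
                    f[idx["sample_name"]], f[idx["p7_index"]].upper(),
                    f[idx["p5_barcode"]].upper(), f[idx["library"]],
                ))
        return cls(entries)


@dataclass(frozen=True)
class UmiSpec:
    """Where the UMI sits inside the p5 index read.

    By default it directly follows the sample barcode and is 8 nt long;
    both are configurable because index-read architectures vary.
    """
    offset: int | None = None  # None -> barcode length of the matched sample
    length: int = 8


@dataclass(frozen=True)
class DsodnTagSpec:
    """Constant dsODN fragments expected as the read-2 prefix, per library."""
    forward_tag: str
    reverse_tag: str
    max_tag_mismatch: int | None = None  # None -> max(1, len(tag)//10)

    def __post_init__(self) -> None:
        if not self.forward_tag or not self.reverse_tag:
            raise ValueError("dsODN tags must be non-empty")
        if self.forward_tag == self.reverse_tag:
            raise ValueError("forward and reverse dsODN tags must differ")

    def budget(self, tag: str) -> int:
        if self.max_tag_mismatch is not None:
            return self.max_tag_mismatch
        return max(1, len(tag) // 10)


def _open_maybe_gz(path: str) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def extract_umi(index2_seq: str, spec: UmiSpec, *, barcode_length: int = 0) -> str:
    """Return the UMI substring of a p5 index read, uppercased.

    Raises ValueError when the read is too short to contain the UMI.
    A zero-length UMI is legal (returns ``""``) so runs without molecular
    indexes can still flow through, though deduplication then keys on
    position alone.
    """
    offset = spec.offset if spec.offset is not None else barcode_length
    if spec.length == 0:
        return ""
    if len(index2_seq) < offset + spec.length:
        raise ValueError(
            f"index read length {len(index2_seq)} < offset {offset} + umi length {spec.length}")
    return index2_seq[offset:offset + spec.length].upper()


def detect_and_trim_dsodn(read2_seq: str, tag_spec: DsodnTagSpec, library: str,
                          ) -> tuple[str, bool]:
    """Trim the library's dsODN tag off the read-2 prefix if present.

    Matching is a fixed-offset Hamming comparison (blunt ligation gives a
    constant junction, so no indel tolerance). Absence of the tag is data,
    not an error: the sequence is returned unchanged with ``has_tag=False``
    and the downstream pair filter decides what to do with it.
    """
    tag = tag_spec.forward_tag if library == "forward" else tag_spec.reverse_tag
    tag = tag.upper()
    prefix = read2_seq[:len(tag)].upper()
    if len(prefix) == len(tag) and hamming(tag, prefix) <= tag_spec.budget(tag):
        return read2_seq[len(tag):], True
    return read2_seq, False


def _match_barcode(observed: str, candidates: dict[str, list[SampleEntry]],
                   budget: int) -> list[SampleEntry] | None:
    """Entries whose barcode is within ``budget`` of ``observed``.

    Returns None when zero or more than one *distinct barcode* qualifies
    (ambiguity routes the read to undetermined).
    """
    hits = []
    for bc, entries in candidates.items():
        if len(bc) <= len(observed) and hamming(bc, observed[:len(bc)]) <= budget:
            hits.append((bc, entries))
    if len(hits) != 1:
        return None
    return hits[0][1]


@dataclass
class DemuxResult:
    counts: dict[str, int] = field(default_factory=dict)
    n_input: int = 0
    n_undetermined: int = 0
    n_umi_reject: int = 0
    fastq_paths: dict[str, tuple[str, str]] = field(default_factory=dict)
    umi_paths: dict[str, str] = field(default_factory=dict)
    tag_paths: dict[str, str] = field(default_factory=dict)


def demultiplex(read1_fastq: str, read2_fastq: str, index1_fastq: str,
                index2_fastq: str, sheet: SampleSheet, outdir: str,
                umi_spec: UmiSpec = UmiSpec(),
                tag_spec: DsodnTagSpec | None = None,
                barcode_mismatch_budget: int = 1) -> DemuxResult:
    """Bin reads into per-sample FASTQ pairs and write UMI / tag tables.

    The four FASTQ streams must be record-synchronized (identical read ids
    in identical order); the first divergence is a hard error. Each read
    lands in exactly one sample or in "undetermined". p7 and p5 barcodes
    are matched independently under a Hamming budget (default 1); a read
    within budget of two samples' barcodes is undetermined.
    """
    os.makedirs(outdir, exist_ok=True)
    if umi_spec.length == 0:
        import warnings
        warnings.warn("UMI length 0 configured: deduplication will key on position only")

    by_p7: dict[str, dict[str, list[SampleEntry]]] = {}
    for e in sheet.entries:
        by_p7.setdefault(e.p7_index, {}).setdefault(e.p5_barcode, []).append(e)

    res = DemuxResult()
    handles: dict[str, tuple[IO[str], IO[str], IO[str], IO[str]]] = {}

    def _handles(sample: str):
        if sample not in handles:
            r1p = os.path.join(outdir, f"{sample}_R1.fastq")
            r2p = os.path.join(outdir, f"{sample}_R2.fastq")
            up = os.path.join(outdir, f"{sample}_umi.tsv")
            tp = os.path.join(outdir, f"{sample}_tag.tsv")
            handles[sample] = (open(r1p, "w"), open(r2p, "w"), open(up, "w"), open(tp, "w"))
            res.fastq_paths[sample] = (r1p, r2p)
            res.umi_paths[sample] = up
            res.tag_paths[sample] = tp
        return handles[sample]

    streams = [SeqIO.parse(_open_maybe_gz(p), "fastq")
               for p in (read1_fastq, read2_fastq, index1_fastq, index2_fastq)]
    try:
        for recs in _zip_synced(streams):
            r1, r2, i1, i2 = recs
            res.n_input += 1
            entries = None
            p7_hit = _match_barcode(str(i1.seq).upper(), {k: [k] for k in by_p7},
                                    barcode_mismatch_budget) if by_p7 else None
            if p7_hit is not None:
                p7 = p7_hit[0]
                entries = _match_barcode(str(i2.seq).upper(), by_p7[p7],
                                         barcode_mismatch_budget)
            if not entries:
                res.n_undetermined += 1
                res.counts["undetermined"] = res.counts.get("undetermined", 0) + 1
                continue
            entry = entries[0]
            try:
                umi = extract_umi(str(i2.seq), umi_spec,
                                  barcode_length=len(entry.p5_barcode))
            except ValueError:
                res.n_umi_reject += 1
                continue
            seq2 = str(r2.seq)
            has_tag = True
            if tag_spec is not None:
                seq2, has_tag = detect_and_trim_dsodn(seq2, tag_spec, entry.library)
            fh1, fh2, fhu, fht = _handles(entry.sample_name)
            SeqIO.write(r1, fh1, "fastq")
            _write_fastq_trimmed(fh2, r2, seq2)
            fhu.write(f"{r1.id}\t{umi}\n")
            fht.write(f"{r1.id}\t{int(has_tag)}\n")
            res.counts[entry.sample_name] = res.counts.get(entry.sample_name, 0) + 1
    finally:
        for hs in handles.values():
            for h in hs:
                h.close()
    return res


def _write_fastq_trimmed(fh: IO[str], rec, new_seq: str) -> None:
    # keep original qualities for the retained suffix
    n_trim = len(rec.seq) - len(new_seq)
    quals = rec.letter_annotations["phred_quality"][n_trim:]
    qstr = "".join(chr(q + 33) for q in quals)
    fh.write(f"@{rec.description}\n{new_seq}\n+\n{qstr}\n")


def _zip_synced(streams) -> Iterator[tuple]:
    """Zip FASTQ iterators, erroring on the first read-id mismatch."""
    iters = [iter(s) for s in streams]
    while True:
        recs = []
        for it in iters:
            recs.append(next(it, None))
        if all(r is None for r in recs):
            return
        if any(r is None for r in recs):
            raise ValueError("FASTQ streams desynchronized: unequal record counts")
        base_ids = [_base_id(r.id) for r in recs]
        if len(set(base_ids)) != 1:
            raise ValueError(f"FASTQ streams desynchronized at read id {base_ids[0]!r}")
        yield tuple(recs)


def _base_id(read_id: str) -> str:
    # strip legacy /1 /2 mate suffixes
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id
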