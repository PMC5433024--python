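"""Deterministic GUIDE-seq simulator: toy genomes, planted cleavage
sites, and two-library read pairs with UMIs, PCR duplicates, background
noise and nuclease-independent hotspots.

The simulator reproduces the structural features the pipeline exploits:
at each planted cut, minus-strand (Crick) integration events fall just
upstream of the cut and plus-strand (Watson) events at/after it, so a
true site yields a Crick peak preceding a Watson peak; each unique
molecule carries a UMI and is emitted with PCR-duplicate copies sharing
(UMI, ligation site, integration site); read 2's 5' end sits at the
integration site with the library's dsODN tag recorded; read 1 lies at
fragment distance on the opposite strand. Hotspot loci are emitted into
both the sample and a paired nuclease-free control so hotspot
subtraction can be exercised. A single RNG stream keyed by the seed
drives all sampling in a fixed order, making outputs byte-identical for
a given seed.

Deliberately not modelled: sequencing errors, indel-bearing
integration junctions, realistic insert-size distributions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pysam

from .dna import revcomp
from .offtargets import GuideSpec, predicted_cut_position

# deterministic substitution used when planting a mismatch
_SUBST = {"A": "C", "C": "A", "G": "T", "T": "G", "N": "A"}


@dataclass(frozen=True)
class PlantSpec:
    locus: int                      # window start (protospacer+PAM) on the + strand
    mismatch_positions: tuple[int, ...] = ()   # 1-based from PAM-distal end
    pam_variant: str | None = None  # None -> concrete canonical PAM
    strand: str = "+"
    abundance: int = 5              # unique events per strand
    label: str = "site"

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError("abundance must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    genome_length: int = 200_000
    gc_fraction: float = 0.45
    fragment_length: tuple[int, int] = (150, 250)   # inclusive range
    read_length: int = 50
    pcr_duplication_mean: float = 3.0   # mean copies per unique molecule
    background_event_rate: float = 1e-4  # unique events per bp, genome-wide
    hotspot_loci: tuple[int, ...] = ()
    hotspot_abundance: int = 8
    umi_length: int = 8

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        if self.background_event_rate < 0 or self.pcr_duplication_mean < 1:
            raise ValueError("rates must be non-negative, duplication mean >= 1")


@dataclass
class TruthRecord:
    label: str
    chrom: str
    window_start: int
    window_end: int
    strand: str
    cut_pos: int
    n_mismatch_guide: int
    abundance: int


def make_genome(cfg: SimConfig, chrom: str = "chrSim") -> str:
    """Random genome sequence; base composition follows gc_fraction."""
    rng = np.random.default_rng(cfg.seed)
    p_gc = cfg.gc_fraction / 2
    p_at = (1 - cfg.gc_fraction) / 2
    bases = rng.choice(np.array(list("ACGT")), size=cfg.genome_length,
                       p=[p_at, p_gc, p_gc, p_at])
    return "".join(bases)


def write_fasta(seq: str, path: str, chrom: str = "chrSim", width: int = 80) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")


def build_site_sequence(guide: GuideSpec, mismatch_positions: tuple[int, ...],
                        pam_variant: str | None) -> str:
    """Guide-sense protospacer+PAM with the requested mismatches planted."""
    proto = list(guide.guide_seq)
    for pos in mismatch_positions:
        if not 1 <= pos <= guide.guide_length:
            raise ValueError(f"mismatch position {pos} outside guide")
        idx = pos - 1 if guide.pam_location == "three_prime" else guide.guide_length - pos
        proto[idx] = _SUBST[proto[idx]]
    pam = pam_variant if pam_variant is not None else _concrete_pam(guide.pam)
    if guide.pam_location == "three_prime":
        return "".join(proto) + pam
    return pam + "".join(proto)


def _concrete_pam(pam_mask: str) -> str:
    from .dna import IUPAC
    return "".join(sorted(IUPAC[m])[-1] if m != "N" else "A" for m in pam_mask.upper())


def plant_sites(genome: str, guide: GuideSpec, plants: list[PlantSpec],
                chrom: str = "chrSim") -> tuple[str, list[TruthRecord]]:
    """Rewrite planted windows to protospacer+PAM (with mismatches) and
    return the modified genome plus the truth table."""
    L = guide.site_length
    spans = sorted((p.locus, p.locus + L) for p in plants)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping plant loci [{s1},{e1}) and [{s2},{e2})")
    g = list(genome)
    truth = []
    for p in plants:
        if p.locus < 0 or p.locus + L > len(genome):
            raise ValueError(f"plant locus {p.locus} out of bounds")
        site = build_site_sequence(guide, p.mismatch_positions, p.pam_variant)
        embedded = site if p.strand == "+" else revcomp(site)
        g[p.locus:p.locus + L] = embedded
        if (guide.pam_location == "three_prime") == (p.strand == "+"):
            proto_start, proto_end = p.locus, p.locus + guide.guide_length
        else:
            proto_start, proto_end = p.locus + guide.pam_size, p.locus + L
        cut = predicted_cut_position(proto_start, proto_end, p.strand, guide)
        truth.append(TruthRecord(label=p.label, chrom=chrom, window_start=p.locus,
                                 window_end=p.locus + L, strand=p.strand, cut_pos=cut,
                                 n_mismatch_guide=len(p.mismatch_positions),
                                 abundance=p.abundance))
    return "".join(g), truth


@dataclass
class SimOutput:
    sample_sams: dict[str, str] = field(default_factory=dict)    # library -> path
    control_sams: dict[str, str] = field(default_factory=dict)
    sample_umis: dict[str, str] = field(default_factory=dict)
    control_umis: dict[str, str] = field(default_factory=dict)
    expected_events_path: str = ""
    n_expected_events: int = 0


def simulate_reads(genome: str, truth: list[TruthRecord], cfg: SimConfig,
                   outdir: str, chrom: str = "chrSim") -> SimOutput:
    """Emit forward/reverse-library SAMs + UMI TSVs for a sample and a
    paired nuclease-free control, plus the expected unique-event table.

    Draw order (fixed for reproducibility): per truth record in input
    order, minus then plus strand, events in index order (jitter,
    fragment length, UMI, duplicate count); then hotspots into sample
    and control; then background for sample, then control.
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 1)  # distinct from make_genome stream
    used_keys: set = set()
    events: dict[str, list] = {"sample": [], "control": []}

    def add_unique_events(dest: str, label: str, cut: int, abundance: int) -> None:
        for strand in ("-", "+"):
            for i in range(abundance):
                jitter = int(rng.integers(0, 4))
                pos = cut + jitter if strand == "+" else cut - 1 - jitter
                frag = int(rng.integers(cfg.fragment_length[0], cfg.fragment_length[1] + 1))
                library = "forward" if i % 2 == 0 else "reverse"
                _append_event(dest, label, pos, strand, library, frag)

    def _append_event(dest: str, label: str, pos: int, strand: str, library: str,
                      frag: int) -> None:
        for _ in range(64):  # redraw UMI on dedup-key collision
            umi = "".join(np.array(list("ACGT"))[rng.integers(0, 4, cfg.umi_length)])
            key = (dest, library, pos, strand, frag, umi)
            if key not in used_keys:
                used_keys.add(key)
                break
        copies = 1 + int(rng.poisson(max(cfg.pcr_duplication_mean - 1.0, 0.0)))
        events[dest].append((label, pos, strand, library, frag, umi, copies))

    for t in truth:
        add_unique_events("sample", t.label, t.cut_pos, t.abundance)
    for h, locus in enumerate(cfg.hotspot_loci):
        add_unique_events("sample", f"hotspot_{h}", locus, cfg.hotspot_abundance)
        add_unique_events("control", f"hotspot_{h}", locus, cfg.hotspot_abundance)
    for dest in ("sample", "control"):
        n_bg = int(rng.poisson(cfg.background_event_rate * cfg.genome_length))
        for _ in range(n_bg):
            pos = int(rng.integers(cfg.read_length, cfg.genome_length - cfg.read_length))
            strand = "+" if rng.integers(0, 2) else "-"
            library = "forward" if rng.integers(0, 2) else "reverse"
            frag = int(rng.integers(cfg.fragment_length[0], cfg.fragment_length[1] + 1))
            _append_event(dest, "background", pos, strand, library, frag)

    out = SimOutput()
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": chrom, "LN": len(genome)}]}
    for dest, sams, umis in (("sample", out.sample_sams, out.sample_umis),
                             ("control", out.control_sams, out.control_umis)):
        for library in ("forward", "reverse"):
            sam_path = os.path.join(outdir, f"{dest}_{library}.sam")
            umi_path = os.path.join(outdir, f"{dest}_{library}_umi.tsv")
            with pysam.AlignmentFile(sam_path, "wh", header=header) as af, \
                    open(umi_path, "w") as ufh:
                for ei, ev in enumerate(events[dest]):
                    label, pos, strand, lib, frag, umi, copies = ev
                    if lib != library:
                        continue
                    for copy in range(copies):
                        qname = f"sim:{dest}:{label}:{ei}:{copy}"
                        r1, r2 = _make_pair(qname, genome, chrom, pos, strand, frag,
                                            cfg.read_length, af.header)
                        if r1 is None:
                            continue
                        af.write(r1)
                        af.write(r2)
                        ufh.write(f"{qname}\t{umi}\n")
            sams[library] = sam_path
            umis[library] = umi_path

    out.expected_events_path = os.path.join(outdir, "expected_events.tsv")
    with open(out.expected_events_path, "w") as fh:
        fh.write("dest\tlabel\tchrom\tintegration_pos\tstrand\tlibrary\tumi\tsupport\n")
        for dest in ("sample", "control"):
            for label, pos, strand, library, frag, umi, copies in events[dest]:
                fh.write(f"{dest}\t{label}\t{chrom}\t{pos}\t{strand}\t{library}\t"
                         f"{umi}\t{copies}\n")
    out.n_expected_events = len(events["sample"])
    return out


def _make_pair(qname: str, genome: str, chrom: str, pos: int, strand: str,
               frag: int, read_len: int, header):
    """Build a proper read pair for one integration event.

    Plus-strand event: read 2 forward starting at pos, read 1 reverse at
    fragment distance downstream. Minus-strand event mirrored. Pairs
    running off either end of the toy genome are skipped.
    """
    if strand == "+":
        r2_start, r2_rev = pos, False
        r1_end = pos + frag
        r1_start, r1_rev = r1_end - read_len, True
    else:
        r2_start, r2_rev = pos + 1 - read_len, True
        r1_start, r1_rev = pos + 1 - frag, False
    lo = min(r1_start, r2_start)
    hi = max(r1_start, r2_start) + read_len
    if lo < 0 or hi > len(genome):
        return None, None

    def seg(start: int, rev: bool, is_read1: bool):
        a = pysam.AlignedSegment(header=header)
        a.query_name = qname
        seq = genome[start:start + read_len]
        a.query_sequence = seq if not rev else revcomp(seq)
        a.flag = (0x1 | 0x2 | (0x10 if rev else 0) | (0x20 if not rev else 0)
                  | (0x40 if is_read1 else 0x80))
        a.reference_id = 0
        a.reference_start = start
        a.mapping_quality = 60
        a.cigarstring = f"{read_len}M"
        a.query_qualities = pysam.qualitystring_to_array("I" * read_len)
        a.set_tag("ZT", 1)
        return a

    r1 = seg(r1_start, r1_rev, True)
    r2 = seg(r2_start, r2_rev, False)
    for a, b in ((r1, r2), (r2, r1)):
        a.next_reference_id = 0
        a.next_reference_start = b.reference_start
        a.template_length = (hi - lo) if a.reference_start == lo else -(hi - lo)
    return r1, r2


def write_truth_table(truth: list[TruthRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("label\tchrom\twindow_start\twindow_end\tstrand\tcut_pos\t"
                 "n_mismatch_guide\tabundance\n")
        for t in truth:
            fh.write(f"{t.label}\t{t.chrom}\t{t.window_start}\t{t.window_end}\t"
                     f"{t.strand}\t{t.cut_pos}\t{t.n_mismatch_guide}\t{t.abundance}\n")
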