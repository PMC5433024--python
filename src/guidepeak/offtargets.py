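"""Protospacer/PAM homology search around merged peaks.

Each merged peak's flanking genomic sequence (default 20 bp on each
side) is scanned on both strands for windows of guide_length + pam_size
that decompose, per the nuclease's PAM geometry, into a candidate
protospacer and a candidate PAM. A window is accepted when the guide
mismatch count, the PAM mismatch count (vs. the canonical PAM's IUPAC
classes), and at least one PAM pattern mask are all satisfied. Separate
guide and PAM budgets let users weight the two elements differently —
essential for nucleases like NmCas9 (24-nt guide, 8-nt PAM NNNNGATT) or
AsCpf1 (5' TTTN PAM).

Mismatch positions are reported 1-based from the PAM-distal end of the
guide regardless of PAM location, matching the convention of the
position-weight cleavage models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .dna import iupac_match, revcomp, validate_dna
from .peakcall import MergedPeak


@dataclass(frozen=True)
class GuideSpec:
    """Guide RNA plus the nuclease's PAM model and mismatch budgets."""
    guide_seq: str
    guide_length: int = 20
    pam: str = "NGG"
    pam_size: int = 3
    pam_location: str = "three_prime"   # or "five_prime"
    pam_pattern: tuple[str, ...] = ()   # IUPAC masks (alternation); () -> (pam,)
    max_mismatch_guide: int = 6
    max_mismatch_pam: int = 2
    cut_offset: int = 3                 # bp from the PAM-proximal guide end

    def __post_init__(self) -> None:
        object.__setattr__(self, "guide_seq", self.guide_seq.upper().replace("U", "T"))
        validate_dna(self.guide_seq, alphabet="ACGTN", context="guide_seq")
        if len(self.guide_seq) != self.guide_length:
            raise ValueError(f"guide_seq length {len(self.guide_seq)} != "
                             f"guide_length {self.guide_length}")
        if len(self.pam) != self.pam_size:
            raise ValueError("pam length != pam_size")
        if self.pam_location not in ("three_prime", "five_prime"):
            raise ValueError("pam_location must be three_prime or five_prime")
        if not self.pam_pattern:
            object.__setattr__(self, "pam_pattern", (self.pam.upper(),))
        else:
            object.__setattr__(self, "pam_pattern",
                               tuple(m.upper() for m in self.pam_pattern))
        for m in self.pam_pattern:
            if len(m) != self.pam_size:
                raise ValueError(f"pam_pattern mask {m!r} length != pam_size")
        if self.max_mismatch_guide < 0 or self.max_mismatch_pam < 0:
            raise ValueError("mismatch budgets must be >= 0")

    @property
    def site_length(self) -> int:
        return self.guide_length + self.pam_size


@dataclass(frozen=True)
class OffTargetSite:
    chrom: str
    proto_start: int        # protospacer only, 0-based half-open
    proto_end: int
    strand: str
    protospacer_seq: str    # guide-sense
    pam_seq: str
    n_mismatch_guide: int
    mismatch_detail: tuple[tuple[int, str, str], ...]  # (pos from PAM-distal, guide, genome)
    n_mismatch_pam: int
    predicted_cut_pos: int
    peak_score: int = 0
    peak_id: str = ""
    cleavage_score: float = float("nan")
    annotation: dict = field(default_factory=dict, compare=False, hash=False)


def count_guide_mismatches(guide_seq: str, candidate: str, *,
                           pam_location: str = "three_prime",
                           ) -> tuple[int, tuple[tuple[int, str, str], ...]]:
    """Positionwise guide/protospacer comparison.

    Positions are 1-based from the PAM-distal end: index 0 of a 3'-PAM
    guide is position 1; for a 5' PAM the numbering runs from the far
    (right) end back.
    """
    if len(guide_seq) != len(candidate):
        raise ValueError("guide and candidate protospacer lengths differ")
    L = len(guide_seq)
    detail = []
    for i, (g, c) in enumerate(zip(guide_seq.upper(), candidate.upper())):
        if g != c:
            pos = i + 1 if pam_location == "three_prime" else L - i
            detail.append((pos, g, c))
    detail.sort()
    return len(detail), tuple(detail)


def count_pam_mismatches(pam: str, candidate_pam: str) -> int:
    """Positions of ``candidate_pam`` outside the canonical PAM's IUPAC class."""
    if len(pam) != len(candidate_pam):
        raise ValueError("PAM lengths differ")
    n = 0
    for m, c in zip(pam.upper(), candidate_pam.upper()):
        if not iupac_match(m, c):
            n += 1
    return n


def predicted_cut_position(proto_start: int, proto_end: int, strand: str,
                           spec: GuideSpec) -> int:
    """Blunt-cut genome coordinate, ``cut_offset`` bases from the
    PAM-proximal end of the protospacer (the cut falls immediately 5' of
    the returned coordinate on the protospacer strand)."""
    if spec.pam_location == "three_prime":
        # PAM-proximal end is the 3' end of the protospacer
        return proto_end - spec.cut_offset if strand == "+" else proto_start + spec.cut_offset
    # five_prime: PAM precedes the protospacer
    return proto_start + spec.cut_offset if strand == "+" else proto_end - spec.cut_offset


def _decompose(window: str, spec: GuideSpec) -> tuple[str, str]:
    """(protospacer, pam) from a guide-sense window of site_length."""
    if spec.pam_location == "three_prime":
        return window[:spec.guide_length], window[spec.guide_length:]
    return window[spec.pam_size:], window[:spec.pam_size]


def scan_region(genome_fetch, chrom: str, region_start: int, region_end: int,
                spec: GuideSpec, *, chrom_length: int | None = None,
                ) -> list[OffTargetSite]:
    """Enumerate accepted protospacer+PAM windows in a genomic region.

    ``genome_fetch(chrom, start, end)`` must return the sequence (e.g.
    ``pysam.FastaFile.fetch``). Only windows fully inside the (clipped)
    region are considered; soft-masked lowercase is uppercased first.
    Both strands are scanned; minus-strand candidates are reported with
    guide-sense sequences and genome coordinates of the protospacer.
    """
    region_start = max(0, region_start)
    if chrom_length is not None:
        region_end = min(region_end, chrom_length)
    L = spec.site_length
    if region_end - region_start < L:
        return []
    seq = str(genome_fetch(chrom, region_start, region_end)).upper()
    validate_dna(seq, context=f"{chrom}:{region_start}-{region_end}")

    sites: list[OffTargetSite] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        n = len(s)
        for i in range(n - L + 1):
            window = s[i:i + L]
            proto, pam_cand = _decompose(window, spec)
            n_pam = count_pam_mismatches(spec.pam, pam_cand)
            if n_pam > spec.max_mismatch_pam:
                continue
            if not any(iupac_match(mask, pam_cand) for mask in spec.pam_pattern):
                continue
            n_guide, detail = count_guide_mismatches(
                spec.guide_seq, proto, pam_location=spec.pam_location)
            if n_guide > spec.max_mismatch_guide:
                continue
            # genome coordinates of the whole window, then of the protospacer
            if strand == "+":
                w_start = region_start + i
            else:
                w_start = region_start + (n - i - L)
            w_end = w_start + L
            if (spec.pam_location == "three_prime") == (strand == "+"):
                proto_start, proto_end = w_start, w_end - spec.pam_size
            else:
                proto_start, proto_end = w_start + spec.pam_size, w_end
            sites.append(OffTargetSite(
                chrom=chrom, proto_start=proto_start, proto_end=proto_end,
                strand=strand, protospacer_seq=proto, pam_seq=pam_cand,
                n_mismatch_guide=n_guide, mismatch_detail=detail,
                n_mismatch_pam=n_pam,
                predicted_cut_pos=predicted_cut_position(
                    proto_start, proto_end, strand, spec),
            ))
    sites.sort(key=lambda s: (s.proto_start, s.strand))
    return sites


def assign_site_to_peak(peak: MergedPeak, candidates: Sequence[OffTargetSite],
                        *, peak_id: str = "", report_all: bool = False,
                        ) -> list[OffTargetSite]:
    """Pick the best candidate for a peak (or all, in report-all mode).

    Ranking: fewest guide mismatches, then fewest PAM mismatches, then
    smallest |predicted cut - peak midpoint|, then leftmost. Returns []
    when the peak has no candidate (it then belongs in the
    "peaks without target homology" output).
    """
    if not candidates:
        return []
    midpoint = (peak.start + peak.end) // 2

    def key(site: OffTargetSite):
        return (site.n_mismatch_guide, site.n_mismatch_pam,
                abs(site.predicted_cut_pos - midpoint), site.proto_start)

    chosen = sorted(candidates, key=key) if report_all else [min(candidates, key=key)]
    from dataclasses import replace
    return [replace(s, peak_score=peak.score, peak_id=peak_id) for s in chosen]


def search_offtargets(merged_peaks: Sequence[MergedPeak], genome_fetch, spec: GuideSpec,
                      *, flank: int = 20, chrom_lengths: dict[str, int] | None = None,
                      report_all: bool = False,
                      ) -> tuple[list[OffTargetSite], list[MergedPeak]]:
    """Scan ``flank`` bases on each side of every merged peak and assign sites.

    Returns (assigned sites, peaks without homology).
    """
    sites: list[OffTargetSite] = []
    orphans: list[MergedPeak] = []
    for i, peak in enumerate(sorted(merged_peaks, key=lambda m: (m.chrom, m.start)), 1):
        clen = chrom_lengths.get(peak.chrom) if chrom_lengths else None
        cands = scan_region(genome_fetch, peak.chrom, peak.start - flank,
                            peak.end + flank, spec, chrom_length=clen)
        assigned = assign_site_to_peak(peak, cands, peak_id=f"peak_{i}",
                                       report_all=report_all)
        if assigned:
            sites.extend(assigned)
        else:
            orphans.append(peak)
    return sites, orphans
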