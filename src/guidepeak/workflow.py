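"""One-call GUIDE-seq analysis: filter -> dedup -> peak call -> homology
search -> cleavage score -> annotate -> ranked off-target report.

``run_analysis`` mirrors the single-workflow-function style of the
original tooling: given per-library alignments + UMI tables, a guide, a
genome and optional annotation, it writes the ranked off-target table
(``offTargetsInPeakRegions.tsv``) plus the intermediate BED/TSV files
and a run log recording every effective parameter, and returns the
in-memory ExperimentResult for downstream comparison.

Reports use 1-based inclusive coordinates (spreadsheet convention); all
BED outputs are 0-based half-open. Floats are printed at 4 significant
digits so identical inputs give byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import os
import shutil
from dataclasses import dataclass, field

import pysam

from . import annotate as annotate_mod
from . import ingest, peakcall
from .compare import ExperimentResult
from .offtargets import GuideSpec, OffTargetSite, search_offtargets
from .peakcall import MergedPeak, PeakCallConfig
from .scoring import load_scoring_model, score_site

REPORT_COLUMNS = [
    "peak_id", "chrom", "start", "end", "strand", "offtarget_sequence",
    "n_mismatch_guide", "mismatch_detail", "n_mismatch_pam", "peak_score",
    "p_value", "sn_ratio", "predicted_cleavage_score",
    "gene_symbols", "gene_ids", "in_exon", "in_intron",
]

# external config keys mirroring the original R interface -> internal names
PARAM_ALIASES = {
    "max.mismatch": "max_mismatch_guide",
    "allowed.mismatch.PAM": "max_mismatch_pam",
    "PAM": "pam",
    "PAM.size": "pam_size",
    "PAM.pattern": "pam_pattern",
    "PAM.location": "pam_location",
    "gRNA.length": "guide_length",
    "scoring.method": "scoring_method",
    "window.size": "window_size",
    "min.reads": "min_reads",
    "bg.window.size": "background_window",
    "distance.threshold": "merge_distance",
    "upstream": "flank",
    "downstream": "flank",
}


@dataclass
class RunConfig:
    sample_name: str
    bam_forward: str
    bam_reverse: str
    umi_forward: str
    umi_reverse: str
    guide_fasta: str
    genome_fasta: str
    outdir: str
    annotation_path: str | None = None
    annotation_format: str | None = None
    filter_cfg: ingest.FilterConfig = field(default_factory=ingest.FilterConfig)
    peak_cfg: PeakCallConfig = field(default_factory=PeakCallConfig)
    guide_overrides: dict = field(default_factory=dict)  # GuideSpec fields sans guide_seq
    scoring_method: str = "hsu_zhang_2013"
    scoring_matrix: str | None = None
    flank: int = 20
    control_bam_forward: str | None = None
    control_bam_reverse: str | None = None
    control_umi_forward: str | None = None
    control_umi_reverse: str | None = None
    legacy_filename: bool = False   # emit offTargetsInPeakRegions.xls alongside


def read_guide_fasta(path: str) -> str:
    from Bio import SeqIO
    records = list(SeqIO.parse(path, "fasta"))
    if len(records) != 1:
        raise ValueError(f"guide FASTA must contain exactly one record, got {len(records)}")
    return str(records[0].seq).upper()


def _events_for(bam_fwd, bam_rev, umi_fwd, umi_rev, filter_cfg, log):
    pairs = []
    for lib, bam, umi in (("forward", bam_fwd, umi_fwd), ("reverse", bam_rev, umi_rev)):
        recs, stats = ingest.load_read_pairs(bam, umi, lib)
        log.append(f"{lib}: loaded pairs={stats['pairs']} "
                   f"missing_umi={stats['missing_umi']} unpaired={stats['unpaired']}")
        pairs.extend(recs)
    kept, fstats = ingest.filter_pairs(pairs, filter_cfg)
    log.append(f"filter: kept={fstats.n_kept} removed={dict(fstats.removed)}")
    events = ingest.collapse_duplicates(kept)
    log.append(f"dedup: unique_events={len(events)} from kept_pairs={fstats.n_kept}")
    return events, kept


def _peaks_for(events, peak_cfg, log, tag):
    strand_peaks = peakcall.call_strand_peaks(events, peak_cfg)
    merged = peakcall.merge_watson_crick(strand_peaks, peak_cfg)
    merged = peakcall.filter_library_support(merged, peak_cfg)
    log.append(f"{tag}: strand_peaks={len(strand_peaks)} merged_peaks={len(merged)}")
    return strand_peaks, merged


def run_analysis(cfg: RunConfig) -> ExperimentResult:
    """Run the full pipeline; on any stage failure partial outputs are
    removed and a stage-tagged error is raised."""
    os.makedirs(cfg.outdir, exist_ok=True)
    written: list[str] = []
    log: list[str] = []
    try:
        stage = "guide"
        guide_seq = read_guide_fasta(cfg.guide_fasta)
        overrides = dict(cfg.guide_overrides)
        overrides.setdefault("guide_length", len(guide_seq))
        guide = GuideSpec(guide_seq=guide_seq, **overrides)

        stage = "ingest"
        events, kept = _events_for(cfg.bam_forward, cfg.bam_reverse,
                                   cfg.umi_forward, cfg.umi_reverse,
                                   cfg.filter_cfg, log)
        ev_path = os.path.join(cfg.outdir, "unique_events.bed")
        ingest.write_events_bed(events, ev_path)
        written.append(ev_path)

        stage = "peakcall"
        strand_peaks, merged = _peaks_for(events, cfg.peak_cfg, log, "sample")
        if cfg.control_bam_forward:
            c_events, _ = _events_for(cfg.control_bam_forward, cfg.control_bam_reverse,
                                      cfg.control_umi_forward, cfg.control_umi_reverse,
                                      cfg.filter_cfg, log)
            _, c_merged = _peaks_for(c_events, cfg.peak_cfg, log, "control")
            merged, removed = peakcall.subtract_control_peaks(merged, c_merged)
            log.append(f"control subtraction: removed={len(removed)} kept={len(merged)}")
        sp_path = os.path.join(cfg.outdir, "strand_peaks.bed")
        mp_path = os.path.join(cfg.outdir, "merged_peaks.bed")
        peakcall.write_strand_peaks_bed(strand_peaks, sp_path)
        peakcall.write_merged_peaks_bed(merged, mp_path)
        written += [sp_path, mp_path]

        stage = "offtarget_search"
        with pysam.FastaFile(cfg.genome_fasta) as fa:
            chrom_lengths = dict(zip(fa.references, fa.lengths))
            sites, orphans = search_offtargets(merged, fa.fetch, guide,
                                               flank=cfg.flank,
                                               chrom_lengths=chrom_lengths)
        log.append(f"search: assigned={len(sites)} without_homology={len(orphans)}")
        peak_stats = {}
        for i, m in enumerate(sorted(merged, key=lambda m: (m.chrom, m.start)), 1):
            parts = [p for p in (m.minus_peak, m.plus_peak) if p is not None]
            peak_stats[f"peak_{i}"] = (min(p.p_value for p in parts),
                                       max(p.sn_ratio for p in parts))

        stage = "cleavage_scoring"
        model = load_scoring_model(cfg.scoring_matrix or cfg.scoring_method,
                                   guide.guide_length)
        sites = [dataclasses.replace(s, cleavage_score=score_site(s, model))
                 for s in sites]

        stage = "annotate"
        if cfg.annotation_path:
            index = annotate_mod.load_gene_models(cfg.annotation_path,
                                                  cfg.annotation_format)
            sites = annotate_mod.annotate_sites(sites, index)

        stage = "report"
        sites.sort(key=lambda s: (-s.peak_score, s.chrom, s.proto_start))
        report = os.path.join(cfg.outdir, "offTargetsInPeakRegions.tsv")
        write_offtarget_report(sites, guide, report, peak_stats=peak_stats)
        written.append(report)
        if cfg.legacy_filename:
            legacy = os.path.join(cfg.outdir, "offTargetsInPeakRegions.xls")
            shutil.copyfile(report, legacy)
            written.append(legacy)
        orphan_path = os.path.join(cfg.outdir, "peaks_without_homology.tsv")
        write_orphan_peaks(orphans, orphan_path)
        written.append(orphan_path)

        stage = "log"
        log_path = os.path.join(cfg.outdir, "run_log.txt")
        _write_run_log(cfg, guide, log, log_path)
        written.append(log_path)
    except Exception as exc:
        for p in written:
            if os.path.exists(p):
                os.remove(p)
        raise RuntimeError(f"[{stage}] {exc}") from exc
    return ExperimentResult(sample_name=cfg.sample_name, sites=sites)


def _fmt(x) -> str:
    if isinstance(x, float):
        return f"{x:.4g}"
    return str(x)


def write_offtarget_report(sites: list[OffTargetSite], guide: GuideSpec,
                           path: str, peak_stats: dict | None = None) -> None:
    """Ranked report, one row per site; coordinates 1-based inclusive.

    offtarget_sequence is protospacer+PAM in guide-sense orientation;
    mismatch_detail entries read pos:guide>genome with positions numbered
    from the PAM-distal end. ``peak_stats`` maps peak_id to the merged
    peak's (best p-value, best SNratio) across its two strand peaks.
    """
    peak_stats = peak_stats or {}
    with open(path, "w") as fh:
        fh.write("# off-target report; coordinates 1-based inclusive; "
                 "ranked by peak_score desc\n")
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for s in sites:
            if guide.pam_location == "three_prime":
                full_seq = s.protospacer_seq + s.pam_seq
            else:
                full_seq = s.pam_seq + s.protospacer_seq
            mm = ";".join(f"{p}:{g}>{b}" for p, g, b in s.mismatch_detail) or "."
            ann = s.annotation or {}
            pv, sn = peak_stats.get(s.peak_id, ("", ""))
            row = [
                s.peak_id, s.chrom, s.proto_start + 1, s.proto_end, s.strand,
                full_seq, s.n_mismatch_guide, mm, s.n_mismatch_pam, s.peak_score,
                _fmt(pv), _fmt(sn),
                _fmt(s.cleavage_score),
                ann.get("gene_symbols", ""), ann.get("gene_ids", ""),
                _fmt(ann.get("in_exon", "")), _fmt(ann.get("in_intron", "")),
            ]
            fh.write("\t".join(_fmt(x) for x in row) + "\n")


def write_orphan_peaks(orphans: list[MergedPeak], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# merged peaks with no guide-homologous sequence in the "
                 "searched flanks; 0-based half-open\n")
        fh.write("chrom\tstart\tend\tscore\tlibraries\n")
        for m in orphans:
            fh.write(f"{m.chrom}\t{m.start}\t{m.end}\t{m.score}\t"
                     f"{','.join(sorted(m.libraries))}\n")


def _write_run_log(cfg: RunConfig, guide: GuideSpec, log: list[str],
                   path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# effective parameters (sufficient to reproduce this run)\n")
        for name, obj in (("run", cfg), ("guide", guide),
                          ("filter", cfg.filter_cfg), ("peaks", cfg.peak_cfg)):
            for f in dataclasses.fields(obj):
                if f.name in ("filter_cfg", "peak_cfg", "guide_overrides"):
                    continue
                fh.write(f"{name}.{f.name}\t{getattr(obj, f.name)!r}\n")
        fh.write("# stage log\n")
        for line in log:
            fh.write(f"# {line}\n")
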