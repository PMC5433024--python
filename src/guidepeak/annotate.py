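"""Gene/exon overlap annotation of off-target sites.

Off-target sites falling in genes — and especially in exons — are the
ones most likely to matter functionally, so each site is flagged with
the overlapping gene symbols/ids and whether it touches an exon.
Overlap is strand-agnostic (a nuclease lesion disrupts the gene
regardless of which strand the protospacer matched) and requires >= 1 bp
against the protospacer interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import gffutils
from intervaltree import IntervalTree

from .offtargets import OffTargetSite


@dataclass
class GeneRecord:
    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class GeneModelIndex:
    genes: dict[str, IntervalTree] = field(default_factory=dict)   # chrom -> tree of GeneRecord
    exons: dict[str, IntervalTree] = field(default_factory=dict)

    def add(self, rec: GeneRecord) -> None:
        if rec.end <= rec.start:
            return
        self.genes.setdefault(rec.chrom, IntervalTree()).addi(rec.start, rec.end, rec)
        for s, e in rec.exons:
            if e > s:
                self.exons.setdefault(rec.chrom, IntervalTree()).addi(s, e, rec)

    def query_genes(self, chrom: str, start: int, end: int) -> list[GeneRecord]:
        tree = self.genes.get(chrom)
        return [iv.data for iv in tree.overlap(start, end)] if tree else []

    def query_exons(self, chrom: str, start: int, end: int) -> list[GeneRecord]:
        tree = self.exons.get(chrom)
        return [iv.data for iv in tree.overlap(start, end)] if tree else []


def load_gene_models(path: str, fmt: str | None = None) -> GeneModelIndex:
    """Build a GeneModelIndex from GFF3, GTF or BED12.

    Gene spans are the hull over a gene's features; exon sets come from
    "exon" features (GFF3/GTF) or BED12 blocks. The format is inferred
    from the extension when not given.
    """
    if fmt is None:
        low = path.lower()
        if low.endswith((".gff", ".gff3")):
            fmt = "gff3"
        elif low.endswith(".gtf"):
            fmt = "gtf"
        elif low.endswith((".bed", ".bed12")):
            fmt = "bed12"
        else:
            raise ValueError(f"cannot infer annotation format from {path!r}")
    if fmt == "bed12":
        return _load_bed12(path)
    if fmt not in ("gff3", "gtf"):
        raise ValueError(f"unsupported annotation format {fmt!r}")
    try:
        db = gffutils.create_db(path, dbfn=":memory:", force=True, keep_order=True,
                                merge_strategy="create_unique")
    except gffutils.exceptions.EmptyInputError:
        return GeneModelIndex()
    index = GeneModelIndex()
    records: dict[str, GeneRecord] = {}
    for gene in db.features_of_type("gene"):
        gid = _attr(gene, "gene_id", "ID") or gene.id
        sym = _attr(gene, "gene_name", "Name") or gid
        records[gene.id] = GeneRecord(gene_id=gid, symbol=sym, chrom=gene.seqid,
                                      start=gene.start - 1, end=gene.end)
    for exon in db.features_of_type("exon"):
        parent = _owning_gene(db, exon)
        rec = records.get(parent) if parent else None
        if rec is None:
            gid = _attr(exon, "gene_id", "ID") or (parent or exon.id)
            rec = records.setdefault(parent or gid, GeneRecord(
                gene_id=gid, symbol=_attr(exon, "gene_name", "Name") or gid,
                chrom=exon.seqid, start=exon.start - 1, end=exon.end))
        rec.exons.append((exon.start - 1, exon.end))
        rec.start = min(rec.start, exon.start - 1)
        rec.end = max(rec.end, exon.end)
    for rec in records.values():
        index.add(rec)
    return index


def _attr(feature, *names: str) -> str | None:
    for n in names:
        if n in feature.attributes:
            v = feature.attributes[n]
            return v[0] if isinstance(v, list) else v
    return None


def _owning_gene(db, feature) -> str | None:
    cur = feature
    for _ in range(4):  # exon -> transcript -> gene, at most a short chain
        parents = cur.attributes.get("Parent") or cur.attributes.get("gene_id")
        if not parents:
            return None
        pid = parents[0]
        try:
            parent = db[pid]
        except gffutils.FeatureNotFoundError:
            return pid
        if parent.featuretype == "gene":
            return parent.id
        cur = parent
    return None


def _load_bed12(path: str) -> GeneModelIndex:
    index = GeneModelIndex()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 needs 12 columns, got {len(f)}")
            try:
                chrom, start, name = f[0], int(f[1]), f[3]
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable BED12 line: {exc}")
            if not (len(sizes) == len(offsets) == n_blocks):
                raise ValueError(f"{path}:{lineno}: block count mismatch")
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            index.add(GeneRecord(gene_id=name, symbol=name, chrom=chrom,
                                 start=min(s for s, _ in exons),
                                 end=max(e for _, e in exons), exons=exons))
    return index


def annotate_sites(sites: Sequence[OffTargetSite], index: GeneModelIndex,
                   ) -> list[OffTargetSite]:
    """Attach gene_symbols, gene_ids, in_exon and in_intron to each site.

    Multiple overlapping genes are comma-joined, lexicographically
    sorted. in_intron means: inside a gene body but touching no exon.
    """
    out = []
    for s in sites:
        genes = index.query_genes(s.chrom, s.proto_start, s.proto_end)
        exon_hit = bool(index.query_exons(s.chrom, s.proto_start, s.proto_end))
        ann = {
            "gene_symbols": ",".join(sorted({g.symbol for g in genes})),
            "gene_ids": ",".join(sorted({g.gene_id for g in genes})),
            "in_exon": exon_hit,
            "in_intron": bool(genes) and not exon_hit,
        }
        out.append(replace(s, annotation=ann))
    return out
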