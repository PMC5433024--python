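"""Multi-experiment comparison of off-target tables.

When screening nuclease variants or guide designs, the per-sample
off-target tables are merged into one row per genomic locus so shared
and private sites stand out. Sites from different samples are clustered
by single-linkage genomic overlap (>= 1 bp between protospacer
intervals) rather than exact coordinates, so a few bases of
peak-boundary jitter between runs does not split a shared site. The
membership structure feeds Venn region counts for up to five samples;
the counts table is the contract, the diagram a thin optional layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import pandas as pd

from .offtargets import OffTargetSite


@dataclass
class ExperimentResult:
    sample_name: str
    sites: list[OffTargetSite] = field(default_factory=list)

    @classmethod
    def from_tsv(cls, sample_name: str, path: str) -> "ExperimentResult":
        """Read an off-target report TSV (1-based inclusive coordinates)."""
        df = pd.read_csv(path, sep="\t", comment="#")
        sites = [
            OffTargetSite(
                chrom=str(r["chrom"]), proto_start=int(r["start"]) - 1,
                proto_end=int(r["end"]), strand=str(r["strand"]),
                protospacer_seq="", pam_seq="", n_mismatch_guide=0,
                mismatch_detail=(), n_mismatch_pam=0, predicted_cut_pos=0,
                peak_score=int(r["peak_score"]),
            )
            for _, r in df.iterrows()
        ]
        return cls(sample_name, sites)


@dataclass
class CombinedTable:
    sample_names: list[str]
    df: pd.DataFrame  # chrom, start, end, <sample> score columns, membership


def combine_offtargets(results: Sequence[ExperimentResult], *,
                       remove_common: bool = False,
                       control_sample_name: str | None = None,
                       min_overlap: int = 1) -> CombinedTable:
    """Cluster sites across samples into one row per locus.

    ``remove_common`` drops loci present in every non-control sample
    (e.g. to strip guide-independent sites shared across different
    gRNAs); ``control_sample_name`` drops loci present in that sample
    (nuclease-free hotspot subtraction), then drops its column.
    """
    names = [r.sample_name for r in results]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sample names in comparison")
    non_control = [n for n in names if n != control_sample_name]
    if control_sample_name is not None and control_sample_name not in names:
        raise ValueError(f"control sample {control_sample_name!r} not among inputs")
    if not 2 <= len(non_control):
        raise ValueError("need at least 2 non-control samples to combine")

    items = [(r.sample_name, s) for r in results for s in r.sites]
    items.sort(key=lambda t: (t[1].chrom, t[1].proto_start, t[1].proto_end))

    rows = []
    cluster: list[tuple[str, OffTargetSite]] = []
    cluster_end = None

    def flush():
        if not cluster:
            return
        chrom = cluster[0][1].chrom
        start = min(s.proto_start for _, s in cluster)
        end = max(s.proto_end for _, s in cluster)
        row: dict = {"chrom": chrom, "start": start, "end": end}
        members = set()
        for name, s in cluster:
            members.add(name)
            row[name] = max(row.get(name, 0), s.peak_score)
        row["members"] = frozenset(members)
        rows.append(row)

    for name, s in items:
        if cluster and (s.chrom != cluster[0][1].chrom
                        or s.proto_start > cluster_end - min_overlap):
            flush()
            cluster, cluster_end = [], None
        cluster.append((name, s))
        cluster_end = s.proto_end if cluster_end is None else max(cluster_end, s.proto_end)
    flush()

    df = pd.DataFrame(rows, columns=["chrom", "start", "end", *names, "members"])
    if not df.empty:
        for n in names:
            df[n] = df[n].fillna(0).astype(int)
    if control_sample_name is not None and not df.empty:
        df = df[~df["members"].apply(lambda m: control_sample_name in m)]
        df = df.drop(columns=[control_sample_name])
        df["members"] = df["members"].apply(lambda m: m - {control_sample_name})
    elif control_sample_name is not None:
        df = df.drop(columns=[control_sample_name], errors="ignore")
    if remove_common and not df.empty:
        full = frozenset(non_control)
        df = df[df["members"] != full]
    df = df.reset_index(drop=True)
    return CombinedTable(sample_names=non_control, df=df)


def venn_counts(table: CombinedTable) -> dict[frozenset, int]:
    """Counts for all 2^k - 1 membership regions, k = number of samples.

    Region counts partition the combined rows: every row lands in
    exactly one region.
    """
    k = len(table.sample_names)
    if not 2 <= k <= 5:
        raise ValueError(f"Venn requires 2..5 samples, got {k}")
    counts: dict[frozenset, int] = {}
    for r in range(1, k + 1):
        for combo in combinations(sorted(table.sample_names), r):
            counts[frozenset(combo)] = 0
    for members in table.df["members"]:
        counts[frozenset(members)] += 1
    return counts


def write_venn_counts(counts: dict[frozenset, int], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("members\tcount\n")
        for region in sorted(counts, key=lambda r: (len(r), sorted(r))):
            fh.write(f"{'&'.join(sorted(region))}\t{counts[region]}\n")


def write_combined_table(table: CombinedTable, path: str) -> None:
    df = table.df.copy()
    if not df.empty:
        df["members"] = df["members"].apply(lambda m: ",".join(sorted(m)))
        df["start"] = df["start"] + 1  # report 1-based inclusive
    with open(path, "w") as fh:
        fh.write("# combined off-target loci; coordinates 1-based inclusive\n")
        df.to_csv(fh, sep="\t", index=False)


def plot_venn(counts: dict[frozenset, int], path: str) -> bool:
    """Best-effort 2-3 set Venn rendering with plain matplotlib circles.

    Returns False (counts table remains the artifact) for 4-5 sets.
    """
    names = sorted({n for region in counts for n in region})
    if len(names) > 3:
        return False
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    centers = {2: [(-0.5, 0), (0.5, 0)],
               3: [(-0.5, -0.3), (0.5, -0.3), (0.0, 0.6)]}[len(names)]
    for (x, y), name in zip(centers, names):
        ax.add_patch(plt.Circle((x, y), 1.0, alpha=0.3, label=name))
        ax.annotate(name, (x, y + 1.05), ha="center")
    label_pos = _venn_label_positions(names, centers)
    for region, count in counts.items():
        x, y = label_pos[region]
        ax.annotate(str(count), (x, y), ha="center", va="center")
    ax.set_xlim(-2.2, 2.2)
    ax.set_ylim(-2.2, 2.2)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return True


def _venn_label_positions(names, centers):
    import numpy as np
    pos = {}
    regions = [frozenset(c) for r in range(1, len(names) + 1)
               for c in combinations(names, r)]
    for region in regions:
        inside = [np.array(centers[names.index(n)]) for n in region]
        outside = [np.array(centers[names.index(n)]) for n in names if n not in region]
        p = np.mean(inside, axis=0)
        for o in outside:
            p = p + 0.55 * (p - o) / (np.linalg.norm(p - o) + 1e-9)
        pos[region] = tuple(p)
    return pos
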