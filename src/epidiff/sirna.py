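"""siRNA length distributions, cluster calling and TE/methylation links.

Clusters are built by single-linkage over genomic proximity: reads on
the same contig whose end-to-start gap is below 100 bp join the same
raw cluster (strand-agnostic), and raw clusters are kept when they
carry at least 5 reads per million mapped and at least 10 distinct
read sequences.
"""
from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .types import GenomicInterval, SiRNACluster

logger = logging.getLogger("epidiff")


def length_distribution(reads: pd.DataFrame,
                        min_len: int = 18, max_len: int = 30) -> pd.Series:
    """Copy-weighted read-length histogram over ``min_len``..``max_len`` nt."""
    lengths = np.arange(min_len, max_len + 1)
    hist = pd.Series(0, index=lengths, dtype=np.int64, name="count")
    if len(reads):
        size = (reads["end"] - reads["start"]).to_numpy()
        copies = reads["copies"].to_numpy()
        keep = (size >= min_len) & (size <= max_len)
        np.add.at(hist.values, size[keep] - min_len, copies[keep])
    hist.index.name = "length"
    return hist


def compare_length_distributions(hist_a: pd.Series, hist_b: pd.Series,
                                 min_expected: float = 5.0):
    """Pearson chi-squared comparison of two length histograms.

    Builds the 2 x k contingency table of copy-weighted counts; tail
    bins whose expected count falls below ``min_expected`` are pooled
    into their inner neighbour so the asymptotic test stays valid.
    Returns (chi2, df, p).
    """
    if not hist_a.index.equals(hist_b.index):
        raise ValueError("histograms must share the same bins")
    if hist_a.sum() == 0 or hist_b.sum() == 0:
        raise ValueError("a sample has zero reads")
    table = np.vstack([hist_a.to_numpy(float), hist_b.to_numpy(float)])
    table = _pool_sparse_tails(table, min_expected)
    if table.shape[1] < 2:
        raise ValueError("fewer than two informative bins after pooling")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def _pool_sparse_tails(table: np.ndarray, min_expected: float) -> np.ndarray:
    """Pool bins from both tails inward until expected counts pass."""
    def expected(t):
        return np.outer(t.sum(1), t.sum(0)) / t.sum()

    t = table[:, table.sum(0) > 0]  # drop empty columns outright
    while t.shape[1] > 2 and expected(t)[:, 0].min() < min_expected:
        t = np.hstack([(t[:, 0] + t[:, 1])[:, None], t[:, 2:]])
    while t.shape[1] > 2 and expected(t)[:, -1].min() < min_expected:
        t = np.hstack([t[:, :-2], (t[:, -2] + t[:, -1])[:, None]])
    return t


def call_clusters(reads: pd.DataFrame, total_mapped: int,
                  gap: int = 100, min_rpm: float = 5.0,
                  min_distinct: int = 10) -> list[SiRNACluster]:
    """Call siRNA clusters from collapsed reads.

    Raw clusters are maximal runs of reads where each read starts less
    than ``gap`` bp after the furthest end seen so far on its contig
    (strict inequality, strand-agnostic).  A raw cluster is kept when
    its abundance reaches ``min_rpm`` reads per million mapped and it
    contains at least ``min_distinct`` distinct sequences.  Filtering
    removes whole clusters, never splits them.
    """
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    if reads["copies"].sum() > total_mapped:
        raise ValueError("total_mapped smaller than summed read copies")
    clusters: list[SiRNACluster] = []
    df = reads.sort_values(["contig", "start", "end"], kind="stable")
    for contig, grp in df.groupby("contig", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        copies = grp["copies"].to_numpy()
        seqs = grp["sequence"].to_numpy()
        run_start = 0
        run_end = ends[0]
        for i in range(1, len(grp) + 1):
            if i < len(grp) and starts[i] - run_end < gap:
                run_end = max(run_end, ends[i])
                continue
            sl = slice(run_start, i)
            total = int(copies[sl].sum())
            cluster = SiRNACluster(
                interval=GenomicInterval(
                    contig, int(starts[sl].min()), int(ends[sl].max())),
                total_reads=total,
                distinct_reads=int(pd.unique(seqs[sl]).size),
                rpm=total / (total_mapped / 1e6),
            )
            clusters.append(cluster)
            if i < len(grp):
                run_start, run_end = i, ends[i]
    kept = [c for c in clusters
            if c.rpm >= min_rpm and c.distinct_reads >= min_distinct]
    logger.info("call_clusters: %d raw clusters, %d pass rpm>=%g and "
                "distinct>=%d", len(clusters), len(kept), min_rpm,
                min_distinct)
    return kept


def raw_clusters(reads: pd.DataFrame, total_mapped: int,
                 gap: int = 100) -> list[SiRNACluster]:
    """Cluster calling without the abundance filters (for bookkeeping)."""
    return call_clusters(reads, total_mapped, gap=gap, min_rpm=0.0,
                         min_distinct=0)


def cluster_te_overlap(clusters: list[SiRNACluster], tes: pd.DataFrame):
    """Bidirectional overlap of siRNA clusters with TEs (>= 1 shared bp).

    Returns (fraction of clusters on a TE, fraction of TEs hit,
    per-cluster flags); the second fraction is NaN when no TEs exist.
    Also sets ``te_overlap`` on each cluster in place.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, row in enumerate(tes.itertuples(index=False)):
        trees.setdefault(row.contig, IntervalTree()).addi(
            row.start, row.end, idx)
    flags = []
    hit_tes: set[int] = set()
    for c in clusters:
        tree = trees.get(c.interval.contig)
        hits = (tree.overlap(c.interval.start, c.interval.end)
                if tree is not None else set())
        c.te_overlap = bool(hits)
        flags.append(c.te_overlap)
        hit_tes.update(h.data for h in hits)
    frac_clusters = (sum(flags) / len(flags)) if flags else float("nan")
    if len(tes) == 0:
        logger.warning("cluster_te_overlap: no TEs supplied")
        frac_tes = float("nan")
    else:
        frac_tes = len(hit_tes) / len(tes)
    return frac_clusters, frac_tes, flags


def annotate_region_kind(clusters: list[SiRNACluster], genes: pd.DataFrame,
                         tes: pd.DataFrame) -> None:
    """Label each cluster TE / genic / intergenic (TE takes precedence)."""
    trees: dict[tuple[str, str], IntervalTree] = {}
    for label, feats in (("TE", tes), ("genic", genes)):
        for row in feats.itertuples(index=False):
            trees.setdefault((label, row.contig), IntervalTree()).addi(
                row.start, row.end)
    for c in clusters:
        c.region_kind = "intergenic"
        for label in ("TE", "genic"):
            tree = trees.get((label, c.interval.contig))
            if tree is not None and tree.overlap(c.interval.start,
                                                 c.interval.end):
                c.region_kind = label
                break


def pooled_region_level(levels: pd.DataFrame, contig: str, start: int,
                        end: int, context: str = "CG") -> Optional[float]:
    """Pooled methylation level of covered sites inside one interval."""
    sub = levels[(levels["contig"] == contig)
                 & (levels["context"] == context)
                 & (levels["position"] >= start)
                 & (levels["position"] < end)]
    total = sub["meth"].sum() + sub["unmeth"].sum()
    return float(sub["meth"].sum() / total) if total else None


def cluster_methylation_contrast(clusters: list[SiRNACluster],
                                 genes: pd.DataFrame,
                                 levels: pd.DataFrame,
                                 flank: int = 1000,
                                 context: str = "CG"):
    """Methylation of genic regions with vs without siRNA clusters.

    A genic region is the gene body extended by ``flank`` bp on both
    sides; its level pools covered CG counts.  Returns a dict with the
    two groups' levels and the two-sided Mann-Whitney U and p (NaN and
    a warning when a group has under 3 members), plus per-region-kind
    mean cluster methylation set on each cluster (``mcg_level``).
    """
    ctrees: dict[str, IntervalTree] = {}
    for c in clusters:
        ctrees.setdefault(c.interval.contig, IntervalTree()).addi(
            c.interval.start, c.interval.end)

    cg = levels[levels["context"] == context]
    by_contig = {}
    for contig, grp in cg.groupby("contig", sort=False):
        pos = grp["position"].to_numpy()
        order = np.argsort(pos, kind="stable")
        meth = grp["meth"].to_numpy()[order]
        tot = meth + grp["unmeth"].to_numpy()[order]
        by_contig[contig] = (pos[order],
                             np.concatenate([[0], np.cumsum(meth)]),
                             np.concatenate([[0], np.cumsum(tot)]))

    def pooled(contig, start, end):
        if contig not in by_contig:
            return None
        pos, cm, ct = by_contig[contig]
        lo, hi = np.searchsorted(pos, [start, end])
        tot = ct[hi] - ct[lo]
        return float((cm[hi] - cm[lo]) / tot) if tot else None

    with_cluster, without_cluster = [], []
    for row in genes.itertuples(index=False):
        start = max(row.start - flank, 0)
        end = row.end + flank
        lvl = pooled(row.contig, start, end)
        if lvl is None:
            continue
        tree = ctrees.get(row.contig)
        overlaps = tree is not None and bool(tree.overlap(start, end))
        (with_cluster if overlaps else without_cluster).append(lvl)

    for c in clusters:
        c.mcg_level = pooled(c.interval.contig, c.interval.start,
                             c.interval.end)

    if min(len(with_cluster), len(without_cluster)) < 3:
        logger.warning("cluster_methylation_contrast: a group has fewer "
                       "than 3 regions, p undefined")
        u, p = float("nan"), float("nan")
    else:
        u, p = stats.mannwhitneyu(with_cluster, without_cluster,
                                  alternative="two-sided")
    return {
        "with_cluster": np.asarray(with_cluster),
        "without_cluster": np.asarray(without_cluster),
        "U": float(u), "p": float(p),
    }
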