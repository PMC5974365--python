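"""Methylation-expression links: flanking-TE categories and correlation.

Genes are grouped by where TEs sit within 1 kb of their boundaries
(upstream/downstream, strand-oriented) and the groups are compared for
expression and methylation; region-wise methylation is correlated with
log-expression across genes.
"""
from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger("epidiff")

CATEGORIES = ("TE_TE", "TE_non", "non_TE", "non_non")
REGIONS = ("upstream", "body", "downstream")


def _te_trees(tes: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in tes.itertuples(index=False):
        trees.setdefault(row.contig, IntervalTree()).addi(row.start, row.end)
    return trees


def _flank_windows(start: int, end: int, strand: str, flank: int):
    """Strand-oriented (upstream, downstream) windows of one gene."""
    left = (max(start - flank, 0), start)
    right = (end, end + flank)
    return (left, right) if strand != "-" else (right, left)


def flank_category(gene_start: int, gene_end: int, strand: str,
                   te_tree: IntervalTree | None, flank: int = 1000) -> str:
    """TE-flanking category of one gene: TE_TE / TE_non / non_TE / non_non.

    Naming order is (upstream, downstream); a TE counts when it shares
    at least one bp with the flank window.  Flanks truncated at contig
    edges are used as-is.
    """
    (u0, u1), (d0, d1) = _flank_windows(gene_start, gene_end, strand, flank)
    has = []
    for lo, hi in ((u0, u1), (d0, d1)):
        has.append(bool(te_tree is not None and lo < hi
                        and te_tree.overlap(lo, hi)))
    up, down = has
    if up and down:
        return "TE_TE"
    if up:
        return "TE_non"
    if down:
        return "non_TE"
    return "non_non"


def gene_methylation_profiles(genes: pd.DataFrame, tes: pd.DataFrame,
                              levels: pd.DataFrame,
                              expression: pd.DataFrame,
                              flank: int = 1000,
                              context: str = "CG") -> pd.DataFrame:
    """Per-gene methylation/flanking-TE/expression profile table.

    Methylation levels pool covered CG counts over the 1 kb-upstream,
    body and 1 kb-downstream regions (strand-oriented); NaN when a
    region has no covered site.  ``flank_te_meth`` pools CG counts over
    the TE bp inside either flank.  Genes without an expression record
    get NaN FPKM.
    """
    trees = _te_trees(tes)
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

    def pooled(contig, spans):
        if contig not in by_contig:
            return float("nan")
        pos, cm, ct = by_contig[contig]
        m = t = 0
        for lo, hi in spans:
            if lo >= hi:
                continue
            i0, i1 = np.searchsorted(pos, [lo, hi])
            m += cm[i1] - cm[i0]
            t += ct[i1] - ct[i0]
        return m / t if t else float("nan")

    fpkm = expression.set_index("gene_id")["fpkm"]
    rows = []
    for row in genes.itertuples(index=False):
        tree = trees.get(row.contig)
        up, down = _flank_windows(row.start, row.end, row.strand, flank)
        te_spans = []
        for lo, hi in (up, down):
            if tree is not None and lo < hi:
                for hit in tree.overlap(lo, hi):
                    te_spans.append((max(hit.begin, lo), min(hit.end, hi)))
        rows.append({
            "gene_id": row.id,
            "upstream_level": pooled(row.contig, [up]),
            "body_level": pooled(row.contig, [(row.start, row.end)]),
            "downstream_level": pooled(row.contig, [down]),
            "flank_category": flank_category(row.start, row.end, row.strand,
                                             tree, flank),
            "flank_te_meth": pooled(row.contig, te_spans)
            if te_spans else float("nan"),
            "fpkm": float(fpkm.get(row.id, float("nan"))),
        })
    return pd.DataFrame(rows)


def category_contrasts(profiles: pd.DataFrame, min_group: int = 3) -> dict:
    """Mann-Whitney contrasts of each TE-flanked category against non_non.

    Tested separately for expression (FPKM) and gene-body methylation.
    Returns {category: {variable: {U, p, n, median, ref_n, ref_median}}};
    comparisons with an undersized group are flagged with NaN p.
    """
    out: dict = {}
    ref = profiles[profiles["flank_category"] == "non_non"]
    for cat in ("TE_TE", "TE_non", "non_TE"):
        grp = profiles[profiles["flank_category"] == cat]
        out[cat] = {}
        for var in ("fpkm", "body_level"):
            x = grp[var].dropna()
            y = ref[var].dropna()
            entry = {
                "n": int(len(x)), "ref_n": int(len(y)),
                "median": float(x.median()) if len(x) else float("nan"),
                "ref_median": float(y.median()) if len(y) else float("nan"),
            }
            if len(x) < min_group or len(y) < min_group:
                logger.warning("category_contrasts: %s/%s skipped "
                               "(undersized group)", cat, var)
                entry.update(U=float("nan"), p=float("nan"))
            else:
                u, p = stats.mannwhitneyu(x, y, alternative="two-sided")
                entry.update(U=float(u), p=float(p))
            out[cat][var] = entry
    return out


def methylation_expression_correlation(profiles: pd.DataFrame,
                                       region: str = "body",
                                       log_transform: bool = True,
                                       method: str = "pearson",
                                       n_bins: int = 10):
    """Correlation of region methylation with expression across genes.

    Expression enters as log2(FPKM+1) by default.  Besides (r, p), the
    genes are binned by methylation level — a zero-methylation bin plus
    deciles of the positive levels — with per-bin mean expression for
    reporting.  Requires >= 10 genes with both values defined.
    """
    if region not in REGIONS:
        raise ValueError(f"region must be one of {REGIONS}")
    col = f"{region}_level"
    df = profiles.dropna(subset=[col, "fpkm"]).copy()
    if len(df) < 10:
        raise ValueError("need >= 10 genes with defined methylation and "
                         "expression")
    expr = np.log2(df["fpkm"] + 1) if log_transform else df["fpkm"]
    meth = df[col]
    if method == "pearson":
        r, p = stats.pearsonr(meth, expr)
    elif method == "spearman":
        r, p = stats.spearmanr(meth, expr)
    else:
        raise ValueError(f"unknown correlation method {method!r}")

    zero = meth == 0
    bins = pd.Series(np.zeros(len(df), dtype=int), index=df.index)
    pos = meth[~zero]
    if len(pos):
        ranks = pos.rank(method="first") - 1
        bins.loc[~zero] = 1 + np.minimum(
            (ranks * n_bins // max(len(pos), 1)).astype(int), n_bins - 1)
    binned = (pd.DataFrame({"bin": bins, "meth": meth, "expr": expr})
              .groupby("bin")
              .agg(mean_meth=("meth", "mean"), mean_expr=("expr", "mean"),
                   n=("expr", "size"))
              .reset_index())
    return float(r), float(p), binned
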