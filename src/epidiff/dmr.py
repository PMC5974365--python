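"""Differentially methylated region (DMR) calling on synteny blocks.

Each synteny block is tiled into 200 bp windows advanced in 100 bp
steps; within each window the pooled CG counts of the two species are
compared by an exact binomial test, p-values are corrected by
Benjamini-Hochberg FDR, and overlapping significant windows of the same
direction are merged into DMRs, which are then classified as genic,
repeat or intergenic.
"""
from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .types import DMR, GenomicInterval, MethWindow, SyntenyBlock

logger = logging.getLogger("epidiff")

TEST_METHODS = ("binom_pooled", "binom_vs_other", "fisher")


def tile_windows(block: SyntenyBlock, size: int = 200,
                 step: int = 100) -> list[MethWindow]:
    """Sliding windows over one synteny block, paired across species.

    Windows start at offsets 0, step, 2*step, ...; only full windows
    are emitted, so a block shorter than ``size`` yields none.  For
    inverted blocks the B-side window mirrors the A-side offset.
    """
    length = len(block)
    if length < size:
        logger.info("block %s shorter than window size, skipped", block.id)
        return []
    n_win = (length - size) // step + 1
    a, b = block.interval_a, block.interval_b
    out = []
    for k in range(n_win):
        off = k * step
        wa = GenomicInterval(a.contig, a.start + off, a.start + off + size)
        if block.orientation == "same":
            wb = GenomicInterval(b.contig, b.start + off,
                                 b.start + off + size)
        else:
            wb = GenomicInterval(b.contig, b.end - off - size, b.end - off)
        out.append(MethWindow(block_id=block.id, interval_a=wa,
                              interval_b=wb))
    return out


def window_test(meth_a: int, unmeth_a: int, meth_b: int, unmeth_b: int,
                method: str = "binom_pooled") -> float:
    """Two-sided test of differential methylation in one window.

    ``binom_pooled`` (default): exact binomial test of species A's
    methylated count against the level pooled over both species.  This
    keeps the null calibrated when both species' counts are noisy
    estimates, at the price of some conservatism.

    ``binom_vs_other``: exact binomial test of A's counts against B's
    observed level, the most literal two-sample reduction; it ignores
    sampling noise in B and is anti-conservative under the null.

    ``fisher``: Fisher's exact test on the 2x2 count table.
    """
    n_a = meth_a + unmeth_a
    n_b = meth_b + unmeth_b
    if n_a == 0 or n_b == 0:
        raise ValueError("window_test: empty counts")
    if method == "fisher":
        return float(stats.fisher_exact(
            [[meth_a, unmeth_a], [meth_b, unmeth_b]])[1])
    if method == "binom_pooled":
        denom = n_a + n_b
        p0 = (meth_a + meth_b) / denom
    elif method == "binom_vs_other":
        denom = n_b
        p0 = meth_b / n_b
    else:
        raise ValueError(f"unknown test method {method!r}")
    if p0 <= 0.0 or p0 >= 1.0:
        # degenerate reference level: clamp so the test stays defined
        lo = 1.0 / (2 * denom)
        clamped = min(max(p0, lo), 1.0 - lo)
        logger.debug("window_test: reference level %g clamped to %g",
                     p0, clamped)
        p0 = clamped
    return float(stats.binomtest(meth_a, n_a, p0).pvalue)


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fill_window_counts(windows: list[MethWindow],
                       levels_a: pd.DataFrame, levels_b: pd.DataFrame,
                       context: str = "CG") -> None:
    """Pool covered-site counts of one context into each paired window.

    ``levels_a``/``levels_b`` are coverage-filtered site tables from
    :func:`epidiff.methylome.site_levels` with 0-based positions.
    Counts are summed over both strands.
    """
    indexed = {}
    for tag, levels in (("a", levels_a), ("b", levels_b)):
        sub = levels[levels["context"] == context]
        for contig, grp in sub.groupby("contig", sort=False):
            pos = grp["position"].to_numpy()
            order = np.argsort(pos, kind="stable")
            pos = pos[order]
            meth = grp["meth"].to_numpy()[order]
            tot = meth + grp["unmeth"].to_numpy()[order]
            indexed[(tag, contig)] = (
                pos,
                np.concatenate([[0], np.cumsum(meth)]),
                np.concatenate([[0], np.cumsum(tot)]),
            )

    for side in ("a", "b"):
        ivals = [getattr(w, f"interval_{side}") for w in windows]
        starts = np.array([iv.start for iv in ivals])
        ends = np.array([iv.end for iv in ivals])
        contigs = np.array([iv.contig for iv in ivals])
        for contig in np.unique(contigs):
            key = (side, contig)
            sel = np.flatnonzero(contigs == contig)
            if key not in indexed:
                continue
            pos, cmeth, ctot = indexed[key]
            lo = np.searchsorted(pos, starts[sel])
            hi = np.searchsorted(pos, ends[sel])
            meths = cmeth[hi] - cmeth[lo]
            tots = ctot[hi] - ctot[lo]
            for i, wi in enumerate(sel):
                w = windows[wi]
                setattr(w, f"meth_{side}", int(meths[i]))
                setattr(w, f"unmeth_{side}", int(tots[i] - meths[i]))
                setattr(w, f"sites_{side}", int(hi[i] - lo[i]))


def test_windows(windows: list[MethWindow], min_sites: int = 4,
                 method: str = "binom_pooled",
                 q_threshold: float = 0.05) -> list[MethWindow]:
    """Test eligible windows, attach BH q-values, return significant ones.

    Windows with fewer than ``min_sites`` covered CG sites in either
    species are skipped (not tested, not counted in the FDR).
    """
    tested = [w for w in windows
              if w.sites_a >= min_sites and w.sites_b >= min_sites]
    n_skipped = len(windows) - len(tested)
    if n_skipped:
        logger.info("test_windows: %d/%d windows below %d covered sites, "
                    "not tested", n_skipped, len(windows), min_sites)
    if not tested:
        return []
    pvals = [window_test(w.meth_a, w.unmeth_a, w.meth_b, w.unmeth_b,
                         method=method) for w in tested]
    qvals = bh_fdr(pvals)
    for w, p, q in zip(tested, pvals, qvals):
        w.p_value = float(p)
        w.q_value = float(q)
    sig = [w for w in tested
           if w.q_value < q_threshold and w.direction is not None]
    return sig


def merge_dmrs(windows: Iterable[MethWindow]) -> list[DMR]:
    """Merge overlapping/book-ended same-direction windows into DMRs.

    Windows of opposite direction are never merged even when they
    overlap (both DMRs are emitted; the overlap is logged).  Every
    input window ends up in exactly one DMR of its direction.
    """
    dmrs: list[DMR] = []
    by_dir: dict[str, list[MethWindow]] = {}
    for w in windows:
        if w.direction is None:
            continue
        by_dir.setdefault(w.direction, []).append(w)
    for direction, group in by_dir.items():
        group.sort(key=lambda w: (w.interval_a.contig, w.interval_a.start))
        run: list[MethWindow] = []
        for w in group:
            if (run and w.interval_a.contig == run[-1].interval_a.contig
                    and w.interval_a.start <= _run_end(run)):
                run.append(w)
            else:
                if run:
                    dmrs.append(_finish_run(run, direction))
                run = [w]
        if run:
            dmrs.append(_finish_run(run, direction))
    # report opposite-direction overlaps
    for i, d1 in enumerate(dmrs):
        for d2 in dmrs[i + 1:]:
            if d1.direction != d2.direction and d1.interval_a.overlaps(
                    d2.interval_a):
                logger.info("merge_dmrs: opposite-direction DMRs overlap "
                            "at %s:%d-%d", d1.interval_a.contig,
                            d2.interval_a.start, d1.interval_a.end)
    dmrs.sort(key=lambda d: (d.interval_a.contig, d.interval_a.start))
    return dmrs


def _run_end(run: list[MethWindow]) -> int:
    return max(w.interval_a.end for w in run)


def _finish_run(run: list[MethWindow], direction: str) -> DMR:
    contig_a = run[0].interval_a.contig
    contig_b = run[0].interval_b.contig
    ia = GenomicInterval(contig_a, min(w.interval_a.start for w in run),
                         max(w.interval_a.end for w in run))
    ib = GenomicInterval(contig_b, min(w.interval_b.start for w in run),
                         max(w.interval_b.end for w in run))
    return DMR(interval_a=ia, interval_b=ib, direction=direction,
               n_windows=len(run),
               min_q=min(w.q_value for w in run))


def classify_dmrs(dmrs: list[DMR], genes: pd.DataFrame, tes: pd.DataFrame,
                  flank: int = 1000,
                  precedence: tuple[str, ...] = ("genic", "repeat")) -> None:
    """Assign each DMR a category from species-A annotations, in place.

    Genic means overlapping a gene body extended by ``flank`` bp on both
    sides; repeat means overlapping a TE; anything else is intergenic.
    With the default precedence a DMR touching both a gene region and a
    TE counts as genic.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for label, feats, pad in (("genic", genes, flank), ("repeat", tes, 0)):
        for row in feats.itertuples(index=False):
            key = (label, row.contig)
            trees.setdefault(key, IntervalTree()).addi(
                max(row.start - pad, 0), row.end + pad)
    for d in dmrs:
        d.category = "intergenic"
        for label in precedence:
            tree = trees.get((label, d.interval_a.contig))
            if tree is not None and tree.overlap(d.interval_a.start,
                                                 d.interval_a.end):
                d.category = label
                break


def direction_bias_test(dmrs: list[DMR]):
    """Fisher exact test for direction bias among genic DMRs.

    Builds the 2x2 table direction (hyper in A / hyper in B) x category
    (genic / non-genic) and returns (table, p).  Degenerate margins
    give p = NaN, flagged in the log.
    """
    table = np.zeros((2, 2), dtype=int)
    for d in dmrs:
        i = 0 if d.direction == "hyper_in_A" else 1
        j = 0 if d.category == "genic" else 1
        table[i, j] += 1
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        logger.warning("direction_bias_test: degenerate margin, "
                       "p undefined")
        return table, float("nan")
    return table, float(stats.fisher_exact(table)[1])


# ---------------------------------------------------------------------------
# pipeline driver


def call_dmrs(blocks: Sequence[SyntenyBlock],
              levels_a: pd.DataFrame, levels_b: pd.DataFrame,
              config: PipelineConfig | None = None,
              method: str = "binom_pooled",
              context: str = "CG",
              genes_a: pd.DataFrame | None = None,
              tes_a: pd.DataFrame | None = None):
    """Run the full DMR stage: tile, count, test, merge, classify.

    Returns (windows dataframe, list of DMRs).  The dataframe holds
    every tiled window with its counts and, where tested, p/q values.
    """
    cfg = config or PipelineConfig()
    windows: list[MethWindow] = []
    for block in blocks:
        windows.extend(tile_windows(block, cfg.window_size, cfg.window_step))
    fill_window_counts(windows, levels_a, levels_b, context=context)
    sig = test_windows(windows, min_sites=cfg.min_sites, method=method,
                       q_threshold=cfg.q_threshold)
    dmrs = merge_dmrs(sig)
    if genes_a is not None and tes_a is not None:
        classify_dmrs(dmrs, genes_a, tes_a, flank=cfg.flank)
    return windows_to_frame(windows, cfg.q_threshold), dmrs


def windows_to_frame(windows: list[MethWindow],
                     q_threshold: float = 0.05) -> pd.DataFrame:
    rows = []
    for w in windows:
        rows.append({
            "block_id": w.block_id,
            "contig_a": w.interval_a.contig, "start_a": w.interval_a.start,
            "end_a": w.interval_a.end,
            "contig_b": w.interval_b.contig, "start_b": w.interval_b.start,
            "end_b": w.interval_b.end,
            "meth_a": w.meth_a, "unmeth_a": w.unmeth_a, "sites_a": w.sites_a,
            "meth_b": w.meth_b, "unmeth_b": w.unmeth_b, "sites_b": w.sites_b,
            "level_a": w.level_a, "level_b": w.level_b,
            "tested": w.p_value is not None,
            "p_value": w.p_value, "q_value": w.q_value,
            "significant": (w.p_value is not None
                            and w.q_value < q_threshold),
            "direction": w.direction,
        })
    return pd.DataFrame(rows)


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    return pd.DataFrame([{
        "contig_a": d.interval_a.contig, "start_a": d.interval_a.start,
        "end_a": d.interval_a.end,
        "contig_b": d.interval_b.contig, "start_b": d.interval_b.start,
        "end_b": d.interval_b.end,
        "direction": d.direction, "n_windows": d.n_windows,
        "min_q": d.min_q, "category": d.category,
    } for d in dmrs])
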