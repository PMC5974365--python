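"""Methylome profiling: context classification, site levels, genome
means, metagene profiles, bimodality, genome tracks and mCG-TE
co-localization.

Methylation levels come in two flavours throughout: the *site mean*
(unweighted mean of per-site levels, the default for genome-wide
summaries) and the *pooled* level (summed methylated reads over summed
reads, used for bins/windows where per-site coverage is low).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("epidiff")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def classify_context(seq: str, position: int, strand: str) -> Optional[str]:
    """Classify the cytosine at ``position`` (0-based) into CG/CHG/CHH.

    The base at (position, strand) must read C on that strand.  Returns
    ``None`` at contig edges (fewer than two strand-wise downstream
    bases) or when an ambiguity base (N) prevents classification.
    """
    if strand == "+":
        if seq[position] != "C":
            raise ValueError(f"base at +{position} is not C")
        down = seq[position + 1: position + 3]
    elif strand == "-":
        if seq[position] != "G":
            raise ValueError(f"base at -{position} is not C (G on +)")
        down = seq[max(position - 2, 0): position][::-1].translate(_COMPLEMENT)
    else:
        raise ValueError(f"invalid strand {strand!r}")
    if len(down) < 1 or down[0] == "N":
        return None
    if down[0] == "G":
        return "CG"
    if len(down) < 2 or down[1] == "N":
        return None
    return "CHG" if down[1] == "G" else "CHH"


def cytosine_sites(seq: str, contig: str = "contig") -> pd.DataFrame:
    """Enumerate every classifiable cytosine on both strands of ``seq``.

    Returns a frame with columns contig, position (0-based), strand,
    context, tri — vectorized equivalent of calling
    :func:`classify_context` at every C/G.
    """
    arr = np.frombuffer(seq.encode(), dtype="S1")
    n = len(arr)
    frames = []

    # plus strand: C at i, context from i+1, i+2
    pos = np.flatnonzero(arr == b"C")
    pos = pos[pos + 1 < n]
    nxt = arr[pos + 1]
    nxt2 = np.where(pos + 2 < n, arr[np.minimum(pos + 2, n - 1)], b"$")
    ctx = _context_codes(nxt, nxt2)
    keep = ctx != b""
    if keep.any():
        p = pos[keep]
        tri = (arr[p].astype("U1") + arr[p + 1].astype("U1")
               + np.where(p + 2 < n, arr[np.minimum(p + 2, n - 1)],
                          b"N").astype("U1"))
        frames.append(pd.DataFrame({
            "contig": contig, "position": p, "strand": "+",
            "context": ctx[keep].astype("U3"), "tri": tri}))

    # minus strand: G at i; strand-wise next bases are complements of
    # i-1, i-2 read rightward on the minus strand
    pos = np.flatnonzero(arr == b"G")
    pos = pos[pos - 1 >= 0]
    nxt = _complement_bytes(arr[pos - 1])
    nxt2 = np.where(pos - 2 >= 0,
                    _complement_bytes(arr[np.maximum(pos - 2, 0)]), b"$")
    ctx = _context_codes(nxt, nxt2)
    keep = ctx != b""
    if keep.any():
        p = pos[keep]
        t1 = _complement_bytes(arr[p]).astype("U1")
        t2 = _complement_bytes(arr[p - 1]).astype("U1")
        t3 = np.where(p - 2 >= 0,
                      _complement_bytes(arr[np.maximum(p - 2, 0)]),
                      b"N").astype("U1")
        frames.append(pd.DataFrame({
            "contig": contig, "position": p, "strand": "-",
            "context": ctx[keep].astype("U3"), "tri": t1 + t2 + t3}))

    if not frames:
        return pd.DataFrame(
            columns=["contig", "position", "strand", "context", "tri"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["position", "strand"], ignore_index=True)


def _complement_bytes(a: np.ndarray) -> np.ndarray:
    out = np.full(a.shape, b"N", dtype="S1")
    for x, y in ((b"A", b"T"), (b"C", b"G"), (b"G", b"C"), (b"T", b"A")):
        out[a == x] = y
    return out


def _context_codes(nxt: np.ndarray, nxt2: np.ndarray) -> np.ndarray:
    """Map strand-wise (next, next-next) bases to context labels.

    ``b"$"`` marks a missing base (contig edge); empty string means
    unclassifiable (edge or N).
    """
    ctx = np.full(nxt.shape, b"", dtype="S3")
    is_h = np.isin(nxt, [b"A", b"C", b"T"])
    ctx[nxt == b"G"] = b"CG"
    chg = is_h & (nxt2 == b"G")
    ctx[chg] = b"CHG"
    chh = is_h & np.isin(nxt2, [b"A", b"C", b"T"])
    ctx[chh] = b"CHH"
    return ctx


# ---------------------------------------------------------------------------
# site levels


def site_levels(records: pd.DataFrame, min_coverage: int = 5,
                merge_cg_strands: bool = False) -> pd.DataFrame:
    """Per-site methylation levels after the coverage filter.

    Sites with fewer than ``min_coverage`` reads are dropped.  With
    ``merge_cg_strands`` the two strands of each symmetric CG pair are
    summed into one record (position of the plus-strand C) before
    filtering.

    Input positions are 1-based (cytosine-report convention); the
    returned table carries 0-based positions, like every other
    in-memory coordinate.
    """
    df = records.assign(position=records["position"] - 1)
    if merge_cg_strands:
        cg = df[df["context"] == "CG"]
        rest = df[df["context"] != "CG"]
        key = np.where(cg["strand"] == "+", cg["position"],
                       cg["position"] - 1)
        merged = (cg.assign(pair_pos=key)
                  .groupby(["contig", "pair_pos"], as_index=False)
                  .agg(meth=("meth", "sum"), unmeth=("unmeth", "sum"),
                       tri=("tri", "first")))
        merged = merged.rename(columns={"pair_pos": "position"})
        merged["strand"] = "+"
        merged["context"] = "CG"
        df = pd.concat([merged[records.columns.intersection(merged.columns)],
                        rest], ignore_index=True)
    cov = df["meth"] + df["unmeth"]
    out = df.loc[cov >= min_coverage].copy()
    out["level"] = out["meth"] / (out["meth"] + out["unmeth"])
    return out.reset_index(drop=True)


def genome_mean_level(levels: pd.DataFrame, context: str | None = None,
                      weighted: bool = False) -> float:
    """Mean methylation level over covered sites of one context.

    Default is the unweighted mean of per-site levels; ``weighted``
    pools read counts instead (total methylated / total reads).
    Returns NaN when no covered site matches.
    """
    df = levels if context is None else levels[levels["context"] == context]
    if len(df) == 0:
        logger.warning("genome_mean_level: no covered sites (context=%s)",
                       context)
        return float("nan")
    if weighted:
        total = df["meth"].sum() + df["unmeth"].sum()
        return float(df["meth"].sum() / total)
    return float(df["level"].mean())


# ---------------------------------------------------------------------------
# metagene profiles


@dataclass
class MetageneProfile:
    """Pooled methylation around and along a set of features.

    Bin values are pooled counts (sum meth / sum reads per bin), laid
    out upstream flank -> scaled body (start to end of the feature) ->
    downstream flank, orientation-normalized by feature strand.
    """

    context: str
    feature_kind: str
    n_features: int
    flank: int
    meth: np.ndarray = field(repr=False)
    total: np.ndarray = field(repr=False)
    flank_bins: int = 10
    body_bins: int = 20

    @property
    def values(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.total > 0, self.meth / self.total, np.nan)

    @property
    def flank_bins_up(self) -> np.ndarray:
        return self.values[: self.flank_bins]

    @property
    def body_values(self) -> np.ndarray:
        return self.values[self.flank_bins: self.flank_bins + self.body_bins]

    @property
    def flank_bins_down(self) -> np.ndarray:
        return self.values[self.flank_bins + self.body_bins:]


def metagene_profile(levels: pd.DataFrame, features: pd.DataFrame,
                     flank: int = 1000, body_bins: int = 20,
                     flank_bins: int = 10,
                     context: str = "CG") -> MetageneProfile:
    """Average methylation within and around features of one kind.

    Features shorter than ``body_bins`` bp are excluded (logged); each
    bin pools methylated/total read counts over all mapped sites of all
    features, so low-coverage sites are weighted by their reads rather
    than each contributing a noisy level.
    """
    feats = features[(features["end"] - features["start"]) >= body_bins]
    n_short = len(features) - len(feats)
    if n_short:
        logger.info("metagene_profile: %d features shorter than %d bp "
                    "excluded", n_short, body_bins)
    if len(feats) == 0:
        raise ValueError("no qualifying features for metagene profile")
    kinds = feats["kind"].unique()
    if len(kinds) > 1:
        raise ValueError(f"features of mixed kinds {kinds}")

    df = levels[levels["context"] == context]
    total_bins = 2 * flank_bins + body_bins
    meth = np.zeros(total_bins)
    total = np.zeros(total_bins)
    flank_bin_w = flank / flank_bins

    for contig, sites in df.groupby("contig", sort=False):
        pos = sites["position"].to_numpy()
        order = np.argsort(pos)
        pos = pos[order]
        m = sites["meth"].to_numpy()[order]
        u = sites["unmeth"].to_numpy()[order]
        sub = feats[feats["contig"] == contig]
        for row in sub.itertuples(index=False):
            lo, hi = row.start - flank, row.end + flank
            i0, i1 = np.searchsorted(pos, [lo, hi])
            if i0 == i1:
                continue
            p = pos[i0:i1]
            idx = np.empty(len(p), dtype=np.int64)
            up = p < row.start
            down = p >= row.end
            body = ~up & ~down
            idx[up] = ((p[up] - lo) / flank_bin_w).astype(np.int64)
            length = row.end - row.start
            idx[body] = flank_bins + (
                (p[body] - row.start) * body_bins // length)
            idx[down] = (flank_bins + body_bins
                         + ((p[down] - row.end) / flank_bin_w).astype(
                             np.int64))
            if row.strand == "-":
                idx = total_bins - 1 - idx
            np.add.at(meth, idx, m[i0:i1])
            np.add.at(total, idx, m[i0:i1] + u[i0:i1])

    return MetageneProfile(context=context, feature_kind=str(kinds[0]),
                           n_features=len(feats), flank=flank,
                           meth=meth, total=total,
                           flank_bins=flank_bins, body_bins=body_bins)


# ---------------------------------------------------------------------------
# bimodality


def bimodality_summary(levels: np.ndarray | pd.Series,
                       low: float = 0.10, high: float = 0.80,
                       bin_width: float = 0.05):
    """Share of sites at the extremes of the level distribution.

    Returns (fraction below ``low``, fraction above ``high``, histogram
    counts over [0, 1] in ``bin_width`` bins).  CG site levels in fungi
    and plants are typically bimodal: most sites sit near 0 or near 1.
    """
    arr = np.asarray(levels, dtype=float)
    if arr.size == 0:
        raise ValueError("bimodality_summary: no sites")
    frac_low = float((arr < low).mean())
    frac_high = float((arr > high).mean())
    edges = np.arange(0, 1 + bin_width / 2, bin_width)
    hist, _ = np.histogram(arr, bins=edges)
    return frac_low, frac_high, hist


# ---------------------------------------------------------------------------
# genome tracks


def window_tracks(features: pd.DataFrame, levels: pd.DataFrame,
                  sirna_reads: pd.DataFrame | None,
                  contig_lengths: dict[str, int],
                  window: int = 10_000) -> pd.DataFrame:
    """Per-window feature content, pooled mCG level and siRNA coverage.

    Windows tile each contig without overlap (last window truncated).
    Gene/TE content is the covered-bp fraction; a feature spanning a
    boundary contributes to both windows proportionally.  Windows with
    no covered CG site get NaN methylation, never 0.
    """
    rows = []
    cg = levels[levels["context"] == "CG"]
    for contig, length in contig_lengths.items():
        n_win = max((length + window - 1) // window, 1)
        starts = np.arange(n_win) * window
        ends = np.minimum(starts + window, length)
        widths = (ends - starts).astype(float)

        cover = {}
        for kind in ("gene", "TE"):
            mask = np.zeros(length, dtype=bool)
            sub = features[(features["contig"] == contig)
                           & (features["kind"] == kind)]
            for row in sub.itertuples(index=False):
                mask[row.start:row.end] = True
            csum = np.concatenate([[0], np.cumsum(mask)])
            cover[kind] = (csum[ends] - csum[starts]) / widths

        meth = np.zeros(n_win)
        total = np.zeros(n_win)
        sub = cg[cg["contig"] == contig]
        if len(sub):
            widx = np.minimum(sub["position"].to_numpy() // window, n_win - 1)
            np.add.at(meth, widx, sub["meth"].to_numpy())
            np.add.at(total, widx,
                      (sub["meth"] + sub["unmeth"]).to_numpy())
        with np.errstate(invalid="ignore"):
            mcg = np.where(total > 0, meth / total, np.nan)

        sirna_bp = np.zeros(n_win)
        if sirna_reads is not None and len(sirna_reads):
            sub = sirna_reads[sirna_reads["contig"] == contig]
            for row in sub.itertuples(index=False):
                w0 = row.start // window
                w1 = (row.end - 1) // window
                for w in range(w0, min(w1, n_win - 1) + 1):
                    ov = (min(row.end, (w + 1) * window)
                          - max(row.start, w * window))
                    sirna_bp[w] += ov * row.copies

        rows.append(pd.DataFrame({
            "contig": contig, "start": starts, "end": ends,
            "gene_fraction": cover["gene"], "te_fraction": cover["TE"],
            "mcg_level": mcg, "sirna_coverage": sirna_bp / widths,
        }))
    return pd.concat(rows, ignore_index=True)


def colocalization(tracks: pd.DataFrame,
                   x: str = "mcg_level", y: str = "te_fraction"):
    """Spearman rank correlation between two window tracks.

    Measures the genome-wide co-localization of CG methylation with TE
    content.  Returns (rho, p); NaN rho when either track is constant.
    """
    df = tracks.dropna(subset=[x, y])
    if len(df) < 10:
        raise ValueError("colocalization needs >= 10 windows with data")
    if df[x].nunique() < 2 or df[y].nunique() < 2:
        logger.warning("colocalization: constant track, correlation "
                       "undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(df[x], df[y])
    return float(rho), float(p)
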