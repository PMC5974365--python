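"""File-to-file pipeline stages.

Each function reads standard-format inputs, runs the corresponding
library operations and writes deterministic TSV/BED outputs into
``out_dir``.  The command-line interface is a thin wrapper over these;
tests call them directly.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import dmr as dmr_mod
from . import expression as expr_mod
from . import io as eio
from . import ltr as ltr_mod
from . import methylome as meth_mod
from . import sirna as sirna_mod
from .config import PipelineConfig

logger = logging.getLogger("epidiff")

_FLOAT_FMT = "%.6g"


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_profile(cx_path, genes_path, tes_path, out_dir,
                config: PipelineConfig | None = None) -> dict:
    """Genome methylation summary: context means, metagenes, bimodality."""
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = eio.read_cytosine_report(cx_path)
    genes = eio.read_features(genes_path)
    tes = eio.read_features(tes_path)
    levels = meth_mod.site_levels(records, min_coverage=cfg.min_coverage)

    means = pd.DataFrame([
        {"context": ctx,
         "site_mean": meth_mod.genome_mean_level(levels, ctx),
         "weighted_mean": meth_mod.genome_mean_level(levels, ctx,
                                                     weighted=True),
         "n_sites": int((levels["context"] == ctx).sum())}
        for ctx in ("CG", "CHG", "CHH")])
    _write(means, out / "genome_means.tsv")

    cg = levels[levels["context"] == "CG"]
    frac_low, frac_high, hist = meth_mod.bimodality_summary(
        cg["level"].to_numpy(), cfg.bimodal_low, cfg.bimodal_high)
    _write(pd.DataFrame({"bin_start": np.arange(len(hist)) * 0.05,
                         "count": hist}), out / "bimodality_hist.tsv")
    _write(pd.DataFrame([{"fraction_low": frac_low,
                          "fraction_high": frac_high,
                          "n_sites": len(cg)}]),
           out / "bimodality.tsv")

    summary = {"means": means, "fraction_low": frac_low,
               "fraction_high": frac_high}
    for kind, feats in (("gene", genes[genes["kind"] == "gene"]),
                        ("TE", tes[tes["kind"] == "TE"])):
        prof = meth_mod.metagene_profile(
            levels, feats, flank=cfg.flank, body_bins=cfg.body_bins,
            flank_bins=cfg.flank_bins)
        vals = prof.values
        region = (["upstream"] * cfg.flank_bins + ["body"] * cfg.body_bins
                  + ["downstream"] * cfg.flank_bins)
        _write(pd.DataFrame({"bin": np.arange(len(vals)), "region": region,
                             "level": vals}),
               out / f"metagene_{kind}.tsv")
        summary[f"metagene_{kind}"] = prof
    return summary


def run_tracks(cx_path, genes_path, tes_path, fasta_path, out_dir,
               reads_path=None, config: PipelineConfig | None = None
               ) -> dict:
    """10 kb window tracks and mCG-TE co-localization."""
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = eio.read_cytosine_report(cx_path)
    genes = eio.read_features(genes_path)
    tes = eio.read_features(tes_path)
    lengths = {name: len(seq)
               for name, seq in eio.read_fasta(fasta_path).items()}
    reads = eio.read_sirna_reads(reads_path) if reads_path else None
    levels = meth_mod.site_levels(records, min_coverage=cfg.min_coverage)
    feats = pd.concat([genes, tes], ignore_index=True)
    tracks = meth_mod.window_tracks(feats, levels, reads, lengths,
                                    window=cfg.track_window)
    _write(tracks, out / "tracks.tsv")
    for col in ("gene_fraction", "te_fraction", "mcg_level",
                "sirna_coverage"):
        eio.write_bedgraph(
            tracks.rename(columns={col: "value"})[
                ["contig", "start", "end", "value"]],
            out / f"track_{col}.bedgraph")
    rho, p = meth_mod.colocalization(tracks)
    _write(pd.DataFrame([{"x": "mcg_level", "y": "te_fraction",
                          "spearman_rho": rho, "p_value": p,
                          "n_windows": int(tracks["mcg_level"]
                                           .notna().sum())}]),
           out / "colocalization.tsv")
    return {"tracks": tracks, "rho": rho, "p": p}


def run_dmr(synteny_path, cx_a_path, cx_b_path, out_dir,
            genes_a_path=None, tes_a_path=None,
            config: PipelineConfig | None = None,
            method: str = "binom_pooled") -> dict:
    """DMR calling between the two species over synteny blocks."""
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    blocks = eio.read_synteny(synteny_path)
    levels_a = meth_mod.site_levels(eio.read_cytosine_report(cx_a_path),
                                    min_coverage=cfg.min_coverage)
    levels_b = meth_mod.site_levels(eio.read_cytosine_report(cx_b_path),
                                    min_coverage=cfg.min_coverage)
    genes_a = eio.read_features(genes_a_path) if genes_a_path else None
    tes_a = eio.read_features(tes_a_path) if tes_a_path else None
    windows, dmrs = dmr_mod.call_dmrs(blocks, levels_a, levels_b,
                                      config=cfg, method=method,
                                      genes_a=genes_a, tes_a=tes_a)
    _write(windows, out / "dmr_windows.tsv")
    dmr_frame = dmr_mod.dmrs_to_frame(dmrs)
    _write(dmr_frame, out / "dmrs.tsv")
    if len(dmr_frame):
        bed = dmr_frame[["contig_a", "start_a", "end_a", "direction"]]
        bed.to_csv(out / "dmrs_A.bed", sep="\t", header=False, index=False)
    else:
        (out / "dmrs_A.bed").write_text("")
    table, fisher_p = dmr_mod.direction_bias_test(dmrs)
    counts = (dmr_frame.groupby(["category", "direction"])
              .size().reset_index(name="count")
              if len(dmr_frame) else
              pd.DataFrame(columns=["category", "direction", "count"]))
    _write(counts, out / "dmr_summary.tsv")
    _write(pd.DataFrame([{
        "n_windows": len(windows),
        "n_tested": int(windows["tested"].sum()) if len(windows) else 0,
        "n_significant": (int(windows["significant"].sum())
                          if len(windows) else 0),
        "n_dmrs": len(dmrs), "fisher_p": fisher_p,
        "genic_hyper_a": int(table[0, 0]),
        "genic_hyper_b": int(table[1, 0]),
    }]), out / "dmr_stats.tsv")
    return {"windows": windows, "dmrs": dmrs, "fisher_p": fisher_p}


def run_sirna(reads_path, total_mapped, out_dir, tes_path=None,
              genes_path=None, cx_path=None,
              config: PipelineConfig | None = None) -> dict:
    """siRNA length distribution, cluster calling and annotations."""
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reads = eio.read_sirna_reads(reads_path)
    hist = sirna_mod.length_distribution(reads)
    _write(hist.reset_index(), out / "length_hist.tsv")
    clusters = sirna_mod.call_clusters(
        reads, total_mapped, gap=cfg.cluster_gap,
        min_rpm=cfg.cluster_min_rpm,
        min_distinct=cfg.cluster_min_distinct)
    result = {"clusters": clusters, "length_hist": hist}
    if tes_path:
        tes = eio.read_features(tes_path)
        fc, ft, _ = sirna_mod.cluster_te_overlap(clusters, tes)
        result.update(frac_clusters_on_te=fc, frac_tes_hit=ft)
        if genes_path:
            genes = eio.read_features(genes_path)
            sirna_mod.annotate_region_kind(clusters, genes, tes)
            if cx_path:
                levels = meth_mod.site_levels(
                    eio.read_cytosine_report(cx_path),
                    min_coverage=cfg.min_coverage)
                contrast = sirna_mod.cluster_methylation_contrast(
                    clusters, genes, levels, flank=cfg.flank)
                _write(pd.DataFrame([{
                    "n_with_cluster": len(contrast["with_cluster"]),
                    "n_without_cluster": len(contrast["without_cluster"]),
                    "median_with": float(np.median(
                        contrast["with_cluster"]))
                    if len(contrast["with_cluster"]) else float("nan"),
                    "median_without": float(np.median(
                        contrast["without_cluster"]))
                    if len(contrast["without_cluster"]) else float("nan"),
                    "U": contrast["U"], "p": contrast["p"],
                }]), out / "sirna_contrast.tsv")
                result["contrast"] = contrast
        _write(pd.DataFrame([{
            "n_clusters": len(clusters),
            "frac_clusters_on_te": result.get("frac_clusters_on_te",
                                              float("nan")),
            "frac_tes_hit": result.get("frac_tes_hit", float("nan")),
        }]), out / "sirna_stats.tsv")
    cl = pd.DataFrame([{
        "contig": c.interval.contig, "start": c.interval.start,
        "end": c.interval.end, "total_reads": c.total_reads,
        "distinct_reads": c.distinct_reads, "rpm": c.rpm,
        "te_overlap": c.te_overlap, "region_kind": c.region_kind,
        "mcg_level": (c.mcg_level if c.mcg_level is not None
                      else float("nan")),
    } for c in clusters])
    _write(cl, out / "clusters.tsv")
    return result


def run_ltrage(pairs_path, out_dir, rate: float = 1.05e-9,
               bin_my: float = 1.0) -> dict:
    """Date LTR pairs and histogram their insertion ages."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pairs = ltr_mod.date_pairs_fasta(pairs_path, rate=rate)
    frame = ltr_mod.pairs_to_frame(pairs)
    _write(frame, out / "ltr_elements.tsv")
    hist, n_unest = ltr_mod.age_histogram(pairs, bin_my=bin_my)
    _write(hist, out / "ltr_age_hist.tsv")
    _write(pd.DataFrame([{"n_pairs": len(pairs),
                          "n_unestimable": n_unest,
                          "mean_age_my": float(np.nanmean(
                              frame["age_my"]))
                          if frame["estimable"].any() else float("nan")}]),
           out / "ltr_stats.tsv")
    return {"pairs": pairs, "hist": hist, "n_unestimable": n_unest}


def run_exprlink(genes_path, tes_path, cx_path, expr_path, out_dir,
                 config: PipelineConfig | None = None) -> dict:
    """Flanking-TE categories, contrasts and methylation-expression
    correlations."""
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes = eio.read_features(genes_path)
    tes = eio.read_features(tes_path)
    levels = meth_mod.site_levels(eio.read_cytosine_report(cx_path),
                                  min_coverage=cfg.min_coverage)
    expr = eio.read_expression(expr_path)
    profiles = expr_mod.gene_methylation_profiles(
        genes, tes, levels, expr, flank=cfg.flank)
    _write(profiles, out / "gene_profiles.tsv")
    contrasts = expr_mod.category_contrasts(profiles)
    rows = []
    for cat, per_var in contrasts.items():
        for var, entry in per_var.items():
            rows.append({"category": cat, "variable": var, **entry})
    _write(pd.DataFrame(rows), out / "category_contrasts.tsv")
    corr_rows, bins_frames = [], []
    for region in expr_mod.REGIONS:
        r, p, binned = expr_mod.methylation_expression_correlation(
            profiles, region=region)
        corr_rows.append({"region": region, "pearson_r": r, "p_value": p})
        bins_frames.append(binned.assign(region=region))
    _write(pd.DataFrame(corr_rows), out / "correlations.tsv")
    _write(pd.concat(bins_frames, ignore_index=True),
           out / "correlation_bins.tsv")
    return {"profiles": profiles, "contrasts": contrasts,
            "correlations": pd.DataFrame(corr_rows)}


def run_all(sim_dir, out_dir, config: PipelineConfig | None = None) -> None:
    """Run every analysis stage on a simulated dataset directory."""
    sim = Path(sim_dir)
    out = Path(out_dir)
    totals = json.loads((sim / "sirna_totals.json").read_text())
    run_profile(sim / "methylome_A.cx.tsv", sim / "genes_A.gff3",
                sim / "tes_A.gff3", out / "profile_A", config)
    run_tracks(sim / "methylome_A.cx.tsv", sim / "genes_A.gff3",
               sim / "tes_A.gff3", sim / "genome_A.fasta",
               out / "tracks_A", reads_path=sim / "sirna_A.bed",
               config=config)
    run_dmr(sim / "synteny.tsv", sim / "methylome_A.cx.tsv",
            sim / "methylome_B.cx.tsv", out / "dmr",
            genes_a_path=sim / "genes_A.gff3",
            tes_a_path=sim / "tes_A.gff3", config=config)
    run_sirna(sim / "sirna_A.bed", totals["A"], out / "sirna_A",
              tes_path=sim / "tes_A.gff3", genes_path=sim / "genes_A.gff3",
              cx_path=sim / "methylome_A.cx.tsv", config=config)
    run_ltrage(sim / "ltr_pairs.fasta", out / "ltr")
    run_exprlink(sim / "genes_A.gff3", sim / "tes_A.gff3",
                 sim / "methylome_A.cx.tsv", sim / "fpkm_A.tsv",
                 out / "exprlink_A", config)
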