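"""Aggregate stage outputs into one run report with conservation checks.

The report is rebuilt purely from the stage output files, so every
number in it can be traced back to a TSV a stage wrote; re-running the
summary is idempotent.
"""
from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger("epidiff")

# stage -> (directory glob, files we summarize)
_STAGE_FILES = {
    "profile": ["genome_means.tsv", "bimodality.tsv"],
    "tracks": ["tracks.tsv", "colocalization.tsv"],
    "dmr": ["dmrs.tsv", "dmr_summary.tsv", "dmr_stats.tsv",
            "dmr_windows.tsv"],
    "sirna": ["clusters.tsv", "sirna_stats.tsv", "sirna_contrast.tsv"],
    "ltr": ["ltr_elements.tsv", "ltr_stats.tsv"],
    "exprlink": ["gene_profiles.tsv", "correlations.tsv"],
}


def _find(run_dir: Path, filename: str) -> Path | None:
    hits = sorted(run_dir.rglob(filename))
    return hits[0] if hits else None


def summarize(run_dir: str | Path) -> pd.DataFrame:
    """Build the run report table from whatever stage outputs exist.

    Returns a (section, metric, value) dataframe; missing stages are
    reported as explicit gaps rather than silently dropped.  Raises
    ``AssertionError`` when a conservation check fails (e.g. DMR
    category counts not summing to the DMR total).
    """
    run = Path(run_dir)
    rows: list[tuple[str, str, object]] = []

    def add(section, metric, value):
        rows.append((section, metric, value))

    path = _find(run, "genome_means.tsv")
    if path:
        means = pd.read_csv(path, sep="\t")
        for r in means.itertuples(index=False):
            add("methylome", f"mean_{r.context}", r.site_mean)
        bim = pd.read_csv(_find(run, "bimodality.tsv"), sep="\t")
        add("methylome", "cg_fraction_low", bim["fraction_low"][0])
        add("methylome", "cg_fraction_high", bim["fraction_high"][0])
    else:
        add("methylome", "status", "missing")

    path = _find(run, "colocalization.tsv")
    if path:
        coloc = pd.read_csv(path, sep="\t")
        add("tracks", "mcg_te_spearman_rho", coloc["spearman_rho"][0])
        add("tracks", "mcg_te_p", coloc["p_value"][0])
        tracks = pd.read_csv(_find(run, "tracks.tsv"), sep="\t")
        add("tracks", "n_windows", len(tracks))
    else:
        add("tracks", "status", "missing")

    path = _find(run, "dmrs.tsv")
    if path:
        dmrs = pd.read_csv(path, sep="\t")
        stats = pd.read_csv(_find(run, "dmr_stats.tsv"), sep="\t")
        summary = pd.read_csv(_find(run, "dmr_summary.tsv"), sep="\t")
        windows = pd.read_csv(_find(run, "dmr_windows.tsv"), sep="\t")
        assert int(stats["n_dmrs"][0]) == len(dmrs), \
            "DMR total in stats does not match dmrs.tsv"
        if len(summary):
            assert summary["count"].sum() == len(dmrs), \
                "DMR category counts do not sum to total"
        assert int(stats["n_windows"][0]) == len(windows), \
            "window count mismatch"
        add("dmr", "n_windows", len(windows))
        add("dmr", "n_tested", int(stats["n_tested"][0]))
        add("dmr", "n_significant_windows", int(stats["n_significant"][0]))
        add("dmr", "n_dmrs", len(dmrs))
        for r in summary.itertuples(index=False):
            add("dmr", f"n_{r.category}_{r.direction}", r.count)
        add("dmr", "direction_bias_fisher_p", stats["fisher_p"][0])
    else:
        add("dmr", "status", "missing")

    path = _find(run, "clusters.tsv")
    if path:
        clusters = pd.read_csv(path, sep="\t")
        add("sirna", "n_clusters", len(clusters))
        stats_path = _find(run, "sirna_stats.tsv")
        if stats_path:
            st = pd.read_csv(stats_path, sep="\t")
            assert int(st["n_clusters"][0]) == len(clusters), \
                "cluster count mismatch"
            add("sirna", "frac_clusters_on_te",
                st["frac_clusters_on_te"][0])
            add("sirna", "frac_tes_hit", st["frac_tes_hit"][0])
        contrast_path = _find(run, "sirna_contrast.tsv")
        if contrast_path:
            ct = pd.read_csv(contrast_path, sep="\t")
            add("sirna", "genic_meth_contrast_p", ct["p"][0])
    else:
        add("sirna", "status", "missing")

    path = _find(run, "ltr_elements.tsv")
    if path:
        elements = pd.read_csv(path, sep="\t")
        st = pd.read_csv(_find(run, "ltr_stats.tsv"), sep="\t")
        assert int(st["n_pairs"][0]) == len(elements), \
            "LTR pair count mismatch"
        add("ltr", "n_pairs", len(elements))
        add("ltr", "n_unestimable", int(st["n_unestimable"][0]))
        add("ltr", "mean_age_my", st["mean_age_my"][0])
    else:
        add("ltr", "status", "missing")

    path = _find(run, "correlations.tsv")
    if path:
        corr = pd.read_csv(path, sep="\t")
        profiles = pd.read_csv(_find(run, "gene_profiles.tsv"), sep="\t")
        add("exprlink", "n_genes", len(profiles))
        for r in corr.itertuples(index=False):
            add("exprlink", f"pearson_r_{r.region}", r.pearson_r)
            add("exprlink", f"pearson_p_{r.region}", r.p_value)
    else:
        add("exprlink", "status", "missing")

    return pd.DataFrame(rows, columns=["section", "metric", "value"])


def write_report(run_dir: str | Path, out_dir: str | Path | None = None
                 ) -> pd.DataFrame:
    """Write ``report.tsv`` and a human-readable ``report.txt``."""
    out = Path(out_dir) if out_dir else Path(run_dir)
    report = summarize(run_dir)
    report.to_csv(out / "report.tsv", sep="\t", index=False,
                  float_format="%.6g")
    lines = ["epidiff run report", "=" * 40]
    for section, grp in report.groupby("section", sort=False):
        lines.append(f"\n[{section}]")
        for r in grp.itertuples(index=False):
            val = (f"{r.value:.6g}" if isinstance(r.value, float)
                   else str(r.value))
            lines.append(f"  {r.metric}: {val}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return report
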