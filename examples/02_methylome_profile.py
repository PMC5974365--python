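"""Genome-wide methylation summaries on a synthetic methylome.

Computes per-context mean levels, the bimodality of CG site levels,
metagene profiles, and the co-localization of CG methylation with TE
content in 10 kb windows.
"""
import numpy as np
import pandas as pd

from epidiff import methylome as mm
from epidiff.simulate import SimulationConfig, simulate_dataset

data = simulate_dataset(SimulationConfig(
    n_contigs=1, contig_length=400_000, block_length=50_000,
    n_dmr=10, n_ltr=5), seed=2)
levels = mm.site_levels(data.cx_a, min_coverage=5)

for ctx in ("CG", "CHG", "CHH"):
    mean = mm.genome_mean_level(levels, ctx)
    print(f"mean m{ctx} level: {100 * mean:5.2f}%")
# CG methylation dominates; CHG/CHH stay near background, as in fungi.

cg = levels.loc[levels["context"] == "CG", "level"].to_numpy()
lo, hi, _ = mm.bimodality_summary(cg)
print(f"CG sites <10% methylated: {100 * lo:.1f}%, "
      f">80%: {100 * hi:.1f}%  (bimodal: {100 * (lo + hi):.1f}%)")

gene_prof = mm.metagene_profile(levels, data.genes_a)
te_prof = mm.metagene_profile(levels, data.tes_a)
print(f"metagene body level: genes {np.nanmean(gene_prof.body_values):.3f}"
      f" vs TEs {np.nanmean(te_prof.body_values):.3f}")

feats = pd.concat([data.genes_a, data.tes_a], ignore_index=True)
lengths = {c: len(s) for c, s in data.genome_a.items()}
tracks = mm.window_tracks(feats, levels, data.sirna_a, lengths)
rho, p = mm.colocalization(tracks)
print(f"mCG vs TE content across 10 kb windows: "
      f"Spearman rho = {rho:.2f} (p = {p:.2g})")
# A strongly positive rho means methylation concentrates where TEs are.
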