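"""siRNA cluster calling and transposon co-localization.

Reads closer than 100 bp join one raw cluster; clusters with >= 5 RPM
and >= 10 distinct sequences survive.  Their overlap with TEs and the
methylation of cluster-bearing genic regions mark RNA-directed DNA
methylation targets.
"""
from epidiff import sirna
from epidiff.methylome import site_levels
from epidiff.simulate import SimulationConfig, simulate_dataset

data = simulate_dataset(SimulationConfig(
    n_contigs=2, contig_length=500_000, block_length=50_000,
    n_dmr=10, n_ltr=5), seed=4)

hist = sirna.length_distribution(data.sirna_a)
peak = hist.loc[21:25].sum() / hist.sum()
print(f"siRNA length peak 21-25 nt: {100 * peak:.1f}% of read mass")

clusters = sirna.call_clusters(data.sirna_a, data.sirna_total_a)
fc, ft, _ = sirna.cluster_te_overlap(clusters, data.tes_a)
print(f"clusters called: {len(clusters)}")
print(f"clusters overlapping a TE: {100 * fc:.1f}%")
print(f"TEs hit by a cluster: {100 * ft:.1f}% "
      f"(targeted in truth: "
      f"{100 * len(data.truth.cluster_te_targets) / len(data.tes_a):.0f}%)")

levels = site_levels(data.cx_a, min_coverage=5)
res = sirna.cluster_methylation_contrast(clusters, data.genes_a, levels)
print(f"genic regions with/without clusters: "
      f"{len(res['with_cluster'])}/{len(res['without_cluster'])}, "
      f"Mann-Whitney p = {res['p']:.2g}")
# Cluster-bearing genic regions are the more methylated group.
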