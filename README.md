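# epidiff

Comparative methylome and small-RNA epigenomics between two closely
related fungal genomes, built as a reusable, fully testable pipeline.

Fungi such as the oyster-mushroom relatives carry DNA methylation that
is almost entirely CG-context, strongly bimodal at the site level
(sites sit below 10% or above 80% methylation), and concentrated in
transposable elements (TEs), where it silences both the elements and —
collaterally — neighboring genes. `epidiff` implements the analyses
used to compare two such methylomes:

* **Methylome profiling** — per-site levels from strand-resolved
  cytosine reports with a ≥5-read coverage floor, genome means per
  context (CG/CHG/CHH), metagene profiles around genes and TEs,
  site-level bimodality, 10 kb genome tracks, and Spearman
  co-localization of mCG with TE content.
* **DMR calling** — synteny blocks between the two species are tiled
  into 200 bp windows with 100 bp steps; pooled CG counts are compared
  by a two-sided exact binomial test, corrected by Benjamini–Hochberg
  FDR (q < 0.05); overlapping same-direction windows merge into
  differentially methylated regions, classified as genic (gene body
  ± 1 kb), repeat or intergenic, with a Fisher test for direction bias.
* **siRNA clusters** — reads closer than 100 bp join one raw cluster;
  clusters with ≥ 5 reads per million mapped and ≥ 10 distinct
  sequences survive; outputs include length distributions (chi-squared
  cross-species comparison), TE overlap in both directions, and
  Mann–Whitney contrasts of methylation in cluster-bearing vs
  cluster-free genic regions.
* **LTR insertion dating** — the Kimura 2-parameter distance of paired
  long terminal repeats,

      d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q),

  with transition proportion *P* and transversion proportion *Q*,
  converted to age = d / (2 × 1.05·10⁻⁹) years using the fungal
  neutral substitution rate.
* **Expression links** — genes categorized by TE presence in their
  1 kb flanks (TE_TE / TE_non / non_TE / non_non, strand-oriented),
  Mann–Whitney contrasts of FPKM across categories, and Pearson
  correlation of upstream/body/downstream methylation with
  log₂(FPKM + 1).
* **Synthetic data** — a seeded generator that emits a complete
  two-species dataset (FASTA, GFF3, synteny table, cytosine reports,
  siRNA reads, FPKM table, LTR pairs) with planted ground truth for
  every stage, so the whole pipeline runs and is scored without any
  download.

## Worked example

```bash
python examples/05_ltr_dating.py
```

```
element ltr_0000: P = 0.0244, Q = 0.0128, d = 0.0383, age = 18.2 MY
batch of 30: mean age 18.18 MY (planted 18.00 MY), sd 1.06
age histogram mode: [18, 19) MY with 13.0 elements; 0 saturated pairs excluded
```

Thirty LTR pairs were mutated under a K2P process to a total divergence
of 0.0378 substitutions/site — the divergence an element inserted 18
million years ago would accumulate at the fungal rate — and the
estimator recovers that age per element and in the batch mean.  The
other scripts in `examples/` walk through each capability the same way;
for instance `examples/06_expression_link.py` prints

```
median FPKM by flanking-TE category:
  non_non :   28.11  (n=254)
  TE_non  :    8.79  (n=45)
  non_TE  :    7.95  (n=32)
  TE_TE   :    8.62  (n=3)
upstream   methylation vs log2(FPKM+1): Pearson r = -0.26 (p = 2e-06)
body       methylation vs log2(FPKM+1): Pearson r = -0.50 (p = 1.8e-22)
downstream methylation vs log2(FPKM+1): Pearson r = -0.15 (p = 0.0075)
```

— TE-flanked genes are expressed several-fold lower than genes with
clean flanks, and methylation correlates negatively with expression in
all three gene regions, recovering the planted repression model.

A thin CLI mirrors the library for file-to-file runs:

```bash
epidiff simulate --out-dir sim/ --seed 7 --genome-size 1000000
epidiff dmr --synteny sim/synteny.tsv --cx-a sim/methylome_A.cx.tsv \
            --cx-b sim/methylome_B.cx.tsv --genes-a sim/genes_A.gff3 \
            --tes-a sim/tes_A.gff3 --out-dir out/dmr
epidiff report --run-dir out/
```

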