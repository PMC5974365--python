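"""Seeded synthetic dual-genome dataset with planted ground truth.

The generator emulates the statistical structure the downstream
analyses assume, without pretending to be a real genome:

* two species whose genomes are identical up to point substitutions
  inside equal-length synteny blocks;
* bimodal CG methylation — TE cytosines drawn from Beta(8, 2), genic
  and intergenic cytosines from Beta(1, 30) — and CHG/CHH methylation
  from Beta(1, 60), so CG >> CHG/CHH and methylation concentrates in
  TEs;
* planted differentially methylated 200 bp windows with known
  coordinates and directions;
* siRNA reads concentrated in dense runs over a chosen subset of TEs
  with a 21-25 nt length peak;
* per-gene FPKM generated from a log-linear model with negative
  coefficients on flanking-TE and gene-body CG methylation;
* LTR pairs mutated from a common ancestor under a Kimura 2-parameter
  process at known total divergence.

Everything is driven by a single integer seed through independent
numpy Generators per stage, so outputs are reproducible byte for byte.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import expm

from . import io as eio
from .methylome import cytosine_sites
from .types import GenomicInterval, SyntenyBlock

logger = logging.getLogger("epidiff")

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic dataset (defaults are the study conditions)."""

    n_contigs: int = 2
    contig_length: int = 5_000_000
    gc_content: float = 0.5
    gene_fraction: float = 0.50      # bp share of genes
    te_fraction: float = 0.20        # bp share of TEs
    gene_mean_length: int = 1500
    te_mean_length: int = 4000
    divergence: float = 0.03         # A->B substitution rate per site
    cg_preserving: bool = True       # do not mutate CG-dinucleotide bases
    block_length: int = 100_000      # synteny block tile

    # methylation mixture (beta parameters per compartment/context);
    # a minority of genes carry highly methylated bodies, mirroring the
    # bimodal genic methylation of real fungal genomes
    te_cg_beta: tuple = (8.0, 2.0)
    gene_cg_beta: tuple = (1.0, 40.0)
    intergenic_cg_beta: tuple = (1.0, 40.0)
    meth_gene_fraction: float = 0.15
    meth_gene_cg_beta: tuple = (12.0, 2.0)
    chg_beta: tuple = (1.0, 60.0)
    chh_beta: tuple = (1.0, 60.0)
    coverage: float = 20.0           # mean reads per site (Poisson)

    # planted DMRs
    n_dmr: int = 100
    dmr_window: int = 200
    dmr_level_high: float = 0.8
    dmr_level_low: float = 0.2

    # siRNA; total copies default to 0.02 per genome bp (200k at 10 Mb)
    sirna_total_copies: int | None = None
    sirna_te_read_fraction: float = 0.75
    sirna_cluster_te_fraction: float = 0.6
    sirna_length_range: tuple = (18, 30)
    # peak at 21-25 nt (~79% of mass)
    sirna_length_weights: tuple = (
        1, 1, 2, 8, 10, 12, 10, 8, 2, 1, 1, 1, 1)

    # expression model: log2(fpkm+1) =
    #   baseline - beta*flank_te_mcg - gamma*body_mcg + N(0, sd)
    expr_baseline: float = 5.0
    expr_beta_flank: float = 2.0
    expr_gamma_body: float = 2.0
    expr_noise_sd: float = 1.0

    # LTR pairs
    n_ltr: int = 50
    ltr_length: int = 1000
    ltr_d_mean: float = 0.0378       # 18 MY at 1.05e-9 subs/site/year
    ltr_d_sd: float = 0.002
    ltr_kappa: float = 2.0           # transition/transversion ratio

    @property
    def total_sirna_copies(self) -> int:
        if self.sirna_total_copies is not None:
            return self.sirna_total_copies
        return int(0.02 * self.n_contigs * self.contig_length)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimulationTruth:
    """Planted ground truth, sufficient to score every stage."""

    planted_dmrs: list = field(default_factory=list)
    ltr_true_divergences: dict = field(default_factory=dict)
    cluster_te_targets: list = field(default_factory=list)
    expression_model: dict = field(default_factory=dict)
    methylation_mixture: dict = field(default_factory=dict)
    coverage_rate: float = 0.0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2,
                          sort_keys=True)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    truth: SimulationTruth
    genome_a: dict
    genome_b: dict
    genes_a: pd.DataFrame
    tes_a: pd.DataFrame
    genes_b: pd.DataFrame
    tes_b: pd.DataFrame
    synteny: list
    cx_a: pd.DataFrame
    cx_b: pd.DataFrame
    sirna_a: pd.DataFrame
    sirna_b: pd.DataFrame
    sirna_total_a: int
    sirna_total_b: int
    expression_a: pd.DataFrame
    ltr_pairs: list  # (element_id, seq5, seq3)


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stage])


# ---------------------------------------------------------------------------
# genomes and annotations


def _random_sequence(rng, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return BASES[rng.choice(4, size=length, p=p)]


def _feature_lengths(rng, total_bp: int, mean_len: int,
                     min_len: int = 200) -> np.ndarray:
    n = max(int(round(total_bp / mean_len)), 1)
    raw = rng.gamma(4.0, mean_len / 4.0, size=n)
    raw = np.maximum(raw, min_len)
    lengths = np.round(raw * total_bp / raw.sum()).astype(np.int64)
    lengths = np.maximum(lengths, min_len)
    return lengths


def simulate_genomes(config: SimulationConfig, seed: int):
    """Species A genome + annotations, species B by point substitution.

    Genes and TEs are packed without overlap to the configured bp
    fractions; species B keeps coordinates (equal-length blocks), with
    substitutions optionally avoiding CG-dinucleotide bases so CG sites
    stay comparable across species.
    """
    rng = _rng(seed, 1)
    cfg = config
    genome_a, genome_b = {}, {}
    genes_rows, tes_rows = [], []
    blocks = []
    for ci in range(cfg.n_contigs):
        name_a, name_b = f"A_ctg{ci + 1}", f"B_ctg{ci + 1}"
        length = cfg.contig_length
        seq = _random_sequence(rng, length, cfg.gc_content)

        glens = _feature_lengths(rng, int(length * cfg.gene_fraction),
                                 cfg.gene_mean_length)
        tlens = _feature_lengths(rng, int(length * cfg.te_fraction),
                                 cfg.te_mean_length, min_len=400)
        feats = ([("gene", int(l)) for l in glens]
                 + [("TE", int(l)) for l in tlens])
        order = rng.permutation(len(feats))
        feats = [feats[i] for i in order]
        feat_bp = sum(l for _, l in feats)
        if feat_bp > 0.9 * length:
            raise ValueError("infeasible packing: gene+TE densities "
                             "exceed 90% of contig")
        gap_bp = length - feat_bp
        gaps = rng.multinomial(gap_bp, np.full(len(feats) + 1,
                                               1 / (len(feats) + 1)))
        pos = 0
        for (kind, flen), gap in zip(feats, gaps[:-1]):
            pos += int(gap)
            strand = "+" if rng.random() < 0.5 else "-"
            row = {"contig": name_a, "start": pos, "end": pos + flen,
                   "strand": strand, "kind": kind}
            if kind == "gene":
                row["id"] = f"gene_{name_a}_{len(genes_rows):05d}"
                genes_rows.append(row)
            else:
                row["id"] = f"te_{name_a}_{len(tes_rows):05d}"
                tes_rows.append(row)
            pos += flen

        # species B: point substitutions; CG-preserving mode neither
        # destroys nor creates CG dinucleotides, so CG sites stay
        # coordinate-matched across species
        seq_b = seq.copy()
        eligible = np.ones(length, dtype=bool)
        if cfg.cg_preserving:
            is_cg_start = (seq[:-1] == b"C") & (seq[1:] == b"G")
            cg_pos = np.flatnonzero(is_cg_start)
            eligible[cg_pos] = False
            eligible[cg_pos + 1] = False
        mut = np.flatnonzero((rng.random(length) < cfg.divergence)
                             & eligible)
        if mut.size:
            old_idx = np.searchsorted(BASES, seq[mut])
            shift = rng.integers(1, 4, size=mut.size)
            new = (old_idx + shift) % 4
            if cfg.cg_preserving:
                prev_c = np.zeros(mut.size, dtype=bool)
                prev_c[mut > 0] = seq[mut[mut > 0] - 1] == b"C"
                next_g = np.zeros(mut.size, dtype=bool)
                next_g[mut < length - 1] = seq[
                    mut[mut < length - 1] + 1] == b"G"
                for _ in range(8):  # resample until no CG is created
                    bad = ((prev_c & (new == 2))
                           | (next_g & (new == 1)))
                    if not bad.any():
                        break
                    new[bad] = (old_idx[bad]
                                + rng.integers(1, 4, size=int(bad.sum()))
                                ) % 4
                keep = ~((prev_c & (new == 2)) | (next_g & (new == 1)))
                mut, new = mut[keep], new[keep]
            seq_b[mut] = BASES[new]
            if cfg.cg_preserving:
                # adjacent substitutions can still pair into a fresh
                # CG; revert both members of any such dinucleotide
                is_cg_b = (seq_b[:-1] == b"C") & (seq_b[1:] == b"G")
                created = np.flatnonzero(is_cg_b & ~(
                    (seq[:-1] == b"C") & (seq[1:] == b"G")))
                if created.size:
                    seq_b[created] = seq[created]
                    seq_b[created + 1] = seq[created + 1]
        genome_a[name_a] = seq.tobytes().decode()
        genome_b[name_b] = seq_b.tobytes().decode()

        for bi, bstart in enumerate(range(0, length, cfg.block_length)):
            bend = min(bstart + cfg.block_length, length)
            blocks.append(SyntenyBlock(
                id=f"block_{name_a}_{bi:04d}",
                interval_a=GenomicInterval(name_a, bstart, bend),
                interval_b=GenomicInterval(name_b, bstart, bend),
            ))

    genes_a = pd.DataFrame(genes_rows, columns=eio.FEATURE_COLUMNS)
    tes_a = pd.DataFrame(tes_rows, columns=eio.FEATURE_COLUMNS)
    genes_b = genes_a.assign(
        contig=genes_a["contig"].str.replace("A_", "B_", regex=False),
        id=genes_a["id"].str.replace("_A_", "_B_", regex=False))
    tes_b = tes_a.assign(
        contig=tes_a["contig"].str.replace("A_", "B_", regex=False),
        id=tes_a["id"].str.replace("_A_", "_B_", regex=False))
    return genome_a, genome_b, genes_a, tes_a, genes_b, tes_b, blocks


def plant_dmrs(blocks, config: SimulationConfig, seed: int) -> list[dict]:
    """Choose planted DMR windows: aligned, non-adjacent, mixed direction."""
    rng = _rng(seed, 2)
    slots = []
    for b in blocks:
        n_slots = len(b) // (2 * config.dmr_window)
        for k in range(n_slots):
            slots.append((b.id, b.interval_a.contig,
                          b.interval_a.start + k * 2 * config.dmr_window))
    if config.n_dmr > len(slots):
        raise ValueError("not enough room for planted DMRs")
    chosen = rng.choice(len(slots), size=config.n_dmr, replace=False)
    planted = []
    for j, si in enumerate(sorted(chosen)):
        block_id, contig, start = slots[si]
        direction = "hyper_in_A" if j % 2 == 0 else "hyper_in_B"
        hi, lo = config.dmr_level_high, config.dmr_level_low
        planted.append({
            "block_id": block_id, "contig_a": contig,
            "start": int(start), "end": int(start + config.dmr_window),
            "direction": direction,
            "level_a": hi if direction == "hyper_in_A" else lo,
            "level_b": lo if direction == "hyper_in_A" else hi,
        })
    return planted


# ---------------------------------------------------------------------------
# methylome


def simulate_methylome(genome: dict, genes: pd.DataFrame, tes: pd.DataFrame,
                       config: SimulationConfig, seed: int,
                       planted: list[dict] | None = None,
                       species: str = "A",
                       meth_gene_idx: np.ndarray | None = None,
                       shared_cg: bool = False) -> pd.DataFrame:
    """Per-cytosine report for one species.

    Site methylation probabilities follow compartment beta mixtures;
    read coverage is Poisson; methylated counts binomial.  Genes whose
    positional index appears in ``meth_gene_idx`` use the
    body-methylated beta parameters (the class is shared across species
    so orthologs agree).  Planted DMR windows override the CG-site
    probability with the species' planted level (planted coordinates
    are shared across species because the blocks are colinear).

    With ``shared_cg`` the baseline CG probabilities come from a stream
    derived only from the seed and contig order, so the two species
    share their baseline CG methylome (requires CG-preserving
    substitutions) and planted windows are the only true differences.
    """
    rng = _rng(seed, 3 if species == "A" else 4)
    level_key = "level_a" if species == "A" else "level_b"
    meth_set = (set(meth_gene_idx.tolist())
                if meth_gene_idx is not None else set())
    frames = []
    for contig_i, (contig, seq) in enumerate(genome.items()):
        sites = cytosine_sites(seq, contig=contig)
        pos = sites["position"].to_numpy()

        compartment = np.zeros(len(seq), dtype=np.uint8)  # 0 intergenic
        sub = genes[genes["contig"] == contig]
        for gi, row in zip(sub.index, sub.itertuples(index=False)):
            compartment[row.start:row.end] = 3 if gi in meth_set else 1
        for row in tes[tes["contig"] == contig].itertuples(index=False):
            compartment[row.start:row.end] = 2
        comp = compartment[pos]

        ctx = sites["context"].to_numpy()
        a = np.empty(len(sites))
        b = np.empty(len(sites))
        cg = ctx == "CG"
        params = {0: config.intergenic_cg_beta, 1: config.gene_cg_beta,
                  2: config.te_cg_beta, 3: config.meth_gene_cg_beta}
        for c, (pa, pb) in params.items():
            m = cg & (comp == c)
            a[m], b[m] = pa, pb
        chg = ctx == "CHG"
        a[chg], b[chg] = config.chg_beta
        chh = ctx == "CHH"
        a[chh], b[chh] = config.chh_beta
        p = rng.beta(a, b)
        if shared_cg:
            cg_rng = _rng(seed, 20 + contig_i)
            p[cg] = cg_rng.beta(a[cg], b[cg])

        if planted:
            for w in planted:
                w_contig = w["contig_a"]
                if species == "B":
                    w_contig = w_contig.replace("A_", "B_", 1)
                if w_contig != contig:
                    continue
                m = cg & (pos >= w["start"]) & (pos < w["end"])
                p[m] = w[level_key]

        cov = rng.poisson(config.coverage, size=len(sites))
        meth = rng.binomial(cov, p)
        frames.append(pd.DataFrame({
            "contig": contig,
            "position": pos + 1,  # cytosine reports are 1-based
            "strand": sites["strand"].to_numpy(),
            "meth": meth,
            "unmeth": cov - meth,
            "context": ctx,
            "tri": sites["tri"].to_numpy(),
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# siRNA


def simulate_sirna(tes: pd.DataFrame, contig_lengths: dict,
                   config: SimulationConfig, seed: int, stage: int = 5):
    """Collapsed siRNA reads: dense runs over target TEs + background.

    Returns (reads dataframe, total mapped copies, target TE ids).
    """
    rng = _rng(seed, stage)
    lo, hi = config.sirna_length_range
    lweights = np.asarray(config.sirna_length_weights, dtype=float)
    lweights = lweights / lweights.sum()
    lengths_supported = np.arange(lo, hi + 1)

    n_targets = max(int(round(len(tes) * config.sirna_cluster_te_fraction)),
                    1)
    target_idx = np.sort(rng.choice(len(tes), size=n_targets, replace=False))
    targets = tes.iloc[target_idx]
    total_copies = config.total_sirna_copies
    te_copies = int(total_copies * config.sirna_te_read_fraction)
    bg_copies = total_copies - te_copies
    per_cluster = rng.multinomial(
        te_copies, np.full(n_targets, 1 / n_targets))

    rows = []
    for (row, copies) in zip(targets.itertuples(index=False), per_cluster):
        if copies == 0:
            continue
        n_distinct = min(10 + rng.poisson(20), copies)
        anchor = int(rng.integers(row.start, row.end))
        # consecutive start gaps < 80 bp keep each run one cluster;
        # starts are capped inside the TE so every read overlaps it
        offsets = np.concatenate(
            [[0], rng.integers(1, 80, size=n_distinct - 1)]).cumsum()
        starts = np.minimum(anchor + offsets, row.end - 1)
        lens = rng.choice(lengths_supported, size=n_distinct, p=lweights)
        per_read = rng.multinomial(copies - n_distinct,
                                   np.full(n_distinct, 1 / n_distinct)) + 1
        for s, ln, cp in zip(starts, lens, per_read):
            seq = BASES[rng.integers(0, 4, size=ln)].tobytes().decode()
            rows.append((row.contig, int(s), int(s + ln), seq, int(cp)))

    contigs = list(contig_lengths)
    probs = np.array([contig_lengths[c] for c in contigs], dtype=float)
    probs /= probs.sum()
    n_bg_reads = bg_copies  # background reads are singletons
    which = rng.choice(len(contigs), size=n_bg_reads, p=probs)
    for ci in which:
        contig = contigs[ci]
        ln = int(rng.choice(lengths_supported, p=lweights))
        s = int(rng.integers(0, contig_lengths[contig] - ln))
        seq = BASES[rng.integers(0, 4, size=ln)].tobytes().decode()
        rows.append((contig, s, s + ln, seq, 1))

    reads = pd.DataFrame(rows, columns=eio.READ_COLUMNS)
    reads = reads.sort_values(["contig", "start", "end"],
                              ignore_index=True)
    total = int(reads["copies"].sum())
    return reads, total, targets["id"].tolist()


# ---------------------------------------------------------------------------
# expression


def simulate_expression(genes: pd.DataFrame, tes: pd.DataFrame,
                        cx: pd.DataFrame, config: SimulationConfig,
                        seed: int, flank: int = 1000,
                        min_coverage: int = 5) -> pd.DataFrame:
    """FPKM per gene from the planted log-linear repression model."""
    from .expression import gene_methylation_profiles
    from .methylome import site_levels

    rng = _rng(seed, 7)
    levels = site_levels(cx, min_coverage=min_coverage)
    empty_expr = pd.DataFrame({"gene_id": pd.Series(dtype=str),
                               "fpkm": pd.Series(dtype=float)})
    prof = gene_methylation_profiles(genes, tes, levels, empty_expr,
                                     flank=flank)
    flank_m = prof["flank_te_meth"].fillna(0.0).to_numpy()
    body_m = prof["body_level"].fillna(0.0).to_numpy()
    log_expr = (config.expr_baseline
                - config.expr_beta_flank * flank_m
                - config.expr_gamma_body * body_m
                + rng.normal(0, config.expr_noise_sd, size=len(prof)))
    fpkm = np.maximum(np.exp2(log_expr) - 1.0, 0.0)
    return pd.DataFrame({"gene_id": prof["gene_id"], "fpkm": fpkm})


# ---------------------------------------------------------------------------
# LTR pairs


def _k2p_transition_matrix(d_branch: float, kappa: float) -> np.ndarray:
    """K2P substitution probabilities after ``d_branch`` expected subs/site.

    Base order A, C, G, T; transition rate alpha, each transversion
    beta, with kappa = alpha / (2 * beta) and alpha + 2 * beta = 1 so
    that branch length equals expected substitutions per site.
    """
    beta = 1.0 / (2.0 * kappa + 2.0)
    alpha = 2.0 * kappa * beta
    q = np.full((4, 4), beta)
    for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):  # A<->G, C<->T
        q[i, j] = alpha
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return expm(q * d_branch)


def simulate_ltr_pairs(n: int, d_values, ltr_length: int, seed: int,
                       kappa: float = 2.0, gc: float = 0.5):
    """LTR pairs diverged under a K2P process at known total divergence.

    ``d_values`` may be a scalar or an array of per-element total
    divergences; each repeat copy evolves independently for d/2.
    Returns (list of (element_id, seq5, seq3), {element_id: d}).
    """
    rng = _rng(seed, 8)
    d_arr = np.broadcast_to(np.asarray(d_values, dtype=float), (n,))
    pairs, truth = [], {}
    for i, d in enumerate(d_arr):
        if d < 0:
            raise ValueError("divergence must be non-negative")
        anc = rng.choice(4, size=ltr_length,
                         p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        m = _k2p_transition_matrix(d / 2.0, kappa)
        cum = np.cumsum(m, axis=1)
        copies = []
        for _ in range(2):
            u = rng.random(ltr_length)
            new = (u[:, None] < cum[anc]).argmax(axis=1)
            copies.append(BASES[new].tobytes().decode())
        element_id = f"ltr_{i:04d}"
        pairs.append((element_id, copies[0], copies[1]))
        truth[element_id] = float(d)
    return pairs, truth


# ---------------------------------------------------------------------------
# full dataset


def simulate_dataset(config: SimulationConfig | None = None,
                     seed: int = 0) -> SimulatedDataset:
    """Generate the complete two-species dataset with ground truth."""
    cfg = config or SimulationConfig()
    (genome_a, genome_b, genes_a, tes_a, genes_b, tes_b,
     blocks) = simulate_genomes(cfg, seed)
    planted = plant_dmrs(blocks, cfg, seed)
    n_meth_genes = int(round(len(genes_a) * cfg.meth_gene_fraction))
    meth_gene_idx = np.sort(_rng(seed, 11).choice(
        len(genes_a), size=n_meth_genes, replace=False))
    cx_a = simulate_methylome(genome_a, genes_a, tes_a, cfg, seed,
                              planted=planted, species="A",
                              meth_gene_idx=meth_gene_idx,
                              shared_cg=cfg.cg_preserving)
    cx_b = simulate_methylome(genome_b, genes_b, tes_b, cfg, seed,
                              planted=planted, species="B",
                              meth_gene_idx=meth_gene_idx,
                              shared_cg=cfg.cg_preserving)
    lengths_a = {c: len(s) for c, s in genome_a.items()}
    lengths_b = {c: len(s) for c, s in genome_b.items()}
    sirna_a, total_a, targets_a = simulate_sirna(tes_a, lengths_a, cfg,
                                                 seed, stage=5)
    sirna_b, total_b, _ = simulate_sirna(tes_b, lengths_b, cfg, seed,
                                         stage=6)
    expr_a = simulate_expression(genes_a, tes_a, cx_a, cfg, seed)
    rng_d = _rng(seed, 9)
    d_values = np.maximum(
        rng_d.normal(cfg.ltr_d_mean, cfg.ltr_d_sd, size=cfg.n_ltr), 0.001)
    ltr_pairs, ltr_truth = simulate_ltr_pairs(
        cfg.n_ltr, d_values, cfg.ltr_length, seed, kappa=cfg.ltr_kappa,
        gc=cfg.gc_content)

    truth = SimulationTruth(
        planted_dmrs=planted,
        ltr_true_divergences=ltr_truth,
        cluster_te_targets=targets_a,
        expression_model={
            "baseline": cfg.expr_baseline,
            "beta_flank": cfg.expr_beta_flank,
            "gamma_body": cfg.expr_gamma_body,
            "noise_sd": cfg.expr_noise_sd,
        },
        methylation_mixture={
            "te_cg": cfg.te_cg_beta, "gene_cg": cfg.gene_cg_beta,
            "intergenic_cg": cfg.intergenic_cg_beta,
            "meth_gene_cg": cfg.meth_gene_cg_beta,
            "meth_gene_ids": genes_a["id"].iloc[meth_gene_idx].tolist(),
            "chg": cfg.chg_beta, "chh": cfg.chh_beta,
        },
        coverage_rate=cfg.coverage,
    )
    return SimulatedDataset(
        config=cfg, truth=truth, genome_a=genome_a, genome_b=genome_b,
        genes_a=genes_a, tes_a=tes_a, genes_b=genes_b, tes_b=tes_b,
        synteny=blocks, cx_a=cx_a, cx_b=cx_b,
        sirna_a=sirna_a, sirna_b=sirna_b,
        sirna_total_a=total_a, sirna_total_b=total_b,
        expression_a=expr_a, ltr_pairs=ltr_pairs)


def write_dataset(data: SimulatedDataset, out_dir: str | Path) -> None:
    """Serialize every simulated input in its standard plain-text format."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    eio.write_fasta(data.genome_a, out / "genome_A.fasta")
    eio.write_fasta(data.genome_b, out / "genome_B.fasta")
    for name, feats in (("genes_A", data.genes_a), ("tes_A", data.tes_a),
                        ("genes_B", data.genes_b), ("tes_B", data.tes_b)):
        _write_gff3(feats, out / f"{name}.gff3")
    eio.write_synteny(data.synteny, out / "synteny.tsv")
    eio.write_cytosine_report(data.cx_a, out / "methylome_A.cx.tsv")
    eio.write_cytosine_report(data.cx_b, out / "methylome_B.cx.tsv")
    eio.write_sirna_reads(data.sirna_a, out / "sirna_A.bed")
    eio.write_sirna_reads(data.sirna_b, out / "sirna_B.bed")
    (out / "sirna_totals.json").write_text(json.dumps(
        {"A": data.sirna_total_a, "B": data.sirna_total_b}) + "\n")
    eio.write_expression(data.expression_a, out / "fpkm_A.tsv")
    records = []
    for element_id, seq5, seq3 in data.ltr_pairs:
        records.append((f"{element_id}_5LTR", seq5))
        records.append((f"{element_id}_3LTR", seq3))
    eio.write_fasta(records, out / "ltr_pairs.fasta")
    (out / "truth.json").write_text(data.truth.to_json() + "\n")
    (out / "sim_config.json").write_text(
        json.dumps(data.config.to_dict(), indent=2, sort_keys=True) + "\n")


def _write_gff3(feats: pd.DataFrame, path: Path) -> None:
    type_map = {"gene": "gene", "TE": "transposable_element"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in feats.itertuples(index=False):
            fh.write(f"{row.contig}\tepidiff_sim\t"
                     f"{type_map.get(row.kind, row.kind)}\t"
                     f"{row.start + 1}\t{row.end}\t.\t{row.strand}\t.\t"
                     f"ID={row.id}\n")


# ---------------------------------------------------------------------------
# focused DMR benchmark


def simulate_dmr_benchmark(seed: int, n_planted: int = 100,
                           n_null: int = 900, sites_per_window: int = 8,
                           coverage: float = 20.0,
                           level_high: float = 0.8,
                           level_low: float = 0.2,
                           null_level: float = 0.5, window: int = 200):
    """Planted-vs-null windows for scoring DMR sensitivity and FDR.

    Builds one 200 bp synteny block per window (so windows never
    interact through merging), with a fixed number of CG sites each.
    Planted windows alternate direction at levels
    (``level_high``, ``level_low``); null windows sit at ``null_level``
    in both species.  Returns (blocks, cx_a, cx_b, truth dataframe).
    """
    rng = _rng(seed, 10)
    n_total = n_planted + n_null
    spacing = 2 * window
    blocks, truth_rows = [], []
    rows_a, rows_b = [], []
    site_offsets = np.linspace(10, window - 10, sites_per_window,
                               dtype=int)
    for i in range(n_total):
        start = i * spacing
        block = SyntenyBlock(
            id=f"bench_{i:05d}",
            interval_a=GenomicInterval("benchA", start, start + window),
            interval_b=GenomicInterval("benchB", start, start + window))
        blocks.append(block)
        planted = i < n_planted
        if planted:
            direction = "hyper_in_A" if i % 2 == 0 else "hyper_in_B"
            pa = level_high if direction == "hyper_in_A" else level_low
            pb = level_low if direction == "hyper_in_A" else level_high
        else:
            direction = None
            pa = pb = null_level
        truth_rows.append({"block_id": block.id, "planted": planted,
                           "direction": direction})
        for off in site_offsets:
            pos = start + int(off) + 1  # 1-based report position
            for rows, p, contig in ((rows_a, pa, "benchA"),
                                    (rows_b, pb, "benchB")):
                cov = int(rng.poisson(coverage))
                m = int(rng.binomial(cov, p)) if cov else 0
                rows.append((contig, pos, "+", m, cov - m, "CG", "CGA"))
    cols = eio.CX_COLUMNS
    cx_a = pd.DataFrame(rows_a, columns=cols)
    cx_b = pd.DataFrame(rows_b, columns=cols)
    return blocks, cx_a, cx_b, pd.DataFrame(truth_rows)
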