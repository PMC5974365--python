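import numpy as np
import pandas as pd
import pytest

from epidiff import methylome as mm

from conftest import random_cx_frame
from oracles import metagene_bins_bruteforce

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(COMP)[::-1]


class TestClassifyContext:
    @pytest.mark.parametrize("seq,pos,strand,expected", [
        ("ACGT", 1, "+", "CG"),
        ("CAGT", 0, "+", "CHG"),
        ("CTTA", 0, "+", "CHH"),
        ("ACGT", 2, "-", "CG"),
        ("CAGT", 2, "-", "CHG"),   # minus C at 2: next T (H), then G
        ("ACNT", 1, "+", None),    # N blocks CG/CHG/CHH resolution
        ("AC", 1, "+", None),      # contig edge
    ])
    def test_definitions(self, seq, pos, strand, expected):
        assert mm.classify_context(seq, pos, strand) == expected

    def test_non_c_raises(self):
        with pytest.raises(ValueError):
            mm.classify_context("ACGT", 0, "+")

    def test_minus_strand_equals_revcomp_plus(self, rng):
        """The minus-strand rule is the plus-strand rule on the
        reverse complement."""
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), 50))
            rc = revcomp(seq)
            n = len(seq)
            for pos in range(2, n - 2):
                if seq[pos] != "G":
                    continue
                got = mm.classify_context(seq, pos, "-")
                expected = mm.classify_context(rc, n - 1 - pos, "+")
                assert got == expected


class TestCytosineSites:
    def test_matches_scalar_scan(self, rng):
        """Vectorized enumeration agrees with a per-base scalar scan."""
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGTN"), 300,
                                     p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            sites = mm.cytosine_sites(seq)
            expected = []
            for i, base in enumerate(seq):
                for strand, want in (("+", "C"), ("-", "G")):
                    if base != want:
                        continue
                    if strand == "+" and i + 1 >= len(seq):
                        continue
                    if strand == "-" and i == 0:
                        continue
                    ctx = mm.classify_context(seq, i, strand)
                    if ctx is not None:
                        expected.append((i, strand, ctx))
            got = list(zip(sites["position"], sites["strand"],
                           sites["context"]))
            assert sorted(got) == sorted(expected)

    def test_partition_into_single_context(self):
        """Each classifiable cytosine gets exactly one context."""
        sites = mm.cytosine_sites("ACGTCAGCTTCCGG")
        assert not sites.duplicated(subset=["position", "strand"]).any()
        assert sites["context"].isin(["CG", "CHG", "CHH"]).all()


class TestSiteLevels:
    def make(self, rows):
        return pd.DataFrame(rows, columns=["contig", "position", "strand",
                                           "meth", "unmeth", "context",
                                           "tri"])

    def test_coverage_filter_and_levels(self):
        df = self.make([
            ("c", 1, "+", 0, 10, "CG", "CGA"),   # level 0.0
            ("c", 5, "+", 2, 2, "CG", "CGA"),    # below 5 reads: dropped
            ("c", 9, "+", 3, 7, "CG", "CGA"),    # level 0.3
        ])
        out = mm.site_levels(df, min_coverage=5)
        assert list(out["level"]) == [0.0, 0.3]
        assert list(out["position"]) == [0, 8]  # 0-based out

    def test_raising_coverage_is_monotone(self, rng):
        df = random_cx_frame(rng, n=200)
        kept = [len(mm.site_levels(df, min_coverage=c))
                for c in range(1, 40, 3)]
        assert all(a >= b for a, b in zip(kept, kept[1:]))

    def test_merge_cg_strands_sums_counts(self):
        df = self.make([
            ("c", 11, "+", 4, 1, "CG", "CGA"),
            ("c", 12, "-", 2, 3, "CG", "CGT"),
        ])
        out = mm.site_levels(df, min_coverage=5, merge_cg_strands=True)
        assert len(out) == 1
        assert out.iloc[0]["meth"] == 6
        assert out.iloc[0]["unmeth"] == 4
        assert out.iloc[0]["level"] == 0.6


class TestGenomeMean:
    def test_examples(self):
        df = pd.DataFrame({"contig": "c", "position": [1, 2],
                           "strand": "+", "meth": [0, 10],
                           "unmeth": [10, 0], "context": "CG",
                           "tri": "CGA"})
        levels = mm.site_levels(df, min_coverage=5)
        assert mm.genome_mean_level(levels, "CG") == 0.5

    def test_constant_levels_idempotent(self):
        df = pd.DataFrame({"contig": "c", "position": np.arange(1, 41),
                           "strand": "+", "meth": 146, "unmeth": 854,
                           "context": "CG", "tri": "CGA"})
        levels = mm.site_levels(df, min_coverage=5)
        assert mm.genome_mean_level(levels, "CG") == pytest.approx(0.146)

    def test_invariant_to_order_and_partition(self, rng):
        df = random_cx_frame(rng, n=300)
        levels = mm.site_levels(df, min_coverage=5)
        shuffled = mm.site_levels(df.sample(frac=1, random_state=1),
                                  min_coverage=5)
        assert mm.genome_mean_level(levels, "CG") == pytest.approx(
            mm.genome_mean_level(shuffled, "CG"))

    def test_no_sites_flagged_nan(self):
        levels = mm.site_levels(pd.DataFrame(
            columns=["contig", "position", "strand", "meth", "unmeth",
                     "context", "tri"]), min_coverage=5)
        assert np.isnan(mm.genome_mean_level(levels, "CG"))


class TestMetagene:
    def _uniform_fixture(self, strand="+"):
        """1 kb feature: level 0.8 inside, 0.0 in the 1 kb flanks."""
        positions = np.arange(5, 2995, 7)
        start, end = 1000, 2000
        inside = (positions >= start) & (positions < end)
        df = pd.DataFrame({
            "contig": "c", "position": positions + 1, "strand": "+",
            "meth": np.where(inside, 8, 0),
            "unmeth": np.where(inside, 2, 10),
            "context": "CG", "tri": "CGA"})
        feats = pd.DataFrame([{"contig": "c", "start": start, "end": end,
                               "strand": strand, "kind": "gene",
                               "id": "g1"}])
        return mm.site_levels(df, min_coverage=5), feats

    def test_step_function(self):
        levels, feats = self._uniform_fixture()
        prof = mm.metagene_profile(levels, feats, flank=1000)
        assert np.allclose(prof.body_values, 0.8)
        assert np.allclose(prof.flank_bins_up, 0.0)
        assert np.allclose(prof.flank_bins_down, 0.0)

    def test_minus_strand_mirrors(self):
        levels, feats_plus = self._uniform_fixture("+")
        _, feats_minus = self._uniform_fixture("-")
        p_plus = mm.metagene_profile(levels, feats_plus, flank=1000)
        p_minus = mm.metagene_profile(levels, feats_minus, flank=1000)
        assert np.allclose(p_plus.values, p_minus.values[::-1],
                           equal_nan=True)

    def test_matches_bruteforce(self, rng):
        n = 120
        pos = np.sort(rng.choice(5000, size=n, replace=False))
        meth = rng.integers(0, 10, n)
        unmeth = 10 - meth
        df = pd.DataFrame({"contig": "c", "position": pos + 1,
                           "strand": "+", "meth": meth, "unmeth": unmeth,
                           "context": "CG", "tri": "CGA"})
        feats = pd.DataFrame([
            {"contig": "c", "start": 1200, "end": 2000, "strand": "+",
             "kind": "gene", "id": "g1"},
            {"contig": "c", "start": 2500, "end": 4100, "strand": "-",
             "kind": "gene", "id": "g2"}])
        levels = mm.site_levels(df, min_coverage=5)
        prof = mm.metagene_profile(levels, feats, flank=1000,
                                   body_bins=20, flank_bins=10)
        sites = [("c", p, m, u) for p, m, u in
                 zip(pos, meth, unmeth)]
        bf_meth, bf_total = metagene_bins_bruteforce(
            sites, [("c", 1200, 2000, "+"), ("c", 2500, 4100, "-")],
            1000, 20, 10)
        assert np.allclose(prof.meth, bf_meth)
        assert np.allclose(prof.total, bf_total)

    def test_short_features_excluded(self):
        levels, _ = self._uniform_fixture()
        feats = pd.DataFrame([{"contig": "c", "start": 0, "end": 5,
                               "strand": "+", "kind": "gene", "id": "g"}])
        with pytest.raises(ValueError, match="qualifying"):
            mm.metagene_profile(levels, feats)


class TestBimodality:
    def test_extreme_sites(self):
        lo, hi, _ = mm.bimodality_summary(np.array([0.05, 0.95]))
        assert (lo, hi) == (0.5, 0.5)

    def test_midrange_sites(self):
        lo, hi, hist = mm.bimodality_summary(np.full(10, 0.5))
        assert (lo, hi) == (0.0, 0.0)
        assert hist.sum() == 10

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mm.bimodality_summary(np.array([]))


class TestWindowTracks:
    def test_tiling_and_truncation(self):
        levels = mm.site_levels(pd.DataFrame(
            {"contig": "c", "position": [5], "strand": "+", "meth": [5],
             "unmeth": [5], "context": "CG", "tri": "CGA"}), 5)
        feats = pd.DataFrame(columns=["contig", "start", "end", "strand",
                                      "kind", "id"])
        tracks = mm.window_tracks(feats, levels, None, {"c": 25_000},
                                  window=10_000)
        assert list(tracks["start"]) == [0, 10_000, 20_000]
        assert list(tracks["end"]) == [10_000, 20_000, 25_000]

    def test_boundary_spanning_te_split_proportionally(self):
        feats = pd.DataFrame([{"contig": "c", "start": 9_000,
                               "end": 12_000, "strand": "+", "kind": "TE",
                               "id": "t"}])
        levels = mm.site_levels(pd.DataFrame(
            columns=["contig", "position", "strand", "meth", "unmeth",
                     "context", "tri"]), 5)
        tracks = mm.window_tracks(feats, levels, None, {"c": 20_000},
                                  window=10_000)
        # brute-force per-bp: 1000 bp in window 0, 2000 bp in window 1
        assert tracks.loc[0, "te_fraction"] == pytest.approx(0.1)
        assert tracks.loc[1, "te_fraction"] == pytest.approx(0.2)

    def test_no_sites_gives_nan_not_zero(self):
        levels = mm.site_levels(pd.DataFrame(
            columns=["contig", "position", "strand", "meth", "unmeth",
                     "context", "tri"]), 5)
        feats = pd.DataFrame(columns=["contig", "start", "end", "strand",
                                      "kind", "id"])
        tracks = mm.window_tracks(feats, levels, None, {"c": 10_000})
        assert np.isnan(tracks.loc[0, "mcg_level"])

    def test_sirna_coverage_counts_read_bp(self):
        feats = pd.DataFrame(columns=["contig", "start", "end", "strand",
                                      "kind", "id"])
        levels = mm.site_levels(pd.DataFrame(
            columns=["contig", "position", "strand", "meth", "unmeth",
                     "context", "tri"]), 5)
        reads = pd.DataFrame({"contig": ["c"], "start": [9990],
                              "end": [10_010], "sequence": ["A" * 20],
                              "copies": [2]})
        tracks = mm.window_tracks(feats, levels, reads, {"c": 20_000},
                                  window=10_000)
        assert tracks.loc[0, "sirna_coverage"] == pytest.approx(
            10 * 2 / 10_000)
        assert tracks.loc[1, "sirna_coverage"] == pytest.approx(
            10 * 2 / 10_000)


class TestColocalization:
    def test_perfect_monotone(self):
        tracks = pd.DataFrame({
            "mcg_level": np.linspace(0.1, 0.9, 20),
            "te_fraction": np.linspace(0, 1, 20)})
        rho, p = mm.colocalization(tracks)
        assert rho == pytest.approx(1.0)

    def test_constant_track_flagged(self):
        tracks = pd.DataFrame({"mcg_level": np.full(20, 0.5),
                               "te_fraction": np.linspace(0, 1, 20)})
        rho, p = mm.colocalization(tracks)
        assert np.isnan(rho)

    def test_permuted_labels_near_zero(self, rng):
        """Under label permutation the correlation is a null draw."""
        x = np.linspace(0.1, 0.9, 200)
        rhos = []
        for _ in range(30):
            tracks = pd.DataFrame({"mcg_level": x,
                                   "te_fraction": rng.permutation(x)})
            rhos.append(mm.colocalization(tracks)[0])
        assert abs(np.mean(rhos)) < 0.1
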