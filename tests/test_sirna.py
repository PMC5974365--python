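import numpy as np
import pandas as pd
import pytest

from epidiff import sirna as sn
from epidiff.methylome import site_levels

from oracles import mannwhitney_two_sided_p, transitive_closure_clusters


def reads_frame(rows):
    """rows: (contig, start, end) or (contig, start, end, seq, copies)."""
    full = []
    for i, r in enumerate(rows):
        if len(r) == 3:
            c, s, e = r
            full.append((c, s, e, f"{'ACGT'[i % 4]}" * (e - s), 1))
        else:
            full.append(r)
    return pd.DataFrame(full, columns=["contig", "start", "end",
                                       "sequence", "copies"])


class TestLengthDistribution:
    def test_copy_weighting(self):
        reads = reads_frame([("c", 0, 22, "A" * 22, 3)])
        hist = sn.length_distribution(reads)
        assert hist[22] == 3
        assert hist.drop(22).sum() == 0

    def test_empty_input(self):
        hist = sn.length_distribution(reads_frame([]))
        assert (hist == 0).all()
        assert list(hist.index) == list(range(18, 31))


class TestCompare:
    def mk(self, counts):
        return pd.Series(counts, index=range(18, 18 + len(counts)))

    def test_identical_histograms(self):
        h = self.mk([100, 200, 300])
        chi2, df, p = sn.compare_length_distributions(h, h)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_two_by_two(self):
        chi2, df, p = sn.compare_length_distributions(
            self.mk([10, 0]), self.mk([0, 10]))
        assert chi2 == pytest.approx(20.0)
        assert df == 1
        assert p < 1e-4

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError):
            sn.compare_length_distributions(self.mk([0, 0]),
                                            self.mk([1, 1]))

    def test_same_multinomial_p_uniformish(self, rng):
        """Two draws from one length law give well-calibrated p."""
        probs = np.array([1, 2, 6, 10, 6, 2, 1], dtype=float)
        probs /= probs.sum()
        ps = []
        for _ in range(40):
            a = self.mk(rng.multinomial(2000, probs))
            b = self.mk(rng.multinomial(2000, probs))
            ps.append(sn.compare_length_distributions(a, b)[2])
        ps = np.array(ps)
        assert (ps < 0.05).mean() < 0.25
        assert ps.mean() > 0.2


class TestCallClusters:
    def test_gap_rule_boundaries(self):
        # distance 50 (< 100): same cluster; distance 100: split
        same = sn.call_clusters(reads_frame([("c", 80, 100),
                                             ("c", 150, 172)]),
                                total_mapped=100, min_rpm=0,
                                min_distinct=0)
        assert len(same) == 1
        split = sn.call_clusters(reads_frame([("c", 80, 100),
                                              ("c", 200, 222)]),
                                 total_mapped=100, min_rpm=0,
                                 min_distinct=0)
        assert len(split) == 2

    def test_abundance_thresholds(self):
        def cluster(n_distinct, copies_total):
            rows = []
            per = copies_total // n_distinct
            for i in range(n_distinct):
                s = 10 + 30 * i
                seq = np.base_repr(i + 4**10, base=4)
                seq = seq.translate(str.maketrans("0123", "ACGT"))[:21]
                rows.append(("c", s, s + 21, seq.ljust(21, "A"), per))
            return reads_frame(rows)

        kept = sn.call_clusters(cluster(12, 6000), total_mapped=1_000_000)
        assert len(kept) == 1
        assert kept[0].rpm >= 5
        dropped = sn.call_clusters(cluster(8, 6000),
                                   total_mapped=1_000_000)
        assert dropped == []

    def test_matches_transitive_closure(self, rng):
        """Sweep clustering equals brute-force single linkage."""
        for trial in range(10):
            n = int(rng.integers(5, 200))
            starts = np.sort(rng.integers(0, 5000, size=n))
            lens = rng.integers(18, 31, size=n)
            rows = [("c", int(s), int(s + l),
                     "".join(rng.choice(list("ACGT"), l)), 1)
                    for s, l in zip(starts, lens)]
            reads = reads_frame(rows)
            got = sn.call_clusters(reads, total_mapped=10**6, gap=100,
                                   min_rpm=0, min_distinct=0)
            expected = transitive_closure_clusters(
                list(zip(starts, starts + lens)), gap=100)
            assert len(got) == len(expected)
            spans = sorted((c.interval.start, c.interval.end)
                           for c in got)
            exp_spans = sorted(
                (int(starts[g].min()), int((starts[g] + lens[g]).max()))
                for g in (np.array(ix) for ix in expected))
            assert spans == exp_spans

    def test_final_clusters_separated_by_gap(self, rng):
        starts = np.sort(rng.integers(0, 3000, size=150))
        reads = reads_frame([("c", int(s), int(s + 21),
                              "".join(rng.choice(list("ACGT"), 21)), 2)
                             for s in starts])
        clusters = sn.call_clusters(reads, total_mapped=10**6,
                                    min_rpm=0, min_distinct=0)
        for c1, c2 in zip(clusters, clusters[1:]):
            assert c2.interval.start - c1.interval.end >= 100

    def test_filters_are_monotone_and_conservative(self, rng):
        starts = np.sort(rng.integers(0, 10_000, size=200))
        reads = reads_frame([("c", int(s), int(s + 21),
                              "".join(rng.choice(list("ACGT"), 21)),
                              int(rng.integers(1, 5)))
                             for s in starts])
        raw = sn.raw_clusters(reads, total_mapped=10**6)
        assert sum(c.total_reads for c in raw) == reads["copies"].sum()
        counts = [len(sn.call_clusters(reads, 10**6, min_rpm=r,
                                       min_distinct=d))
                  for r, d in [(0, 0), (1, 2), (5, 5), (10, 10)]]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_order_invariance(self, rng):
        starts = rng.integers(0, 2000, size=60)
        reads = reads_frame([("c", int(s), int(s + 21),
                              "".join(rng.choice(list("ACGT"), 21)), 1)
                             for s in starts])
        shuffled = reads.sample(frac=1, random_state=0)
        a = sn.call_clusters(reads, 10**6, min_rpm=0, min_distinct=0)
        b = sn.call_clusters(shuffled, 10**6, min_rpm=0, min_distinct=0)
        assert [(c.interval.start, c.interval.end, c.total_reads)
                for c in a] == \
            [(c.interval.start, c.interval.end, c.total_reads) for c in b]

    def test_total_mapped_validation(self):
        reads = reads_frame([("c", 0, 21)])
        with pytest.raises(ValueError):
            sn.call_clusters(reads, total_mapped=0)


class TestTEOverlap:
    def test_fractions(self):
        clusters = sn.call_clusters(
            reads_frame([("c", 0, 21), ("c", 1000, 1021)]),
            total_mapped=100, min_rpm=0, min_distinct=0)
        tes = pd.DataFrame([{"contig": "c", "start": 10, "end": 500,
                             "strand": "+", "kind": "TE", "id": "t1"}])
        fc, ft, flags = sn.cluster_te_overlap(clusters, tes)
        assert fc == 0.5
        assert ft == 1.0
        assert flags == [True, False]

    def test_no_tes_flagged(self):
        clusters = sn.call_clusters(reads_frame([("c", 0, 21)]),
                                    total_mapped=10, min_rpm=0,
                                    min_distinct=0)
        tes = pd.DataFrame(columns=["contig", "start", "end", "strand",
                                    "kind", "id"])
        fc, ft, _ = sn.cluster_te_overlap(clusters, tes)
        assert fc == 0.0
        assert np.isnan(ft)


class TestMethylationContrast:
    def _fixture(self, with_levels, without_levels):
        genes, cx_rows, clusters_reads = [], [], []
        pos = 0
        for gi, lvl in enumerate(with_levels + without_levels):
            start = pos + 2000
            end = start + 1000
            genes.append({"contig": "c", "start": start, "end": end,
                          "strand": "+", "kind": "gene", "id": f"g{gi}"})
            for k in range(10):
                p = start + 50 + 90 * k
                meth = int(round(lvl * 20))
                cx_rows.append(("c", p + 1, "+", meth, 20 - meth, "CG",
                                "CGA"))
            if gi < len(with_levels):
                clusters_reads.append(("c", start + 10, start + 31))
            pos = end + 2000
        levels = site_levels(pd.DataFrame(
            cx_rows, columns=["contig", "position", "strand", "meth",
                              "unmeth", "context", "tri"]), 5)
        clusters = sn.call_clusters(reads_frame(clusters_reads),
                                    total_mapped=100, min_rpm=0,
                                    min_distinct=0)
        return clusters, pd.DataFrame(genes), levels

    def test_p_matches_exact_rank_enumeration(self):
        with_lv = [0.9, 0.8, 0.85]
        without_lv = [0.1, 0.05, 0.2]
        clusters, genes, levels = self._fixture(with_lv, without_lv)
        res = sn.cluster_methylation_contrast(clusters, genes, levels,
                                              flank=1000)
        assert sorted(res["with_cluster"]) == sorted(with_lv)
        assert res["p"] == pytest.approx(
            mannwhitney_two_sided_p(res["with_cluster"],
                                    res["without_cluster"]), abs=1e-9)

    def test_identical_groups_null(self):
        # same distribution in both groups: no separation
        clusters, genes, levels = self._fixture(
            [0.1, 0.5, 0.9], [0.15, 0.55, 0.95])
        res = sn.cluster_methylation_contrast(clusters, genes, levels)
        assert res["p"] > 0.5

    def test_small_group_flagged(self):
        clusters, genes, levels = self._fixture([0.9], [0.1, 0.2, 0.3])
        res = sn.cluster_methylation_contrast(clusters, genes, levels)
        assert np.isnan(res["p"])


def test_region_kind_precedence():
    clusters = sn.call_clusters(reads_frame([("c", 100, 121)]),
                                total_mapped=10, min_rpm=0,
                                min_distinct=0)
    genes = pd.DataFrame([{"contig": "c", "start": 50, "end": 500,
                           "strand": "+", "kind": "gene", "id": "g"}])
    tes = pd.DataFrame([{"contig": "c", "start": 90, "end": 200,
                         "strand": "+", "kind": "TE", "id": "t"}])
    sn.annotate_region_kind(clusters, genes, tes)
    assert clusters[0].region_kind == "TE"
    sn.annotate_region_kind(clusters, genes, tes.iloc[0:0])
    assert clusters[0].region_kind == "genic"
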