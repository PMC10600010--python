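"""Locus IBD graphs, corrected counts, segment filtering, ROH overlays."""

import numpy as np
import pandas as pd
import pytest

import admixfreq as af
from admixfreq.types import IBD_COLUMNS, MISSING

from conftest import origin_label


def seg(s1, h1, s2, h2, start, end, cm=None):
    return [s1, h1, s2, h2, "1", start, end, cm if cm is not None else (end - start) / 1e6]


def make_haps(sample_alleles: dict[str, tuple[int, int]], pos=500):
    """One-variant cohort from {sample: (allele_hap1, allele_hap2)}."""
    samples = list(sample_alleles)
    alleles = np.array([[[a], [b]] for a, b in sample_alleles.values()], dtype=np.int8)
    return af.PhasedHaplotypeSet(samples, "1", np.array([pos]), ["A"], ["T"], alleles)


def degrees_of(pairs):
    return pd.DataFrame(pairs, columns=["sample1", "sample2", "degree"])


class TestLocusGraph:
    def test_components_follow_segment_links(self):
        haps = make_haps({"A": (1, 0), "B": (1, 0), "C": (1, 0),
                          "D": (0, 0), "E": (0, 0), "F": (0, 0)})
        segs = af.IBDSegmentSet(pd.DataFrame(
            [seg("A", 1, "B", 1, 1, 1000), seg("B", 1, "C", 1, 1, 1000),
             seg("D", 1, "E", 1, 1, 1000)], columns=IBD_COLUMNS))
        deg = degrees_of([("A", "B", 1), ("B", "C", 2), ("D", "E", 1)])
        g = af.build_locus_ibd_graph(haps, segs, deg, 500)
        comp_sets = {frozenset(c) for c in g.components}
        assert frozenset({(0, 0), (1, 0), (2, 0)}) in comp_sets  # A,B,C hap1 chain
        assert frozenset({(3, 0), (4, 0)}) in comp_sets  # D,E
        # all remaining haplotypes are singleton components
        assert sum(len(c) == 1 for c in g.components) == 12 - 5

    def test_conflicting_alleles_break_the_edge(self):
        haps = make_haps({"A": (1, 0), "B": (0, 0)})
        segs = af.IBDSegmentSet(pd.DataFrame(
            [seg("A", 1, "B", 1, 1, 1000)], columns=IBD_COLUMNS))
        deg = degrees_of([("A", "B", 1)])
        g = af.build_locus_ibd_graph(haps, segs, deg, 500)
        assert all(len(c) == 1 for c in g.components)

    def test_fourth_degree_pair_gets_no_edge(self):
        haps = make_haps({"A": (1, 0), "B": (1, 0)})
        segs = af.IBDSegmentSet(pd.DataFrame(
            [seg("A", 1, "B", 1, 1, 1000)], columns=IBD_COLUMNS))
        g = af.build_locus_ibd_graph(haps, segs, degrees_of([("A", "B", 4)]), 500)
        assert all(len(c) == 1 for c in g.components)
        # absent from the table entirely -> also no edge
        g2 = af.build_locus_ibd_graph(haps, segs, degrees_of([]), 500)
        assert all(len(c) == 1 for c in g2.components)

    def test_missing_alleles_leave_vertex_set(self):
        haps = make_haps({"A": (1, MISSING), "B": (0, 0)})
        g = af.build_locus_ibd_graph(
            haps, af.IBDSegmentSet(pd.DataFrame(columns=IBD_COLUMNS)),
            degrees_of([]), 500)
        assert (0, 1) not in g.alleles and len(g.vertices) == 3

    def test_locus_outside_variants_raises(self):
        haps = make_haps({"A": (0, 0)})
        with pytest.raises(ValueError, match="not in variant set"):
            af.build_locus_ibd_graph(
                haps, af.IBDSegmentSet(pd.DataFrame(columns=IBD_COLUMNS)),
                degrees_of([]), 123)


class TestCorrectedCounts:
    def test_component_counting_example(self):
        haps = make_haps({"A": (1, 0), "B": (1, 0), "C": (1, 0),
                          "D": (0, 0), "E": (0, 0), "F": (0, 0)})
        # collapse: keep only hap1 vertices by marking hap2 missing
        haps.alleles[:, 1, 0] = MISSING
        segs = af.IBDSegmentSet(pd.DataFrame(
            [seg("A", 1, "B", 1, 1, 1000), seg("B", 1, "C", 1, 1, 1000),
             seg("D", 1, "E", 1, 1, 1000)], columns=IBD_COLUMNS))
        deg = degrees_of([("A", "B", 1), ("B", "C", 2), ("D", "E", 1)])
        g = af.build_locus_ibd_graph(haps, segs, deg, 500)
        ac, an, freq = af.ibd_corrected_counts(g)
        assert (ac, an) == (1, 3) and freq == pytest.approx(1 / 3)

    def test_edgeless_graph_reduces_to_naive_counts(self):
        rng = np.random.default_rng(5)
        alleles = {f"s{i}": (int(rng.random() < 0.4), int(rng.random() < 0.4))
                   for i in range(5)}
        haps = make_haps(alleles)
        g = af.build_locus_ibd_graph(
            haps, af.IBDSegmentSet(pd.DataFrame(columns=IBD_COLUMNS)),
            degrees_of([]), 500)
        ac, an, _ = af.ibd_corrected_counts(g)
        nac, nan_ = haps.allele_counts()
        assert (ac, an) == (int(nac[0]), int(nan_[0]))

    def test_gene_drop_matches_founder_allele_oracle(self, pedigree_drop):
        _, _, cohort, ibd, degrees, origins = pedigree_drop
        for v in range(0, cohort.n_variants, 10):
            pos = int(cohort.positions[v])
            g = af.build_locus_ibd_graph(cohort, ibd, degrees, pos)
            ac, an, _ = af.ibd_corrected_counts(g)
            alt_f, all_f = set(), set()
            for i, s in enumerate(cohort.samples):
                for j in (0, 1):
                    lab = origin_label(*origins[s][j], pos)
                    all_f.add(lab)
                    if cohort.alleles[i, j, v] == 1:
                        alt_f.add(lab)
            assert (ac, an) == (len(alt_f), len(all_f))

    def test_corrected_an_bounded_by_naive(self, pedigree_drop):
        _, _, cohort, ibd, degrees, _ = pedigree_drop
        table = af.corrected_frequency_table(
            cohort, ibd, degrees, positions=cohort.positions[:30])
        _, naive_an = cohort.allele_counts()
        assert np.all(table["AN"].to_numpy() <= naive_an[:30])
        assert np.all(table["AN"].to_numpy() < naive_an[:30])  # graphs have edges


class TestAncestryCounts:
    def test_component_average_example(self):
        haps = make_haps({"A": (1, 0), "B": (1, 0)})
        haps.alleles[:, 1, 0] = MISSING
        segs = af.IBDSegmentSet(pd.DataFrame(
            [seg("A", 1, "B", 1, 1, 1000)], columns=IBD_COLUMNS))
        g = af.build_locus_ibd_graph(haps, segs, degrees_of([("A", "B", 1)]), 500)
        probs = np.zeros((2, 2, 3))
        probs[0, 0] = [1, 0, 0]
        probs[1, 0] = [0, 1, 0]
        summ = af.ibd_corrected_ancestry_counts(g, probs)
        np.testing.assert_allclose(summ.p_bar[0], [0.5, 0.5, 0.0])
        np.testing.assert_allclose(summ.W, [0.5, 0.5, 0.0])
        np.testing.assert_allclose(summ.N, [0.5, 0.5, 0.0])

    def test_one_hot_consistency_with_plain_counts(self):
        haps = make_haps({"A": (1, 1), "B": (0, 1), "C": (0, 0)})
        g = af.build_locus_ibd_graph(
            haps, af.IBDSegmentSet(pd.DataFrame(columns=IBD_COLUMNS)),
            degrees_of([]), 500)
        probs = np.zeros((3, 2, 2))
        probs[..., 0] = 1.0  # everyone ancestry 0
        summ = af.ibd_corrected_ancestry_counts(g, probs)
        ac, an, freq = af.ibd_corrected_counts(g)
        assert summ.frequencies[0] == pytest.approx(freq)
        assert np.isnan(summ.frequencies[1])

    def test_matches_per_component_brute_force(self):
        rng = np.random.default_rng(8)
        names = list("ABCDEFGH")
        haps = make_haps({s: (int(rng.random() < 0.5), MISSING) for s in names})
        segs = af.IBDSegmentSet(pd.DataFrame(
            [seg("A", 1, "B", 1, 1, 1000), seg("C", 1, "D", 1, 1, 1000),
             seg("E", 1, "F", 1, 1, 1000)], columns=IBD_COLUMNS))
        deg = degrees_of([("A", "B", 1), ("C", "D", 2), ("E", "F", 3)])
        g = af.build_locus_ibd_graph(haps, segs, deg, 500)
        probs = rng.dirichlet(np.ones(3), size=(8, 2))
        summ = af.ibd_corrected_ancestry_counts(g, probs)
        W = np.zeros(3)
        N = np.zeros(3)
        for comp in g.components:
            vecs = np.stack([probs[i, j] for i, j in comp])
            pbar = vecs.mean(axis=0)
            N += pbar
            if g.alleles[next(iter(comp))] == 1:
                W += pbar
        np.testing.assert_allclose(summ.W, W, atol=1e-12)
        np.testing.assert_allclose(summ.N, N, atol=1e-12)
        assert np.all((summ.W >= -1e-12) & (summ.W <= summ.N + 1e-12))


class TestSegmentFilter:
    def _uniform_fixture(self):
        rows = [seg(f"a{i}", 1, f"b{i}", 1, 1, 1_000_000) for i in range(10)]
        positions = np.arange(1, 1_000_001, 10_000)
        return rows, positions

    def test_uniform_coverage_keeps_everything(self):
        rows, positions = self._uniform_fixture()
        segs = af.IBDSegmentSet(pd.DataFrame(rows, columns=IBD_COLUMNS))
        out = af.filter_ibd_segments(segs, positions, window_bp=50_000)
        assert len(out) == len(segs)

    def test_high_coverage_window_removes_overlappers(self):
        # 10 genome-wide segments plus a pile concentrated on one window
        rows, positions = self._uniform_fixture()
        pile = [seg(f"x{i}", 1, f"y{i}", 2, 500_001, 550_000) for i in range(35)]
        segs = af.IBDSegmentSet(pd.DataFrame(rows + pile, columns=IBD_COLUMNS))
        out = af.filter_ibd_segments(segs, positions, window_bp=50_000)
        # brute-force coverage profile: the piled window holds 45 segments,
        # above 4x the median (10), so every overlapping segment is removed
        assert len(out) == 0

        # a milder pile (3 extra) stays under the 4x cut and nothing is lost
        pile = [seg(f"x{i}", 1, f"y{i}", 2, 500_001, 550_000) for i in range(3)]
        segs = af.IBDSegmentSet(pd.DataFrame(rows + pile, columns=IBD_COLUMNS))
        out = af.filter_ibd_segments(segs, positions, window_bp=50_000)
        assert len(out) == 13

    def test_zero_snp_window_removes_overlappers(self):
        rows, positions = self._uniform_fixture()
        gap = (positions < 500_000) | (positions > 550_000)
        segs = af.IBDSegmentSet(pd.DataFrame(rows, columns=IBD_COLUMNS))
        out = af.filter_ibd_segments(segs, positions[gap], window_bp=50_000)
        assert len(out) == 0  # genome-wide segments all cross the empty window

    def test_empty_input_warns_and_returns_empty(self):
        segs = af.IBDSegmentSet(pd.DataFrame(columns=IBD_COLUMNS))
        with pytest.warns(UserWarning, match="empty"):
            out = af.filter_ibd_segments(segs, np.array([100]), window_bp=1000)
        assert len(out) == 0


class TestROH:
    def _lai(self, probs_by_anchor):
        # probs_by_anchor: (n, 2, A, K)
        arr = np.asarray(probs_by_anchor, dtype=float)
        anchors = np.arange(1, arr.shape[2] + 1) * 100
        return af.LocalAncestryField(["A", "B"], anchors, arr)

    def test_concordant_high_posterior_assigned(self):
        p = np.full((1, 2, 3, 2), 0.0)
        p[..., 0] = 0.95
        p[..., 1] = 0.05
        lai = self._lai(p)
        roh = [af.ROHSegment("s", "1", 50, 350, 1.0)]
        out = af.assign_roh_ancestry(roh, lai, {"s": 0})
        assert out[0].assigned_ancestry == "A"

    def test_discordant_haplotypes_unassigned(self):
        p = np.zeros((1, 2, 3, 2))
        p[0, 0, :, 0] = 0.95
        p[0, 0, :, 1] = 0.05
        p[0, 1, :, 1] = 0.95
        p[0, 1, :, 0] = 0.05
        out = af.assign_roh_ancestry(
            [af.ROHSegment("s", "1", 50, 350, 1.0)], self._lai(p), {"s": 0})
        assert out[0].assigned_ancestry is None

    def test_posterior_at_090_not_assigned(self):
        # threshold is strict: posterior must exceed 0.9
        p = np.zeros((1, 2, 3, 2))
        p[..., 0] = 0.8
        p[..., 1] = 0.2
        out = af.assign_roh_ancestry(
            [af.ROHSegment("s", "1", 50, 350, 1.0)], self._lai(p), {"s": 0})
        assert out[0].assigned_ancestry is None
        p[..., 0] = 0.9
        p[..., 1] = 0.1
        out = af.assign_roh_ancestry(
            [af.ROHSegment("s", "1", 50, 350, 1.0)], self._lai(p), {"s": 0})
        assert out[0].assigned_ancestry is None

    def test_no_interior_anchor_uses_nearest(self):
        p = np.zeros((1, 2, 2, 2))
        p[0, :, 0, 0] = 0.99
        p[0, :, 0, 1] = 0.01
        p[0, :, 1, 1] = 0.99
        p[0, :, 1, 0] = 0.01
        lai = af.LocalAncestryField(["A", "B"], np.array([100, 1000]), p)
        out = af.assign_roh_ancestry(
            [af.ROHSegment("s", "1", 120, 180, 0.1)], lai, {"s": 0})
        assert out[0].assigned_ancestry == "A"  # nearest anchor is 100


class TestRhlofOverlap:
    def test_counts_inside_and_outside_roh(self):
        n, m = 6, 5
        alleles = np.zeros((n, 2, m), dtype=np.int8)
        # five rare homozygotes, one per variant, three inside ROH
        for v in range(m):
            alleles[v % n, :, v] = 1
        haps = af.PhasedHaplotypeSet(
            [f"s{i}" for i in range(n)], "1", np.arange(1, m + 1) * 1000,
            ["A"] * m, ["T"] * m, alleles,
        )
        afreq = np.full(m, 0.0005)
        roh = [af.ROHSegment(f"s{v}", "1", v * 1000 + 500, v * 1000 + 1500, 1.0, "AMR")
               for v in range(3)]
        out = af.rhlof_roh_overlap(haps, afreq, roh)
        assert len(out) == 5
        assert out["in_roh"].sum() == 3
        assert out["in_roh"].mean() == pytest.approx(0.6)
        assert set(out.loc[out.in_roh, "roh_ancestry"]) == {"AMR"}

    def test_common_homozygote_excluded_by_af_rule(self):
        alleles = np.ones((1, 2, 1), dtype=np.int8)
        haps = af.PhasedHaplotypeSet(["s"], "1", np.array([100]), ["A"], ["T"], alleles)
        out = af.rhlof_roh_overlap(haps, np.array([0.005]), [])
        assert len(out) == 0
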