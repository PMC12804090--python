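"""Loop integration, APA, featurization, clustering, enrichment, expression."""

import numpy as np
import pandas as pd
import pytest

from nucleome.layout import make_genome
from nucleome.loops import (
    anchor_state_features,
    anchor_tf_enrichment,
    apa,
    capture_overlap,
    classify_ep_sharing,
    cluster_loops,
    expression_breadth,
    expression_quartiles,
    link_genes_to_enhancers,
    loop_state_pair_enrichment,
    mean_loop_strength,
    merge_loops,
    tss_contact_decay,
)
from nucleome.simdata import (
    plant_truth,
    simulate_contact_map,
    simulate_loops_with_states,
)


def mk_loops(rows, resolution=10_000, platform="hic"):
    df = pd.DataFrame(rows, columns=["chrom", "start1", "end1", "start2", "end2"])
    df["resolution"] = resolution
    df["platform"] = platform
    return df


class TestMergeLoops:
    def test_printed_rule_arithmetic(self):
        # distance 100 kb, offsets (10 kb, 10 kb): 10,000 < min(20,000, 15,000)
        a = mk_loops([("chr1", 995_000, 1_005_000, 1_095_000, 1_105_000)], 10_000)
        b = mk_loops([("chr1", 1_005_000, 1_015_000, 1_105_000, 1_115_000)], 20_000)
        merged = merge_loops([a, b])
        assert len(merged) == 1
        assert merged["resolution"].iloc[0] == 10_000  # finer retained

    def test_offset_16kb_not_merged(self):
        a = mk_loops([("chr1", 995_000, 1_005_000, 1_095_000, 1_105_000)], 10_000)
        b = mk_loops([("chr1", 1_011_000, 1_021_000, 1_095_000, 1_105_000)], 20_000)
        assert len(merge_loops([a, b])) == 2

    def test_idempotent(self, rng):
        rows = []
        for _ in range(100):
            s = int(rng.integers(0, 40_000_000))
            d = int(rng.integers(100_000, 2_000_000))
            rows.append(("chr1", s, s + 10_000, s + d, s + d + 10_000))
        loops = mk_loops(rows)
        once = merge_loops([loops])
        twice = merge_loops([once])
        assert len(once) == len(twice)

    def test_matches_transitive_closure_oracle(self, rng):
        import networkx as nx

        sets = []
        for res in (5_000, 10_000, 25_000):
            rows = []
            for _ in range(150):
                s = int(rng.integers(0, 20_000_000))
                d = int(rng.integers(100_000, 1_000_000))
                rows.append(("chr1", s, s + res, s + d, s + d + res))
            sets.append(mk_loops(rows, res))
        merged = merge_loops(sets)
        # oracle: union-find over all pairs via networkx components
        allloops = pd.concat(sets, ignore_index=True).sort_values(
            ["resolution", "chrom", "start1", "start2"], kind="stable"
        ).reset_index(drop=True)
        i = ((allloops.start1 + allloops.end1) / 2).to_numpy()
        j = ((allloops.start2 + allloops.end2) / 2).to_numpy()
        res = allloops.resolution.to_numpy()
        g = nx.Graph()
        g.add_nodes_from(range(len(allloops)))
        for a in range(len(allloops)):
            for b in range(a + 1, len(allloops)):
                span = (j[a] - i[a]) if res[a] <= res[b] else (j[b] - i[b])
                thr = min(0.2 * span, 15_000)
                if abs(i[a] - i[b]) < thr and abs(j[a] - j[b]) < thr:
                    g.add_edge(a, b)
        n_clusters = nx.number_connected_components(g)
        assert len(merged) == n_clusters

    def test_malformed_loop_dropped(self):
        bad = mk_loops([("chr1", 2_000_000, 2_010_000, 1_000_000, 1_010_000)])
        ok = mk_loops([("chr1", 1_000_000, 1_010_000, 2_000_000, 2_010_000)])
        assert len(merge_loops([bad, ok])) == 1


class TestCaptureOverlap:
    def test_identical_overlaps(self, toy_loops):
        assert capture_overlap(toy_loops, toy_loops).all()

    def test_threshold_is_strict(self):
        q = mk_loops([("chr1", 995_000, 1_005_000, 1_495_000, 1_505_000)])
        # distance exactly 80 kb on the i axis; span 500 kb -> threshold 80 kb
        r = mk_loops([("chr1", 1_075_000, 1_085_000, 1_495_000, 1_505_000)])
        assert not capture_overlap(q, r)[0]
        r2 = mk_loops([("chr1", 1_074_000, 1_084_000, 1_495_000, 1_505_000)])
        assert capture_overlap(q, r2)[0]

    def test_matches_bruteforce(self, rng):
        def rand(n):
            rows = []
            for _ in range(n):
                s = int(rng.integers(0, 20_000_000))
                d = int(rng.integers(100_000, 1_000_000))
                rows.append(("chr1", s, s + 10_000, s + d, s + d + 10_000))
            return mk_loops(rows)

        q, r = rand(80), rand(80)
        got = capture_overlap(q, r)
        qi = ((q.start1 + q.end1) / 2).to_numpy()
        qj = ((q.start2 + q.end2) / 2).to_numpy()
        ri = ((r.start1 + r.end1) / 2).to_numpy()
        rj = ((r.start2 + r.end2) / 2).to_numpy()
        for k in range(80):
            d = np.sqrt((ri - qi[k]) ** 2 + (rj - qj[k]) ** 2)
            assert got[k] == bool((d < min(0.3 * (qj[k] - qi[k]), 80_000)).any())


@pytest.fixture(scope="module")
def loop_map():
    layout = make_genome([100_000_000], 200_000)
    truth = plant_truth(layout, block_bins=10**6, tad_bins=10**6,
                        n_loops=250, loop_factor=3.0,
                        loop_distance_bins=(15, 80), seed=4)
    cm = simulate_contact_map(layout, truth, depth=1_000_000, seed=7)
    bs = layout.bin_size
    loops = pd.DataFrame({
        "chrom": "chr1",
        "start1": truth.loops.bin1 * bs, "end1": (truth.loops.bin1 + 1) * bs,
        "start2": truth.loops.bin2 * bs, "end2": (truth.loops.bin2 + 1) * bs,
    })
    return layout, cm, loops


class TestApa:
    def test_planted_factor_recovered(self, loop_map):
        _, cm, loops = loop_map
        res = apa(cm, loops)
        assert res["n_loops"] >= 200
        assert res["score"] == pytest.approx(3.0, abs=0.3)

    def test_null_score_one(self, loop_map, rng):
        layout, cm, _ = loop_map
        b1 = rng.integers(15, 400, 250)
        b2 = b1 + rng.integers(15, 80, 250)
        bs = layout.bin_size
        loops = pd.DataFrame({"chrom": "chr1", "start1": b1 * bs, "end1": (b1 + 1) * bs,
                              "start2": b2 * bs, "end2": (b2 + 1) * bs})
        assert apa(cm, loops)["score"] == pytest.approx(1.0, abs=0.1)

    def test_scalar_invariance(self, loop_map):
        layout, cm, loops = loop_map
        from nucleome.contact import ContactMatrix

        cm2 = ContactMatrix(layout=layout, counts=cm.counts * 5.0)
        assert apa(cm2, loops)["score"] == pytest.approx(apa(cm, loops)["score"])

    def test_near_diagonal_loops_skipped(self, loop_map):
        layout, cm, _ = loop_map
        bs = layout.bin_size
        loops = pd.DataFrame({"chrom": "chr1", "start1": [100 * bs], "end1": [101 * bs],
                              "start2": [105 * bs], "end2": [106 * bs]})
        with pytest.raises(ValueError):
            apa(cm, loops)  # only loop is skipped -> no usable loops


class TestAnchorFeatures:
    def test_pure_anchor_state(self, small_layout):
        loops = mk_loops([("chr1", 1_000_000, 1_010_000, 2_000_000, 2_010_000)])
        segs = pd.DataFrame({
            "chrom": ["chr1", "chr1"],
            "start": [900_000, 1_900_000], "end": [1_100_000, 2_100_000],
            "state": ["E1", "E2"],
        })
        f = anchor_state_features(loops, segs, states=["E1", "E2"])
        np.testing.assert_allclose(f["raw"][0], [1, 0, 0, 1])

    def test_swap_invariance(self, small_layout):
        loops_ab, segs, _ = simulate_loops_with_states(small_layout, 2, 30, seed=1)
        swapped_input = loops_ab.rename(columns={
            "start1": "start2", "end1": "end2", "start2": "start1", "end2": "end1"})
        f1 = anchor_state_features(loops_ab, segs)
        f2 = anchor_state_features(swapped_input, segs)
        np.testing.assert_allclose(f1["matrix"], f2["matrix"], atol=1e-12)

    def test_matches_bp_overlap_oracle(self, rng, small_layout):
        loops, segs, _ = simulate_loops_with_states(small_layout, 2, 50, seed=2)
        f = anchor_state_features(loops, segs)
        states = f["states"]
        for k in rng.choice(len(loops), 10, replace=False):
            row = loops.iloc[int(k)]
            for si, state in enumerate(states):
                seg = segs[(segs.chrom == row.chrom) & (segs.state == state)]
                ov = (np.minimum(seg.end, row.end1) - np.maximum(seg.start, row.start1)).clip(lower=0).sum()
                assert f["raw"][int(k), si] == pytest.approx(ov / (row.end1 - row.start1))


class TestClustering:
    def test_duplicates_cocluster_and_single_cluster_data(self):
        x = np.vstack([np.tile([5.0, 0.0, 0.0], (40, 1)),
                       np.tile([0.0, 5.0, 0.0], (40, 1))])
        labels = cluster_loops(x, k_grid=(10, 20), seed=0)
        assert len(np.unique(labels[:40])) == 1
        assert len(np.unique(labels[40:])) == 1
        one = cluster_loops(np.tile([1.0, 2.0, 3.0], (50, 1)), k_grid=(10,), seed=0)
        assert len(np.unique(one)) == 1

    def test_row_permutation_invariance(self, small_layout):
        loops, segs, planted = simulate_loops_with_states(small_layout, 3, 60, seed=5)
        f = anchor_state_features(loops, segs)["matrix"]
        labels = cluster_loops(f, k_grid=(20, 40), seed=0)
        perm = np.random.default_rng(0).permutation(len(f))
        labels_p = cluster_loops(f[perm], k_grid=(20, 40), seed=0)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels[perm], labels_p) == pytest.approx(1.0)

    def test_oversized_grid_truncated(self):
        x = np.random.default_rng(1).normal(size=(30, 4))
        labels = cluster_loops(x, k_grid=(10, 50, 100), seed=0)
        assert len(labels) == 30


class TestEnrichment:
    def test_forced_homotypic_pair_enriched(self, rng):
        chrom_lengths = {"chr1": 50_000_000}
        # state S covers 10% of the genome in one block; T the rest
        segs = pd.DataFrame({
            "chrom": "chr1", "start": [0, 5_000_000],
            "end": [5_000_000, 50_000_000], "state": ["S", "T"],
        })
        s = rng.integers(0, 4_000_000, 200)
        loops = pd.DataFrame({"chrom": "chr1", "start1": s, "end1": s + 10_000,
                              "start2": s + 500_000, "end2": s + 510_000})
        enr = loop_state_pair_enrichment(loops, segs, chrom_lengths,
                                         n_controls=50, seed=0)
        ss = enr[(enr.state1 == "S") & (enr.state2 == "S")]["fold"].iloc[0]
        assert ss > 3

    def test_zero_controls_rejected(self):
        with pytest.raises(ValueError):
            loop_state_pair_enrichment(pd.DataFrame(), pd.DataFrame(), {}, n_controls=0)

    def test_genome_wide_peaks_fold_one(self, rng):
        chrom_lengths = {"chr1": 10_000_000}
        anchors = pd.DataFrame({"chrom": "chr1",
                                "start": rng.integers(0, 9_000_000, 50)})
        anchors["end"] = anchors.start + 10_000
        peaks = {"TF": pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                     "end": [10_000_000]})}
        res = anchor_tf_enrichment(anchors, peaks, chrom_lengths, n_controls=20, seed=0)
        assert res["fold"].iloc[0] == pytest.approx(1.0)

    def test_empty_peak_set(self, rng):
        chrom_lengths = {"chr1": 10_000_000}
        anchors = pd.DataFrame({"chrom": "chr1",
                                "start": rng.integers(0, 9_000_000, 20)})
        anchors["end"] = anchors.start + 10_000
        peaks = {"TF": pd.DataFrame(columns=["chrom", "start", "end"])}
        res = anchor_tf_enrichment(anchors, peaks, chrom_lengths, n_controls=5, seed=0)
        assert res["observed"].iloc[0] == 0 and res["fold"].iloc[0] == 0


class TestLoopStrength:
    def test_planted_and_null(self):
        layout = make_genome([100_000_000], 200_000)
        truth = plant_truth(layout, block_bins=10**6, tad_bins=10**6,
                            n_loops=150, loop_factor=3.0, seed=3)
        cm = simulate_contact_map(layout, truth, depth=2_000_000, seed=3)
        bs = layout.bin_size
        planted = pd.DataFrame({
            "chrom": "chr1",
            "start1": truth.loops.bin1 * bs, "end1": (truth.loops.bin1 + 1) * bs,
            "start2": truth.loops.bin2 * bs, "end2": (truth.loops.bin2 + 1) * bs})
        assert mean_loop_strength(planted, cm) == pytest.approx(3.0, abs=0.4)
        rng = np.random.default_rng(0)
        b1 = rng.integers(10, 400, 150)
        b2 = b1 + rng.integers(10, 60, 150)
        null = pd.DataFrame({"chrom": "chr1", "start1": b1 * bs, "end1": (b1 + 1) * bs,
                             "start2": b2 * bs, "end2": (b2 + 1) * bs})
        assert mean_loop_strength(null, cm) == pytest.approx(1.0, abs=0.2)

    def test_empty_set_rejected(self):
        layout = make_genome([1_000_000], 200_000)
        from nucleome.contact import ContactMatrix

        cm = ContactMatrix(layout=layout, counts=np.ones((5, 5)))
        with pytest.raises(ValueError):
            mean_loop_strength(pd.DataFrame(columns=["chrom"]), cm)


class TestEpLinking:
    def _fixtures(self):
        loops = mk_loops([
            ("chr1", 1_000_000, 1_010_000, 2_000_000, 2_010_000),
            ("chr1", 3_000_000, 3_010_000, 4_000_000, 4_010_000),
        ])
        tss = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [1_005_000, 5_000_000],
                            "gene": ["g1", "g2"]})
        enh = pd.DataFrame({"chrom": ["chr1", "chr1"],
                            "start": [2_001_000, 2_005_000],
                            "end": [2_002_000, 2_006_000]})
        return loops, tss, enh

    def test_two_enhancers_in_far_anchor(self):
        loops, tss, enh = self._fixtures()
        pairs = link_genes_to_enhancers(loops, tss, enh)
        assert set(pairs.gene) == {"g1"}
        assert len(pairs) == 2

    def test_gene_without_loops_counts_zero(self):
        from nucleome.loops import enhancer_counts_per_gene

        loops, tss, enh = self._fixtures()
        pairs = link_genes_to_enhancers(loops, tss, enh)
        counts = enhancer_counts_per_gene(pairs, ["g1", "g2"])
        assert counts["g1"] == 2 and counts["g2"] == 0

    def test_sharing_fractions(self):
        a = pd.DataFrame({"gene": ["g1", "g1", "g2"], "enhancer_id": ["e1", "e2", "e3"]})
        b = pd.DataFrame({"gene": ["g1", "g2"], "enhancer_id": ["e1", "e4"]})
        res = classify_ep_sharing(a, b)
        # union = {g1e1, g1e2, g2e3, g2e4}; shared = {g1e1}
        assert res["n_pairs"] == 4
        assert res["shared_fraction"] == pytest.approx(0.25)
        assert classify_ep_sharing(a, a)["shared_fraction"] == 1.0


class TestExpression:
    def test_breadth_matches_stepwise_oracle(self):
        tpm = pd.DataFrame(
            [[100.0, 90.0, 80.0, 70.0, 60.0, 50.0],
             [10.0, 0.0, 12.0, 0.0, 9.0, 0.0],
             [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
             [50.0, 60.0, 40.0, 55.0, 45.0, 65.0]],
            index=["hk", "patchy", "silent", "broad"],
            columns=[f"t{i}" for i in range(6)],
        )
        # oracle: explicit log2 / rank / mean-of-sorted substitution
        logt = np.log2(tpm + 1)
        sorted_means = np.sort(logt.to_numpy(), axis=0).mean(axis=1)
        oracle = logt.rank().apply(lambda r: np.interp(r, [1, 2, 3, 4], sorted_means))
        want = (oracle > 3).sum(axis=1)
        got = expression_breadth(tpm)
        pd.testing.assert_series_equal(got, want)
        assert got["silent"] == 0

    def test_quartiles_hand_computed(self):
        rpkm = pd.Series([0.0, 1, 2, 3, 4, 5, 6, 7, 8],
                         index=[f"g{i}" for i in range(9)])
        cls = expression_quartiles(rpkm)
        # non-zero quartiles over 1..8: Q1 = 2.75, Q3 = 6.25
        assert cls["g0"] == "silent"
        assert (cls[["g1", "g2"]] == "low").all()
        assert (cls[["g7", "g8"]] == "high").all()
        assert (cls[["g3", "g4", "g5", "g6"]] == "mid").all()

    def test_equal_values_give_no_extremes(self):
        cls = expression_quartiles(pd.Series([5.0] * 6))
        assert (cls == "mid").all()


class TestTssDecay:
    def test_single_tss_equals_row_slice(self, rng):
        layout = make_genome([20_000_000], 200_000)
        from conftest import random_matrix
        from nucleome.contact import ContactMatrix

        cm = ContactMatrix(layout=layout, counts=random_matrix(rng, layout))
        tss = pd.DataFrame({"chrom": ["chr1"], "pos": [10_000_000], "gene": ["g"]})
        res = tss_contact_decay(cm, tss, half_window_bp=1_000_000)
        b = layout.bin_of("chr1", 10_000_000)
        np.testing.assert_array_equal(res["profile"], cm.counts[b, b - 5 : b + 6])

    def test_edge_tss_truncated_and_mean_oracle(self, rng):
        layout = make_genome([20_000_000], 200_000)
        from conftest import random_matrix
        from nucleome.contact import ContactMatrix

        cm = ContactMatrix(layout=layout, counts=random_matrix(rng, layout))
        pos = rng.integers(1_200_000, 18_800_000, 20)
        tss = pd.DataFrame({"chrom": "chr1", "pos": pos, "gene": [f"g{i}" for i in range(20)]})
        res = tss_contact_decay(cm, tss, half_window_bp=1_000_000)
        stack = np.vstack([
            cm.counts[layout.bin_of("chr1", int(p)),
                      layout.bin_of("chr1", int(p)) - 5 : layout.bin_of("chr1", int(p)) + 6]
            for p in pos])
        np.testing.assert_allclose(res["profile"], stack.mean(axis=0))
        edge = pd.DataFrame({"chrom": ["chr1"], "pos": [100_000], "gene": ["e"]})
        with pytest.raises(ValueError):
            tss_contact_decay(cm, edge, half_window_bp=1_000_000)
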