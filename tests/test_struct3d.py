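"""Structural features of 3D genome structure populations."""

import numpy as np
import pandas as pd
import pytest

from nucleome.layout import make_genome
from nucleome.simdata import NuclearGeometry, StructurePopulation
from nucleome.struct3d import (
    association_frequencies,
    body_distances,
    classify_expression_classes,
    enhancer_density_features,
    feature_enrichment,
    icp,
    ilf,
    lamina_distance,
    local_compaction,
    markov_clustering,
    predict_bodies,
    rad,
    radial_positions,
    spatial_enhancer_count,
    trans_ab_ratio,
    variability,
)


def build_pop(coords, bead_bin, bead_allele, geom=None, layout=None, n_bins=None):
    if layout is None:
        n = n_bins or int(np.max(bead_bin)) + 1
        layout = make_genome([n * 200_000], 200_000)
    geom = geom or NuclearGeometry.sphere(5000.0)
    return StructurePopulation(
        layout=layout, geometry=geom, coords=np.asarray(coords, float),
        bead_bin=np.asarray(bead_bin), bead_allele=np.asarray(bead_allele),
    )


def diploid_single_bin(positions_a, positions_b, geom=None):
    """One region, two alleles; positions per structure for each allele."""
    S = len(positions_a)
    coords = np.stack([np.asarray(positions_a), np.asarray(positions_b)], axis=1)
    return build_pop(coords, [0, 0], [0, 1], geom=geom)


class TestRadial:
    def test_origin_and_envelope(self):
        geom = NuclearGeometry.sphere(5000.0)
        pop = diploid_single_bin([[0, 0, 0]], [[0, 0, 0]], geom)
        assert rad(pop)[0] == pytest.approx(0.0, abs=1e-9)
        pop2 = diploid_single_bin([[5000, 0, 0]], [[0, 5000, 0]], geom)
        assert rad(pop2)[0] == pytest.approx(1.0, abs=1e-9)

    def test_ellipsoid_normalization(self):
        geom = NuclearGeometry(7840.0, 6480.0, 2450.0)
        pop = diploid_single_bin([[7840, 0, 0]], [[0, 0, 2450]], geom)
        r = radial_positions(pop)
        np.testing.assert_allclose(r, 1.0)

    def test_isotropic_scaling_invariance(self, rng):
        geom = NuclearGeometry.sphere(5000.0)
        xs = rng.normal(scale=1000, size=(10, 2, 3))
        pop = build_pop(xs, [0, 0], [0, 1], geom)
        pop2 = build_pop(xs * 2, [0, 0], [0, 1], NuclearGeometry.sphere(10000.0))
        np.testing.assert_allclose(rad(pop), rad(pop2))


class TestVariability:
    def test_constant_feature_undefined(self):
        per = np.ones((10, 4))
        out = variability(per, np.zeros(4, dtype=int))
        assert np.isnan(out).all()

    def test_double_sd_is_one_log2_unit(self):
        rngs = np.random.default_rng(0)
        base = rngs.normal(size=(4000, 3))
        per = np.column_stack([base[:, 0], base[:, 1], 2 * base[:, 2]])
        # chromosome-mean sd ~ (1+1+2)/3; log2(2/(4/3)) = log2(1.5)
        out = variability(per, np.zeros(3, dtype=int))
        sd = per.std(axis=0)
        want = np.log2(sd / sd.mean())
        np.testing.assert_allclose(out, want, rtol=1e-9)

    def test_matches_bruteforce_by_chromosome(self, rng):
        per = rng.normal(size=(50, 6))
        chrom = np.array([0, 0, 0, 1, 1, 1])
        out = variability(per, chrom)
        for c in (0, 1):
            m = chrom == c
            sd = per[:, m].std(axis=0)
            np.testing.assert_allclose(out[m], np.log2(sd / sd.mean()))


class TestLocalCompaction:
    def test_coincident_beads_zero(self):
        layout = make_genome([1_000_000], 200_000)
        coords = np.zeros((3, 10, 3))
        pop = build_pop(coords, list(range(5)) * 2, [0] * 5 + [1] * 5, layout=layout)
        np.testing.assert_allclose(local_compaction(pop), 0.0, atol=1e-12)

    def test_collinear_beads_closed_form(self):
        layout = make_genome([1_000_000], 200_000)
        # 5 beads spaced 100 nm on a line; Rg^2 = mean((x - xbar)^2) = 2e4
        xs = np.zeros((1, 10, 3))
        xs[0, :5, 0] = np.arange(5) * 100.0
        xs[0, 5:, 0] = np.arange(5) * 100.0
        pop = build_pop(xs, list(range(5)) * 2, [0] * 5 + [1] * 5, layout=layout)
        rg = local_compaction(pop, window_bp=2_000_000)  # window spans all 5 beads
        want = np.sqrt(np.mean((np.arange(5) * 100.0 - 200.0) ** 2))
        assert rg[2] == pytest.approx(want)

    def test_homogeneous_degree_one(self, rng):
        layout = make_genome([1_000_000], 200_000)
        xs = rng.normal(scale=500, size=(4, 10, 3))
        pop = build_pop(xs, list(range(5)) * 2, [0] * 5 + [1] * 5, layout=layout)
        pop2 = build_pop(xs * 2, list(range(5)) * 2, [0] * 5 + [1] * 5, layout=layout)
        np.testing.assert_allclose(local_compaction(pop2), 2 * local_compaction(pop))


class TestIcpIlf:
    def test_icp_extremes(self):
        layout = make_genome([400_000, 400_000], 200_000)
        # bins 0,1 on chr1; 2,3 on chr2; beads stacked by allele
        coords = np.zeros((2, 8, 3))
        # structure geometry: bin0/bin1 beads close (cis only), far from chr2
        coords[:, [0, 4], 0] = 0.0      # bin0 alleles
        coords[:, [1, 5], 0] = 100.0    # bin1 alleles near bin0 -> cis contacts
        coords[:, [2, 6], 0] = 4000.0   # chr2 isolated
        coords[:, [3, 7], 0] = -4000.0
        pop = build_pop(coords, [0, 1, 2, 3] * 2, [0] * 4 + [1] * 4, layout=layout)
        v = icp(pop, contact_radius=500.0)
        assert v[0] == 0.0 and v[1] == 0.0       # only cis neighbours
        # move one chr2 bead next to bin0 (its allele stays isolated):
        # that bead's contacts are exclusively trans
        coords2 = coords.copy()
        coords2[:, 2, 0] = 150.0
        pop2 = build_pop(coords2, [0, 1, 2, 3] * 2, [0] * 4 + [1] * 4, layout=layout)
        v2 = icp(pop2, contact_radius=500.0)
        assert v2[2] == 1.0

    def test_icp_matches_bruteforce(self, small_population):
        pop = small_population
        radius = 700.0
        got = icp(pop, radius)
        ch = pop.bead_chrom
        n = pop.layout.n_bins
        sums = np.zeros(pop.n_beads)
        cnts = np.zeros(pop.n_beads)
        for s in range(pop.n_structures):
            for b in range(pop.n_beads):
                ntr = ncis = 0
                for o in range(pop.n_beads):
                    if o == b:
                        continue
                    if np.linalg.norm(pop.coords[s, b] - pop.coords[s, o]) <= radius:
                        if ch[o] == ch[b]:
                            ncis += 1
                        else:
                            ntr += 1
                if ntr + ncis:
                    sums[b] += ntr / (ntr + ncis)
                    cnts[b] += 1
        for bb in range(n):
            beads = np.flatnonzero(pop.bead_bin == bb)
            vals = [sums[b] / cnts[b] for b in beads if cnts[b] > 0]
            if vals:
                assert got[bb] == pytest.approx(np.mean(vals), abs=1e-12)
            else:
                assert np.isnan(got[bb])

    def test_ilf_extremes_and_half(self):
        geom = NuclearGeometry.sphere(5000.0)
        inner = diploid_single_bin([[2000, 0, 0]] * 4, [[2000, 0, 0]] * 4, geom)
        assert ilf(inner)[0] == 1.0
        outer = diploid_single_bin([[4500, 0, 0]] * 4, [[4500, 0, 0]] * 4, geom)
        assert ilf(outer)[0] == 0.0
        half = diploid_single_bin(
            [[2000, 0, 0], [2000, 0, 0], [4500, 0, 0], [4500, 0, 0]],
            [[4500, 0, 0]] * 4, geom)
        assert ilf(half)[0] == 0.5


class TestTransAB:
    def test_extremes_map_to_unit_interval(self):
        """Queries with all-A, all-B and mixed trans neighbourhoods span
        the full [0, 1] range after capping and rescale."""
        layout = make_genome([200_000] * 5, 200_000)
        geom = NuclearGeometry.sphere(9000.0)
        # bins 0-2 are queries (clusters far apart); bins 3 (A) and 4 (B)
        # provide labelled trans neighbours
        coords = np.zeros((1, 10, 3))
        coords[0, 0] = [0, 0, 0]            # query: all-A neighbourhood
        coords[0, 3] = [100, 0, 0]          # A neighbour
        coords[0, 1] = [5000, 0, 0]         # query: all-B neighbourhood
        coords[0, 4] = [5100, 0, 0]         # B neighbour
        coords[0, 2] = [0, 5000, 0]         # query: mixed neighbourhood
        coords[0, 8] = [100, 5000, 0]       # A allele neighbour
        coords[0, 9] = [-100, 5000, 0]      # B allele neighbour
        coords[0, 5] = [0, 0, 6000]         # remaining alleles isolated
        coords[0, 6] = [0, 0, -6000]
        coords[0, 7] = [6000, 0, 6000]
        pop = build_pop(coords, [0, 1, 2, 3, 4, 0, 1, 2, 3, 4],
                        [0, 0, 0, 0, 0, 1, 1, 1, 1, 1], geom=geom, layout=layout)
        ab = np.array([1, 1, 1, 1, -1])     # bin3 = A, bin4 = B
        v = trans_ab_ratio(pop, ab, radius=500.0)
        assert v[0] == 1.0                  # all-A: inf capped to finite max
        assert v[1] == 0.0                  # all-B
        assert 0.0 < v[2] <= 1.0            # mixed

    def test_matches_bruteforce(self, small_population, small_layout):
        from nucleome.simdata import plant_truth

        truth = plant_truth(small_layout, block_bins=5, tad_bins=10)
        labels = truth.compartments
        got = trans_ab_ratio(small_population, labels, radius=900.0)
        pop = small_population
        ch = pop.bead_chrom
        bead_lab = labels[pop.bead_bin]
        pooled = [[] for _ in range(pop.layout.n_bins)]
        for s in range(pop.n_structures):
            for b in range(pop.n_beads):
                nA = nB = 0
                for o in range(pop.n_beads):
                    if o == b or ch[o] == ch[b]:
                        continue
                    if np.linalg.norm(pop.coords[s, b] - pop.coords[s, o]) <= 900.0:
                        if bead_lab[o] > 0:
                            nA += 1
                        elif bead_lab[o] < 0:
                            nB += 1
                if nA + nB:
                    pooled[pop.bead_bin[b]].append(np.inf if nB == 0 else nA / nB)
        allvals = np.concatenate([v for v in pooled if v])
        cap = allvals[np.isfinite(allvals)].max()
        med = np.full(pop.layout.n_bins, np.nan)
        for b, vals in enumerate(pooled):
            if vals:
                med[b] = np.median(np.minimum(vals, cap))
        lo, hi = np.nanmin(med), np.nanmax(med)
        want = (med - lo) / (hi - lo)
        np.testing.assert_allclose(got, want, equal_nan=True, atol=1e-12)


class TestMcl:
    def test_identity_graph_singletons(self):
        parts = markov_clustering(np.zeros((5, 5)))
        assert sorted(len(p) for p in parts) == [1] * 5

    def test_two_triangles(self):
        a = np.zeros((6, 6))
        for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            a[i, j] = a[j, i] = 1.0
        parts = sorted(markov_clustering(a), key=lambda p: p[0])
        assert [list(p) for p in parts] == [[0, 1, 2], [3, 4, 5]]

    def test_disjoint_cliques_equal_connected_components(self, rng):
        import networkx as nx

        a = np.zeros((12, 12))
        for block in (range(0, 4), range(4, 9), range(9, 12)):
            for i in block:
                for j in block:
                    if i < j:
                        a[i, j] = a[j, i] = 1.0
        parts = {frozenset(p.tolist()) for p in markov_clustering(a)}
        g = nx.from_numpy_array(a)
        comps = {frozenset(c) for c in nx.connected_components(g)}
        assert parts == comps

    def test_inflation_bound(self):
        with pytest.raises(ValueError):
            markov_clustering(np.zeros((3, 3)), inflation=1.0)


class TestBodies:
    def test_two_tight_groups(self):
        layout = make_genome([1_600_000], 200_000)
        geom = NuclearGeometry.sphere(8000.0)
        coords = np.zeros((1, 16, 3))
        rng = np.random.default_rng(0)
        coords[0, :8] = rng.normal(scale=50, size=(8, 3))
        coords[0, 8:] = [5000, 0, 0] + rng.normal(scale=50, size=(8, 3))
        pop = build_pop(coords, list(range(8)) * 2, [0] * 8 + [1] * 8,
                        geom=geom, layout=layout)
        bodies = predict_bodies(pop, np.arange(8), distance_cutoff=500.0)
        assert len(bodies[0]) == 2
        centres = bodies[0][np.argsort(bodies[0][:, 0])]
        np.testing.assert_allclose(centres[0], coords[0, :8].mean(axis=0), atol=1e-9)
        np.testing.assert_allclose(centres[1], coords[0, 8:].mean(axis=0), atol=1e-9)

    def test_partition_of_three_discarded(self):
        layout = make_genome([600_000], 200_000)
        geom = NuclearGeometry.sphere(8000.0)
        coords = np.zeros((1, 6, 3))
        coords[0, 3:] = [[6000, 0, 0], [0, 6000, 0], [0, 0, 6000]]  # isolated alleles
        pop = build_pop(coords, [0, 1, 2] * 2, [0] * 3 + [1] * 3,
                        geom=geom, layout=layout)
        bodies = predict_bodies(pop, np.arange(3), distance_cutoff=500.0)
        assert len(bodies[0]) == 0  # only partitions of size 3 or singletons


class TestBodyDistancesAndAssociation:
    def test_bead_at_body_centre(self):
        pop = diploid_single_bin([[1000, 0, 0]] * 3, [[1000, 0, 0]] * 3)
        bodies = [np.array([[1000.0, 0, 0]])] * 3
        assert body_distances(pop, bodies)[0] == pytest.approx(0.0)

    def test_nearest_body_bruteforce(self, small_population, rng):
        pop = small_population
        bodies = [rng.normal(scale=2000, size=(3, 3)) for _ in range(pop.n_structures)]
        got = body_distances(pop, bodies)
        n = pop.layout.n_bins
        per = np.zeros((pop.n_structures, n))
        for s in range(pop.n_structures):
            for b in range(n):
                beads = np.flatnonzero(pop.bead_bin == b)
                d = [min(np.linalg.norm(pop.coords[s, bd] - body) for body in bodies[s])
                     for bd in beads]
                per[s, b] = np.mean(d)
        np.testing.assert_allclose(got, per.mean(axis=0), rtol=1e-9)

    def test_lamina_distance_centre(self):
        pop = diploid_single_bin([[0, 0, 0]] * 2, [[0, 0, 0]] * 2)
        assert lamina_distance(pop)[0] == pytest.approx(1.0)

    def test_saf_extremes_and_boundary(self):
        pop = diploid_single_bin([[1000, 0, 0]] * 4, [[1000, 0, 0]] * 4)
        near = [np.array([[1100.0, 0, 0]])] * 4       # 100 nm away
        exact = [np.array([[1500.0, 0, 0]])] * 4      # exactly 500 nm
        far = [np.array([[4000.0, 0, 0]])] * 4
        assert association_frequencies(pop, speckles=near)["SAF"][0] == 1.0
        assert association_frequencies(pop, speckles=exact)["SAF"][0] == 1.0
        assert association_frequencies(pop, speckles=far)["SAF"][0] == 0.0

    def test_laf_at_half_radius_zero(self):
        pop = diploid_single_bin([[2500, 0, 0]] * 3, [[2500, 0, 0]] * 3)
        assert association_frequencies(pop)["LAF"][0] == 0.0
        hugging = diploid_single_bin([[4500, 0, 0]] * 3, [[4500, 0, 0]] * 3)
        assert association_frequencies(hugging)["LAF"][0] == 1.0

    def test_saf_monotone_in_cutoff(self, small_population):
        pop = small_population
        a = association_frequencies(pop, speckles=pop.speckles, saf_cutoff=300.0)["SAF"]
        b = association_frequencies(pop, speckles=pop.speckles, saf_cutoff=800.0)["SAF"]
        assert (b >= a - 1e-12).all()


class TestClassification:
    def test_class_i_ii_enumeration(self):
        saf = np.array([0.9, 0.8, 0.5, 0.5, 0.45, 0.4, 0.35, 0.3, 0.2, 0.1, 0.05, 0.5])
        expr = pd.Series(
            ["high", "high", "high", "low", "mid", "high",
             "high", "mid", "high", "high", "silent", "high"],
            index=[f"g{i}" for i in range(12)],
        )
        gene_bin = pd.Series(range(12), index=expr.index)
        res = classify_expression_classes(expr, saf, gene_bin)
        q1, q3 = np.quantile(saf, [0.25, 0.75])
        want1 = [g for g in expr.index
                 if expr[g] == "high" and saf[gene_bin[g]] > q3]
        want2 = [g for g in expr.index
                 if expr[g] == "high" and saf[gene_bin[g]] < q1]
        assert res["class_I"] == want1
        assert res["class_II"] == want2


class TestSpatialEnhancers:
    def test_no_enhancers_zero(self, small_population):
        res = spatial_enhancer_count(small_population, np.array([3]), np.array([], dtype=int))
        assert res[["intra", "intra_gt1mb", "inter"]].to_numpy().sum() == 0

    def test_permanent_inter_neighbour(self):
        layout = make_genome([200_000, 200_000], 200_000)
        coords = np.zeros((3, 4, 3))
        coords[:, 1, 0] = 100.0          # enhancer bead (chr2) 100 nm away
        coords[:, 2, 0] = 5000.0         # far alleles
        coords[:, 3, 1] = 5000.0
        pop = build_pop(coords, [0, 1, 0, 1], [0, 0, 1, 1],
                        geom=NuclearGeometry.sphere(8000.0), layout=layout)
        res = spatial_enhancer_count(pop, np.array([0]), np.array([1]), radius=350.0)
        # one allele pair always within 350 nm, the other never: mean 0.5
        assert res["inter"].iloc[0] == pytest.approx(0.5)
        assert res["intra"].iloc[0] == 0.0

    def test_matches_bruteforce_sphere_query(self, small_population, small_layout):
        pop = small_population
        tss_bins = np.array([10, 40])
        enh_bins = np.array([5, 20, 60, 70])
        radius = 900.0
        res = spatial_enhancer_count(pop, tss_bins, enh_bins, radius=radius)
        ch = small_layout.bin_chrom
        mids = small_layout.bin_mids()
        enh_beads = np.flatnonzero(np.isin(pop.bead_bin, enh_bins))
        for row in res.itertuples(index=False):
            t = row.bin
            acc_intra = acc_inter = acc_ultra = 0.0
            n_ev = 0
            for s in range(pop.n_structures):
                for tb in np.flatnonzero(pop.bead_bin == t):
                    n_ev += 1
                    for eb in enh_beads:
                        if eb == tb:
                            continue
                        d = np.linalg.norm(pop.coords[s, eb] - pop.coords[s, tb])
                        if d <= radius:
                            e = pop.bead_bin[eb]
                            if ch[e] == ch[t]:
                                acc_intra += 1
                                if abs(mids[e] - mids[t]) > 1_000_000:
                                    acc_ultra += 1
                            else:
                                acc_inter += 1
            assert row.intra == pytest.approx(acc_intra / n_ev)
            assert row.inter == pytest.approx(acc_inter / n_ev)
            assert row.intra_gt1mb == pytest.approx(acc_ultra / n_ev)


class TestFeatureEnrichment:
    def test_whole_genome_group_zero(self, rng):
        feats = pd.DataFrame({"RAD": rng.uniform(size=200), "RG": rng.uniform(size=200)})
        out = feature_enrichment(feats, np.ones(200, dtype=bool), n_perm=20, seed=0)
        np.testing.assert_allclose(out.to_numpy(), 0.0, atol=1e-12)

    def test_top_decile_enriched(self, rng):
        v = rng.uniform(size=300)
        feats = pd.DataFrame({"SAF": v})
        group = v >= np.quantile(v, 0.9)
        out = feature_enrichment(feats, group, n_perm=50, seed=1)
        assert out["SAF"] > 0

    def test_random_group_near_zero(self, rng):
        feats = pd.DataFrame({"ICP": rng.uniform(size=500)})
        group = np.zeros(500, dtype=bool)
        group[rng.choice(500, 150, replace=False)] = True
        out = feature_enrichment(feats, group, n_perm=100, seed=2)
        assert abs(out["ICP"]) < 0.1

    def test_inverted_features(self, rng):
        v = rng.uniform(size=300)
        feats = pd.DataFrame({"RAD": v})
        group = v >= np.quantile(v, 0.9)    # most peripheral regions
        out = feature_enrichment(feats, group, n_perm=50, seed=3)
        assert out["RAD"] < 0               # RAD inverted: peripheral = depleted


class TestEnhancerDensity:
    def test_hand_enumerated_window(self):
        layout = make_genome([600_000], 200_000)
        enh = pd.DataFrame({
            "chrom": "chr1",
            "start": [10_000, 50_000, 90_000, 130_000, 250_000],
            "end": [11_000, 51_000, 91_000, 131_000, 251_000],
        })
        tss = pd.DataFrame({"chrom": "chr1", "pos": [20_000, 180_000, 420_000],
                            "gene": ["g1", "g2", "g3"]})
        res = enhancer_density_features(layout, enh, tss).set_index("gene")
        assert res.loc["g1", "E"] == 4 and res.loc["g1", "E_per_G"] == 2.0
        assert res.loc["g3", "E"] == 0
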