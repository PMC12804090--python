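"""Per-locus structural features from a population of 3D genome structures.

Given S diploid structures of bead centres inside a nuclear envelope,
computes radial position (RAD), local compaction (radius of gyration,
RG), interchromosomal contact proportion (ICP), interior localization
frequency (ILF), the trans A/B neighbourhood ratio (transAB), distances
and association frequencies to nuclear bodies (SpD/NuD/LaD and
SAF/NAF/LAF), cell-to-cell variability of any per-structure feature,
nuclear-body prediction via Markov clustering of chromatin interaction
networks, structure-feature enrichment folds, class I/II gene
categorization and spatial enhancer counts around TSS loci.

Feature averages follow the population convention: per structure the two
alleles are averaged (the 1/2 sum over i in I), then the structures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simdata import StructurePopulation

__all__ = [
    "radial_positions",
    "rad",
    "variability",
    "local_compaction",
    "icp",
    "ilf",
    "trans_ab_ratio",
    "markov_clustering",
    "predict_bodies",
    "body_distances",
    "association_frequencies",
    "classify_expression_classes",
    "spatial_enhancer_count",
    "feature_enrichment",
    "enhancer_density_features",
]

SAF_CUTOFF_NM = 500.0
NAF_CUTOFF_NM = 1000.0
LAF_CUTOFF = 0.2


def _per_structure_region(pop: StructurePopulation, bead_values: np.ndarray) -> np.ndarray:
    """Average a (S, n_beads) bead array over alleles -> (S, n_bins)."""
    n = pop.layout.n_bins
    out = np.zeros((pop.n_structures, n))
    for allele in (0, 1):
        sel = pop.bead_allele == allele
        out[:, pop.bead_bin[sel]] += bead_values[:, sel] / 2.0
    return out


def radial_positions(pop: StructurePopulation) -> np.ndarray:
    """Normalized radial distance r_is per (structure, bead)."""
    return pop.radial()


def rad(pop: StructurePopulation, per_structure: bool = False) -> np.ndarray:
    """RAD: normalized average radial position per region (0 = centre,
    1 = envelope), averaging the two alleles and all structures."""
    r = _per_structure_region(pop, radial_positions(pop))
    return r if per_structure else r.mean(axis=0)


def variability(per_structure_feature: np.ndarray, chrom_of_region: np.ndarray) -> np.ndarray:
    """Cell-to-cell variability delta-f on a log2 scale.

    delta-f = log2( sd_I / mean chromosome sd ), the region's SD across
    structures over the mean SD of regions on the same chromosome;
    positive = more variable than its chromosome.  Undefined (NaN) where
    the chromosome-mean SD is zero.
    """
    sd = np.asarray(per_structure_feature).std(axis=0)
    out = np.full(sd.shape, np.nan)
    for c in np.unique(chrom_of_region):
        m = chrom_of_region == c
        denom = sd[m].mean()
        if denom > 0:
            with np.errstate(divide="ignore"):
                out[m] = np.log2(sd[m] / denom)
    return out


def local_compaction(
    pop: StructurePopulation, window_bp: int = 1_000_000, per_structure: bool = False
) -> np.ndarray:
    """RG: radius of gyration of the +-window/2 chromatin segment.

    Standard radius of gyration of the bead centres of the window around
    each locus, per structure and allele; chromosome ends use the
    truncated window.
    """
    half_bins = max(1, window_bp // (2 * pop.layout.bin_size))
    S, nb = pop.n_structures, pop.n_beads
    rg_bead = np.zeros((S, nb))
    layout = pop.layout
    for allele in (0, 1):
        off = allele * layout.n_bins
        for c in range(layout.n_chroms):
            sl = layout.chrom_slice(c)
            for i in range(sl.start, sl.stop):
                lo = max(sl.start, i - half_bins) + off
                hi = min(sl.stop, i + half_bins + 1) + off
                seg = pop.coords[:, lo:hi, :]
                centroid = seg.mean(axis=1, keepdims=True)
                rg_bead[:, off + i] = np.sqrt(((seg - centroid) ** 2).sum(-1).mean(1))
    per = _per_structure_region(pop, rg_bead)
    return per if per_structure else per.mean(axis=0)


def _neighbour_masks(pop: StructurePopulation, s: int, radius: float) -> np.ndarray:
    x = pop.coords[s]
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
    hit = d2 <= radius**2
    np.fill_diagonal(hit, False)
    return hit


def icp(pop: StructurePopulation, contact_radius: float = 500.0) -> np.ndarray:
    """ICP: fraction of trans contacts among all contacts of a region.

    Per (bead, structure) the ratio n_trans/(n_trans + n_cis) over
    neighbours within the contact radius; beads with no contacts in a
    structure are excluded from that bead's average.
    """
    ch = pop.bead_chrom
    sums = np.zeros(pop.n_beads)
    cnts = np.zeros(pop.n_beads)
    for s in range(pop.n_structures):
        hit = _neighbour_masks(pop, s, contact_radius)
        trans = hit & (ch[:, None] != ch[None, :])
        n_tr = trans.sum(axis=1).astype(float)
        n_all = hit.sum(axis=1).astype(float)
        ok = n_all > 0
        sums[ok] += n_tr[ok] / n_all[ok]
        cnts[ok] += 1
    with np.errstate(invalid="ignore"):
        bead_icp = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    # allele average per region (NaN-aware)
    n = pop.layout.n_bins
    out = np.full(n, np.nan)
    for b in range(n):
        v = bead_icp[pop.bead_bin == b]
        v = v[np.isfinite(v)]
        if v.size:
            out[b] = v.mean()
    return out


def ilf(pop: StructurePopulation, inner_r: float = 0.5) -> np.ndarray:
    """ILF: fraction of structures where either allele sits at r <= 1/2."""
    r = radial_positions(pop)
    n = pop.layout.n_bins
    inner_any = np.zeros((pop.n_structures, n), dtype=bool)
    for allele in (0, 1):
        sel = pop.bead_allele == allele
        inner_any[:, pop.bead_bin[sel]] |= r[:, sel] <= inner_r
    return inner_any.mean(axis=0)


def trans_ab_ratio(
    pop: StructurePopulation,
    ab_labels: np.ndarray,
    radius: float = 500.0,
) -> np.ndarray:
    """transAB: median trans A-to-B neighbour ratio, min-max rescaled.

    For each (bead, structure), counts trans neighbours within the radius
    labelled A and B; the per-region value is the median of the pooled
    n_A/n_B ratios across homologues and structures.  Infinite ratios
    (n_B = 0) are capped at the largest finite pooled ratio before the
    medians and the genome-wide min-max rescale to [0, 1] are taken.
    """
    ch = pop.bead_chrom
    lab = np.asarray(ab_labels)
    bead_lab = lab[pop.bead_bin]
    pooled: list[list[float]] = [[] for _ in range(pop.layout.n_bins)]
    for s in range(pop.n_structures):
        hit = _neighbour_masks(pop, s, radius)
        trans = hit & (ch[:, None] != ch[None, :])
        nA = (trans & (bead_lab[None, :] > 0)).sum(axis=1)
        nB = (trans & (bead_lab[None, :] < 0)).sum(axis=1)
        for bead in range(pop.n_beads):
            if nA[bead] + nB[bead] == 0:
                continue
            ratio = nA[bead] / nB[bead] if nB[bead] > 0 else np.inf
            pooled[pop.bead_bin[bead]].append(ratio)
    allvals = np.concatenate([v for v in pooled if v] or [[np.nan]])
    finite = allvals[np.isfinite(allvals)]
    cap = finite.max() if finite.size else 1.0
    med = np.full(pop.layout.n_bins, np.nan)
    for b, vals in enumerate(pooled):
        if vals:
            med[b] = np.median(np.minimum(vals, cap))
    lo = np.nanmin(med)
    hi = np.nanmax(med)
    if hi > lo:
        return (med - lo) / (hi - lo)
    return np.where(np.isfinite(med), 0.0, np.nan)


def markov_clustering(
    adjacency: np.ndarray,
    inflation: float = 2.0,
    prune_threshold: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> list[np.ndarray]:
    """Markov clustering (MCL) of an undirected graph.

    Column-stochastic normalization with self-loops, then alternating
    expansion (matrix square) and inflation (elementwise power,
    renormalize) with pruning until the matrix change falls below `tol`.
    Clusters are read from the converged matrix as connected groups of
    nodes sharing attractors.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    n = a.shape[0]
    m = a + np.eye(n)
    m = m / m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = m
        m = m @ m
        m = np.power(m, inflation)
        m[m < prune_threshold] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m = m / colsum
        if np.abs(m - prev).max() < tol:
            break
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n))
    ii, jj = np.nonzero(m > prune_threshold)
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    return [np.asarray(sorted(c)) for c in nx.connected_components(g)]


def predict_bodies(
    pop: StructurePopulation,
    associated_bins: np.ndarray,
    distance_cutoff: float,
    inflation: float = 2.0,
    min_partition_size: int = 4,
) -> list[np.ndarray]:
    """Nuclear-body locations per structure via MCL on the chromatin
    interaction network of body-associated regions.

    Per structure, the CIN has body-associated beads as nodes and edges
    where the pairwise distance is below the cutoff; MCL partitions it,
    partitions of size > 3 are kept and the body is the geometric centre
    of the partition's beads.  Structures without a valid partition get
    an empty (0, 3) array.
    """
    beads = np.flatnonzero(np.isin(pop.bead_bin, associated_bins))
    bodies = []
    for s in range(pop.n_structures):
        x = pop.coords[s, beads]
        d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
        a = (d2 < distance_cutoff**2).astype(float)
        np.fill_diagonal(a, 0.0)
        parts = markov_clustering(a, inflation=inflation)
        centres = [
            x[p].mean(axis=0) for p in parts if len(p) >= min_partition_size
        ]
        bodies.append(np.vstack(centres) if centres else np.zeros((0, 3)))
    return bodies


def body_distances(
    pop: StructurePopulation, bodies: list[np.ndarray], per_structure: bool = False
) -> np.ndarray:
    """Distance to the nearest body per region (SpD / NuD machinery).

    Per structure and bead, the Euclidean distance to the nearest body
    centre; allele-averaged per region and averaged over the structures
    with at least one body (others are excluded from the mean).
    """
    n = pop.layout.n_bins
    per = np.full((pop.n_structures, n), np.nan)
    for s in range(pop.n_structures):
        if len(bodies[s]) == 0:
            continue
        x = pop.coords[s]
        d = np.sqrt(((x[:, None, :] - bodies[s][None, :, :]) ** 2).sum(-1)).min(axis=1)
        per[s] = _per_structure_region(pop, d[None, :])[0]
    if per_structure:
        return per
    with np.errstate(invalid="ignore"):
        return np.nanmean(per, axis=0)


def lamina_distance(pop: StructurePopulation, per_structure: bool = False) -> np.ndarray:
    """LaD: normalized distance to the envelope, 1 - r."""
    per = _per_structure_region(pop, 1.0 - radial_positions(pop))
    return per if per_structure else per.mean(axis=0)


def association_frequencies(
    pop: StructurePopulation,
    speckles: list[np.ndarray] | None = None,
    nucleoli: list[np.ndarray] | None = None,
    saf_cutoff: float = SAF_CUTOFF_NM,
    naf_cutoff: float = NAF_CUTOFF_NM,
    laf_cutoff: float = LAF_CUTOFF,
) -> dict[str, np.ndarray]:
    """SAF / NAF / LAF association frequencies per region.

    A (structure, allele) event is associated when the distance to the
    nearest speckle (nucleolus) is <= 500 nm (1,000 nm), or when the
    normalized lamina distance 1 - r is <= 0.2; the boundary counts as
    associated.  Structures lacking a body are excluded from that
    region's SAF/NAF denominator.
    """
    out = {}
    r = radial_positions(pop)
    lam_assoc = _per_structure_region(pop, ((1.0 - r) <= laf_cutoff).astype(float))
    out["LAF"] = lam_assoc.mean(axis=0)
    for name, blist, cut in (("SAF", speckles, saf_cutoff), ("NAF", nucleoli, naf_cutoff)):
        if blist is None:
            continue
        per = np.full((pop.n_structures, pop.layout.n_bins), np.nan)
        for s in range(pop.n_structures):
            if len(blist[s]) == 0:
                continue
            x = pop.coords[s]
            d = np.sqrt(((x[:, None, :] - blist[s][None, :, :]) ** 2).sum(-1)).min(axis=1)
            per[s] = _per_structure_region(pop, (d <= cut).astype(float)[None, :])[0]
        with np.errstate(invalid="ignore"):
            out[name] = np.nanmean(per, axis=0)
    return out


def classify_expression_classes(
    expr_class: pd.Series, saf: np.ndarray, gene_bin: pd.Series
) -> dict[str, list]:
    """Class I / class II genes from expression level and SAF quartiles.

    Class I: highly expressed genes in regions above the genome-wide SAF
    Q3; class II: highly expressed genes below SAF Q1.  Genes in the
    middle quartiles stay unclassified.
    """
    finite = saf[np.isfinite(saf)]
    q1, q3 = np.quantile(finite, [0.25, 0.75])
    class1, class2 = [], []
    for gene, cls in expr_class.items():
        if cls != "high":
            continue
        b = int(gene_bin[gene])
        if not np.isfinite(saf[b]):
            continue
        if saf[b] > q3:
            class1.append(gene)
        elif saf[b] < q1:
            class2.append(gene)
    return {"class_I": class1, "class_II": class2}


def spatial_enhancer_count(
    pop: StructurePopulation,
    tss_bins: np.ndarray,
    enhancer_bins: np.ndarray,
    radius: float = 350.0,
    ultra_long_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Spatial enhancer neighbourhood counts per TSS region.

    Counts enhancer-labelled loci whose bead centres lie within the
    radius of the TSS-containing bead, averaged over structures and
    alleles, stratified into all intrachromosomal, ultra-long-range
    intrachromosomal (> 1 Mb) and interchromosomal.
    """
    layout = pop.layout
    enh_beads = np.flatnonzero(np.isin(pop.bead_bin, enhancer_bins))
    rows = []
    ch = layout.bin_chrom
    mids = layout.bin_mids()
    for t in np.asarray(tss_bins):
        t_beads = np.flatnonzero(pop.bead_bin == t)
        intra = np.zeros(0)
        acc = {"intra": 0.0, "ultra": 0.0, "inter": 0.0}
        n_events = 0
        for s in range(pop.n_structures):
            x = pop.coords[s]
            for tb in t_beads:
                d = np.sqrt(((x[enh_beads] - x[tb]) ** 2).sum(-1))
                near = enh_beads[(d <= radius) & (enh_beads != tb)]
                nb = pop.bead_bin[near]
                same = ch[nb] == ch[t]
                acc["intra"] += int(same.sum())
                acc["inter"] += int((~same).sum())
                acc["ultra"] += int((same & (np.abs(mids[nb] - mids[t]) > ultra_long_bp)).sum())
                n_events += 1
        rows.append(
            {
                "bin": int(t),
                "intra": acc["intra"] / n_events if n_events else 0.0,
                "intra_gt1mb": acc["ultra"] / n_events if n_events else 0.0,
                "inter": acc["inter"] / n_events if n_events else 0.0,
            }
        )
    return pd.DataFrame(rows)


def feature_enrichment(
    features: pd.DataFrame,
    group_mask: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
    invert: tuple[str, ...] = ("RAD", "SpD", "NuD"),
) -> pd.Series:
    """log2 enrichment of structure features in a region group.

    Features are min-max normalized to [0, 1]; RAD/SpD/NuD are inverted
    (1 - x) so larger means closer/more interior.  The fold is
    log2(group mean / mean of `n_perm` random same-size groups).
    """
    rng = np.random.default_rng(seed)
    group_mask = np.asarray(group_mask, dtype=bool)
    k = int(group_mask.sum())
    if k == 0:
        raise ValueError("empty group")
    out = {}
    n = len(features)
    for name in features.columns:
        v = features[name].to_numpy(dtype=float)
        fin = np.isfinite(v)
        lo, hi = np.nanmin(v), np.nanmax(v)
        norm = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
        if name in invert:
            norm = 1.0 - norm
        gmean = norm[group_mask & fin].mean()
        perms = np.empty(n_perm)
        for p in range(n_perm):
            idx = rng.choice(n, size=k, replace=False)
            sel = norm[idx][fin[idx]]
            perms[p] = sel.mean() if sel.size else np.nan
        base = np.nanmean(perms)
        with np.errstate(divide="ignore"):
            out[name] = float(np.log2(gmean / base)) if base > 0 else np.nan
    return pd.Series(out)


def enhancer_density_features(
    layout,
    enhancers: pd.DataFrame,
    tss: pd.DataFrame,
    pop: StructurePopulation | None = None,
    radius: float = 350.0,
) -> pd.DataFrame:
    """Per-gene enhancer density ratios.

    E: active enhancers in the gene's bin-sized window; E/G: E over the
    number of TSSs in that window; the spatial variants divide the
    350-nm neighbourhood enhancer counts (inter, intra, intra < 2 Mb) by
    the same TSS count.  Windows without genes are flagged NaN.
    """
    n = layout.n_bins
    enh_per_bin = np.zeros(n, dtype=int)
    for row in enhancers.itertuples(index=False):
        mid = (row.start + row.end) // 2
        enh_per_bin[layout.bin_of(row.chrom, int(mid))] += 1
    tss_per_bin = np.zeros(n, dtype=int)
    gene_bin = {}
    for row in tss.itertuples(index=False):
        b = layout.bin_of(row.chrom, int(row.pos))
        tss_per_bin[b] += 1
        gene_bin[row.gene] = b
    spatial = None
    if pop is not None:
        enh_bins = np.flatnonzero(enh_per_bin > 0)
        tss_bins = np.unique(list(gene_bin.values()))
        sc = spatial_enhancer_count(pop, tss_bins, enh_bins, radius=radius, ultra_long_bp=2_000_000)
        spatial = sc.set_index("bin")
    rows = []
    for gene, b in gene_bin.items():
        g = tss_per_bin[b]
        e = enh_per_bin[b]
        row = {"gene": gene, "bin": b, "E": e, "E_per_G": e / g if g else np.nan}
        if spatial is not None:
            s = spatial.loc[b]
            row["En_inter_per_G"] = s["inter"] / g if g else np.nan
            row["En_intra_per_G"] = s["intra"] / g if g else np.nan
            # ultra-long here is >2 Mb, so "< 2 Mb" is the complement
            row["En_intra_lt2mb_per_G"] = (s["intra"] - s["intra_gt1mb"]) / g if g else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
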