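"""Chromatin-loop integration, quantification and annotation.

Covers the union merge of loop calls from multiple platforms and
resolutions, capture-interaction overlap, aggregate peak analysis (APA),
anchor chromatin-state featurization with consensus Leiden clustering,
shuffle-null enrichment of states and transcription factors, per-loop
contact strength, enhancer-promoter linking, expression breadth /
quartiles, and TSS-centred contact-decay profiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .contact import ContactMatrix, expected_by_distance

__all__ = [
    "merge_loops",
    "capture_overlap",
    "apa",
    "anchor_state_features",
    "cluster_loops",
    "loop_state_pair_enrichment",
    "anchor_tf_enrichment",
    "mean_loop_strength",
    "link_genes_to_enhancers",
    "classify_ep_sharing",
    "expression_breadth",
    "expression_quartiles",
    "tss_contact_decay",
]

LOOP_COLS = ["chrom", "start1", "end1", "start2", "end2"]


def _midpoints(loops: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    i = ((loops["start1"] + loops["end1"]) / 2).to_numpy(float)
    j = ((loops["start2"] + loops["end2"]) / 2).to_numpy(float)
    return i, j


def merge_loops(loop_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Union of loop calls across platforms/resolutions.

    Two loops (i, j) and (i', j') overlap iff |i-i'| < min(0.2|i-j|, 15 kb)
    and |j-j'| < min(0.2|i-j|, 15 kb), the span |i-j| being that of the
    finer-resolution loop of the pair.  Overlap clusters are closed
    transitively; each cluster is represented by its finest-resolution
    member (ties broken by deterministic sort order).

    Input frames need LOOP_COLS plus `resolution` (bp; smaller = finer)
    and optionally `platform`.  Malformed records (i >= j) are dropped.
    """
    frames = []
    for k, df in enumerate(loop_sets):
        d = df.copy()
        if "platform" not in d:
            d["platform"] = f"set{k}"
        if "resolution" not in d:
            raise ValueError("each loop set needs a `resolution` column")
        frames.append(d)
    allloops = pd.concat(frames, ignore_index=True)
    i, j = _midpoints(allloops)
    bad = i >= j
    if bad.any():
        allloops = allloops[~bad].reset_index(drop=True)
        i, j = i[~bad], j[~bad]
    allloops = allloops.sort_values(
        ["resolution", "chrom", "start1", "start2"], kind="stable"
    ).reset_index(drop=True)
    i, j = _midpoints(allloops)
    n = len(allloops)
    parent = np.arange(n)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    chroms = allloops["chrom"].to_numpy()
    res = allloops["resolution"].to_numpy(float)
    span = j - i
    for a in range(n):
        m = (chroms == chroms[a]) & (np.arange(n) > a)
        if not m.any():
            continue
        idx = np.flatnonzero(m)
        # finer loop of each pair supplies the span for the threshold
        finer_span = np.where(res[idx] < res[a], span[idx], span[a])
        thr = np.minimum(0.2 * finer_span, 15_000.0)
        hit = (np.abs(i[idx] - i[a]) < thr) & (np.abs(j[idx] - j[a]) < thr)
        for b in idx[hit]:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    roots = np.array([find(x) for x in range(n)])
    # representative per cluster: first by sort order = finest resolution
    reps = np.sort(pd.Series(np.arange(n)).groupby(roots).min().to_numpy())
    out = allloops.iloc[reps].reset_index(drop=True)
    out["cluster_size"] = [int((roots == roots[r]).sum()) for r in reps]
    return out


def capture_overlap(
    query: pd.DataFrame, reference: pd.DataFrame
) -> np.ndarray:
    """Does a capture interaction coincide with a called loop.

    Query (i, j) overlaps iff some reference (i', j') on the same
    chromosome has Euclidean distance sqrt((i-i')^2 + (j-j')^2) strictly
    below min(0.3|i-j|, 80 kb).
    """
    qi, qj = _midpoints(query)
    ri, rj = _midpoints(reference)
    qch = query["chrom"].to_numpy()
    rch = reference["chrom"].to_numpy()
    out = np.zeros(len(query), dtype=bool)
    for k in range(len(query)):
        m = rch == qch[k]
        if not m.any():
            continue
        d = np.sqrt((ri[m] - qi[k]) ** 2 + (rj[m] - qj[k]) ** 2)
        thr = min(0.3 * (qj[k] - qi[k]), 80_000.0)
        out[k] = bool((d < thr).any())
    return out


def apa(
    cm: ContactMatrix,
    loops: pd.DataFrame,
    half_size: int = 10,
    trim_percentiles: tuple[float, float] = (1, 99),
    balanced: bool = False,
) -> dict:
    """Aggregate peak analysis: mean O/E submatrix centred on loops.

    Extracts (2*half_size+1)-square windows of O/E (each value divided by
    the mean contact frequency at its genomic distance), discards windows
    whose mean lies above the 99th or below the 1st percentile of window
    means, and averages the rest.  The APA score is the centre pixel.
    Loops closer than half_size+1 bins to the diagonal or to the matrix
    edges are skipped and counted.
    """
    exp = expected_by_distance(cm, balanced=balanced)
    vals = cm.values(balanced=balanced)
    hw = half_size
    stacks = []
    skipped = 0
    layout = cm.layout
    for row in loops.itertuples(index=False):
        c = layout.chroms.index(row.chrom)
        sl = layout.chrom_slice(c)
        bi = sl.start + int((row.start1 + row.end1) // 2) // layout.bin_size
        bj = sl.start + int((row.start2 + row.end2) // 2) // layout.bin_size
        li, lj = bi - sl.start, bj - sl.start
        m = sl.stop - sl.start
        if (
            li - hw < 0
            or lj + hw + 1 > m
            or (lj - hw) - (li + hw) < 1  # window touches/crosses the diagonal
        ):
            skipped += 1
            continue
        sub = vals[bi - hw : bi + hw + 1, bj - hw : bj + hw + 1]
        rows = np.arange(li - hw, li + hw + 1)[:, None]
        cols = np.arange(lj - hw, lj + hw + 1)[None, :]
        e = exp[row.chrom][np.abs(cols - rows)]
        with np.errstate(divide="ignore", invalid="ignore"):
            stacks.append(np.where(e > 0, sub / e, np.nan))
    if not stacks:
        raise ValueError("no usable loops for APA")
    arr = np.stack(stacks)
    means = np.nanmean(arr, axis=(1, 2))
    lo, hi = np.percentile(means, trim_percentiles)
    keep = (means >= lo) & (means <= hi)
    pileup = np.nanmean(arr[keep], axis=0)
    return {
        "pileup": pileup,
        "score": float(pileup[hw, hw]),
        "n_loops": int(keep.sum()),
        "n_skipped": skipped,
    }


def _state_fractions(
    chrom: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
    segments: pd.DataFrame,
    states: list[str],
) -> np.ndarray:
    """bp-fraction of each state within each interval."""
    out = np.zeros((len(chrom), len(states)))
    seg_by_chrom = {
        c: g.sort_values("start") for c, g in segments.groupby("chrom", sort=False)
    }
    sidx = {s: k for k, s in enumerate(states)}
    for n in range(len(chrom)):
        g = seg_by_chrom.get(chrom[n])
        if g is None:
            continue
        ss = g["start"].to_numpy()
        se = g["end"].to_numpy()
        lab = g["state"].to_numpy()
        ov = np.minimum(se, end[n]) - np.maximum(ss, start[n])
        hit = ov > 0
        width = end[n] - start[n]
        for s, o in zip(lab[hit], ov[hit]):
            if s in sidx:
                out[n, sidx[s]] += o / width
    return out


def anchor_state_features(
    loops: pd.DataFrame, segments: pd.DataFrame, states: list[str] | None = None
) -> dict:
    """Per-loop 2k anchor chromatin-state feature matrix.

    For each anchor, the bp-proportion of each of the k states inside the
    anchor interval; columns are z-scored over loops; each row's anchors
    are swapped if needed so the maximum standardized value lies in the
    first k columns.  Returns the matrix, state order and swap flags.
    """
    if states is None:
        states = sorted(segments["state"].unique())
    k = len(states)
    ch = loops["chrom"].to_numpy()
    f1 = _state_fractions(ch, loops["start1"].to_numpy(), loops["end1"].to_numpy(), segments, states)
    f2 = _state_fractions(ch, loops["start2"].to_numpy(), loops["end2"].to_numpy(), segments, states)
    raw = np.hstack([f1, f2])
    # standardization stats pooled over both anchors per state, so the
    # featurization is invariant to the input order of the two anchors
    stacked = np.vstack([f1, f2])
    mu1 = stacked.mean(axis=0)
    sd1 = stacked.std(axis=0)
    sd1[sd1 == 0] = 1.0
    mu = np.concatenate([mu1, mu1])
    sd = np.concatenate([sd1, sd1])
    z = (raw - mu) / sd
    max1 = z[:, :k].max(axis=1)
    max2 = z[:, k:].max(axis=1)
    swap = max2 > max1
    # ties on the maximum: canonicalize by lexicographic half comparison
    tie = max2 == max1
    for r in np.flatnonzero(tie):
        a, b = tuple(z[r, :k]), tuple(z[r, k:])
        if b > a:
            swap[r] = True
    zs = z.copy()
    zs[swap] = np.hstack([z[swap, k:], z[swap, :k]])
    return {"matrix": zs, "states": states, "swapped": swap, "raw": raw,
            "mean": mu, "sd": sd}


def cluster_loops(
    features: np.ndarray,
    k_grid: tuple[int, ...] | None = None,
    resolution: float = 0.5,
    seed: int = 0,
    n_pcs: int | None = None,
    consensus_threshold: float = 0.5,
) -> np.ndarray:
    """Consensus Leiden clustering of the anchor feature matrix.

    PCA is applied first; a k-NN graph is built for every k in the grid
    (default 50..2000 step 50, truncated below the sample count) and
    Leiden (resolution 0.5) run on each.  The co-assignment matrix is
    averaged over graphs; the consensus partition is one final Leiden
    run on the graph of pairs co-assigned in at least
    `consensus_threshold` of the runs, weighted by co-assignment.
    """
    import igraph as ig
    import leidenalg
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    x = np.asarray(features, dtype=float)
    n = x.shape[0]
    if k_grid is None:
        k_grid = tuple(range(50, 2001, 50))
    k_grid = tuple(k for k in k_grid if k < n)
    if not k_grid:
        raise ValueError("all k in the grid exceed the number of loops")
    pca = PCA(n_components=n_pcs or min(x.shape), random_state=seed)
    xp = pca.fit_transform(x)
    nn = NearestNeighbors(n_neighbors=max(k_grid) + 1).fit(xp)
    _, knn_all = nn.kneighbors(xp)

    co = np.zeros((n, n), dtype=np.float32)
    for k in k_grid:
        src = np.repeat(np.arange(n), k)
        dst = knn_all[:, 1 : k + 1].ravel()
        g = ig.Graph(n=n, edges=list(zip(src.tolist(), dst.tolist())), directed=False)
        g.simplify()
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=seed,
        )
        memb = np.asarray(part.membership)
        onehot = np.zeros((n, memb.max() + 1), dtype=np.float32)
        onehot[np.arange(n), memb] = 1.0
        co += onehot @ onehot.T
    co /= len(k_grid)

    ii, jj = np.nonzero(np.triu(co >= consensus_threshold, k=1))
    g = ig.Graph(n=n, edges=list(zip(ii.tolist(), jj.tolist())), directed=False)
    g.es["weight"] = co[ii, jj].astype(float).tolist()
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership)


def _shuffle_intervals(
    rng: np.random.Generator,
    chrom: np.ndarray,
    width: np.ndarray,
    chrom_lengths: dict[str, int],
    gaps: pd.DataFrame | None,
    span: np.ndarray | None = None,
    max_tries: int = 100,
) -> np.ndarray:
    """Random start positions keeping chromosome and width (and span for
    loops), avoiding gap overlap by rejection sampling."""
    gap_arrays = {}
    if gaps is not None and len(gaps):
        for c, g in gaps.groupby("chrom", sort=False):
            gs = g.sort_values("start")
            gap_arrays[c] = (gs["start"].to_numpy(), gs["end"].to_numpy())
    total_span = width if span is None else span
    starts = np.zeros(len(chrom), dtype=np.int64)
    for c in np.unique(chrom):
        m = chrom == c
        hi = chrom_lengths[c] - total_span[m]
        if (hi <= 0).any():
            raise ValueError("interval longer than chromosome")
        s = rng.integers(0, hi)
        if c in gap_arrays:
            cs, ce = gap_arrays[c]
            for _ in range(max_tries):
                bad = _overlaps_sorted(s, s + total_span[m], cs, ce)
                if not bad.any():
                    break
                s = np.where(bad, rng.integers(0, hi), s)
        starts[m] = s
    return starts


def _overlaps_sorted(starts, ends, cat_starts, cat_ends):
    idx = np.searchsorted(cat_ends, starts, side="right")
    ok = idx < len(cat_starts)
    hit = np.zeros(np.shape(starts), dtype=bool)
    hit[ok] = cat_starts[idx[ok]] < np.asarray(ends)[ok]
    return hit


def _segment_arrays(segments: pd.DataFrame) -> dict:
    out = {}
    for c, g in segments.groupby("chrom", sort=False):
        gs = g.sort_values("start")
        out[c] = (gs["start"].to_numpy(np.int64), gs["end"].to_numpy(np.int64),
                  gs["state"].to_numpy())
    return out


def _anchor_states(
    chrom: np.ndarray, start: np.ndarray, end: np.ndarray, segments
) -> list[set]:
    """Set of states overlapped (>= 1 bp) by each interval.

    Assumes within-chromosome segments are sorted and non-overlapping
    (a segmentation); `segments` may be a DataFrame or the precomputed
    per-chromosome arrays from :func:`_segment_arrays`.
    """
    arrays = segments if isinstance(segments, dict) else _segment_arrays(segments)
    out = []
    for n in range(len(chrom)):
        arr = arrays.get(chrom[n])
        if arr is None:
            out.append(set())
            continue
        ss, se, lab = arr
        lo = np.searchsorted(se, start[n], side="right")
        hi = np.searchsorted(ss, end[n], side="left")
        out.append(set(lab[lo:hi]))
    return out


def loop_state_pair_enrichment(
    loops: pd.DataFrame,
    segments: pd.DataFrame,
    chrom_lengths: dict[str, int],
    gaps: pd.DataFrame | None = None,
    n_controls: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Fold enrichment of unordered anchor chromatin-state pairs.

    A loop counts for the pair (s, t) if one anchor overlaps state s and
    the other overlaps state t.  Controls preserve each loop's anchor
    distance, anchor widths and chromosome, avoid gaps, and are drawn
    `n_controls` times; fold = observed / mean(control).  A zero control
    mean with nonzero observed is reported as +inf with a flag.
    """
    if n_controls < 1:
        raise ValueError("n_controls must be >= 1")
    rng = np.random.default_rng(seed)
    states = sorted(segments["state"].unique())
    seg_arrays = _segment_arrays(segments)

    def pair_counts(ch, s1, e1, s2, e2) -> dict:
        a1 = _anchor_states(ch, s1, e1, seg_arrays)
        a2 = _anchor_states(ch, s2, e2, seg_arrays)
        cnt: dict[tuple, int] = {}
        for x, y in zip(a1, a2):
            pairs = {tuple(sorted((s, t))) for s in x for t in y}
            for p in pairs:
                cnt[p] = cnt.get(p, 0) + 1
        return cnt

    ch = loops["chrom"].to_numpy()
    s1 = loops["start1"].to_numpy(np.int64)
    e1 = loops["end1"].to_numpy(np.int64)
    s2 = loops["start2"].to_numpy(np.int64)
    e2 = loops["end2"].to_numpy(np.int64)
    w1, w2 = e1 - s1, e2 - s2
    offset = s2 - s1
    span = e2 - s1
    obs = pair_counts(ch, s1, e1, s2, e2)

    ctrl_sums: dict[tuple, float] = {}
    for _ in range(n_controls):
        rs = _shuffle_intervals(rng, ch, w1, chrom_lengths, gaps, span=span)
        c = pair_counts(ch, rs, rs + w1, rs + offset, rs + offset + w2)
        for p, v in c.items():
            ctrl_sums[p] = ctrl_sums.get(p, 0.0) + v
    rows = []
    for si in range(len(states)):
        for ti in range(si, len(states)):
            p = (states[si], states[ti])
            o = obs.get(p, 0)
            cmean = ctrl_sums.get(p, 0.0) / n_controls
            fold = o / cmean if cmean > 0 else (np.inf if o > 0 else np.nan)
            rows.append({"state1": p[0], "state2": p[1], "observed": o,
                         "control_mean": cmean, "fold": fold,
                         "degenerate": cmean == 0})
    return pd.DataFrame(rows)


def anchor_tf_enrichment(
    anchors: pd.DataFrame,
    peak_sets: dict[str, pd.DataFrame],
    chrom_lengths: dict[str, int],
    gaps: pd.DataFrame | None = None,
    n_controls: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Fold enrichment of TF peak presence at loop anchors.

    An anchor counts once per factor if it overlaps >= 1 peak; controls
    preserve the anchor size distribution and per-chromosome counts and
    avoid gaps.
    """
    if n_controls < 1:
        raise ValueError("n_controls must be >= 1")
    rng = np.random.default_rng(seed)
    ch = anchors["chrom"].to_numpy()
    st = anchors["start"].to_numpy(np.int64)
    en = anchors["end"].to_numpy(np.int64)
    width = en - st

    peak_arrays = {
        tf: {
            c: (g.sort_values("start")["start"].to_numpy(np.int64),
                g.sort_values("start")["end"].to_numpy(np.int64))
            for c, g in df.groupby("chrom", sort=False)
        }
        for tf, df in peak_sets.items()
    }

    def count_with_peaks(chrom, starts, ends, tf) -> int:
        total = 0
        for c in np.unique(chrom):
            if c not in peak_arrays[tf]:
                continue
            cs, ce = peak_arrays[tf][c]
            m = chrom == c
            total += int(_overlaps_sorted(starts[m], ends[m], cs, ce).sum())
        return total

    ctrl_counts = {tf: 0.0 for tf in peak_sets}
    for _ in range(n_controls):
        rs = _shuffle_intervals(rng, ch, width, chrom_lengths, gaps)
        for tf in peak_sets:
            ctrl_counts[tf] += count_with_peaks(ch, rs, rs + width, tf)
    rows = []
    for tf in peak_sets:
        o = count_with_peaks(ch, st, en, tf)
        cmean = ctrl_counts[tf] / n_controls
        fold = o / cmean if cmean > 0 else (np.inf if o > 0 else 0.0)
        rows.append({"tf": tf, "observed": o, "control_mean": cmean, "fold": fold})
    return pd.DataFrame(rows)


def mean_loop_strength(
    loops: pd.DataFrame,
    cm: ContactMatrix,
    mode: str = "raw_oe",
    npmi: np.ndarray | None = None,
) -> float:
    """Mean per-loop pixel strength.

    mode "balanced_oe" / "raw_oe": distance-normalized contact frequency
    at each loop pixel; "npmi": the NPMI matrix value at the pixel.
    """
    if not len(loops):
        raise ValueError("empty loop set")
    layout = cm.layout
    if mode == "npmi":
        if npmi is None:
            raise ValueError("npmi matrix required for mode='npmi'")
        src = npmi
        exp = None
    else:
        balanced = mode == "balanced_oe"
        src = cm.values(balanced=balanced)
        exp = expected_by_distance(cm, balanced=balanced)
    vals = []
    for row in loops.itertuples(index=False):
        c = layout.chroms.index(row.chrom)
        sl = layout.chrom_slice(c)
        bi = sl.start + int((row.start1 + row.end1) // 2) // layout.bin_size
        bj = sl.start + int((row.start2 + row.end2) // 2) // layout.bin_size
        v = src[bi, bj]
        if exp is not None:
            e = exp[row.chrom][abs(bj - bi)]
            v = v / e if e > 0 else np.nan
        vals.append(v)
    return float(np.nanmean(vals))


def link_genes_to_enhancers(
    loops: pd.DataFrame,
    tss: pd.DataFrame,
    enhancers: pd.DataFrame,
    tss_window: int | None = None,
) -> pd.DataFrame:
    """Gene-enhancer pairs through loop anchors.

    A pair exists iff one anchor overlaps the gene's TSS (extended by
    `tss_window` bp each side; default 0, i.e. plain anchor overlap) and
    the other anchor overlaps the enhancer element.  Returns one row per
    distinct (gene, enhancer) pair with the E-P distance
    |TSS - enhancer midpoint|.

    `tss` needs columns chrom, pos, gene; `enhancers` chrom, start, end
    and optionally `enhancer_id` (default: coordinate string).
    """
    w = tss_window or 0
    enh = enhancers.copy()
    if "enhancer_id" not in enh:
        enh["enhancer_id"] = [
            f"{r.chrom}:{r.start}-{r.end}" for r in enh.itertuples(index=False)
        ]
    pairs = set()
    rows = []
    for lrow in loops.itertuples(index=False):
        for a_s, a_e, b_s, b_e in (
            (lrow.start1, lrow.end1, lrow.start2, lrow.end2),
            (lrow.start2, lrow.end2, lrow.start1, lrow.end1),
        ):
            t = tss[
                (tss["chrom"] == lrow.chrom)
                & (tss["pos"] >= a_s - w)
                & (tss["pos"] < a_e + w)
            ]
            if not len(t):
                continue
            e = enh[
                (enh["chrom"] == lrow.chrom)
                & (enh["end"] > b_s)
                & (enh["start"] < b_e)
            ]
            for trow in t.itertuples(index=False):
                for erow in e.itertuples(index=False):
                    key = (trow.gene, erow.enhancer_id)
                    if key in pairs:
                        continue
                    pairs.add(key)
                    mid = (erow.start + erow.end) // 2
                    rows.append({"gene": trow.gene, "enhancer_id": erow.enhancer_id,
                                 "distance": abs(int(trow.pos) - int(mid))})
    return pd.DataFrame(rows, columns=["gene", "enhancer_id", "distance"])


def enhancer_counts_per_gene(pairs: pd.DataFrame, genes: list[str]) -> pd.Series:
    counts = pairs.groupby("gene")["enhancer_id"].nunique()
    return counts.reindex(genes, fill_value=0)


def classify_ep_sharing(pairs_ct1: pd.DataFrame, pairs_ct2: pd.DataFrame) -> dict:
    """Shared vs cell-type-specific enhancer-promoter pairs.

    Pair identity is (gene, enhancer element); a pair is shared iff it is
    present in both cell types.
    """
    a = set(zip(pairs_ct1["gene"], pairs_ct1["enhancer_id"]))
    b = set(zip(pairs_ct2["gene"], pairs_ct2["enhancer_id"]))
    union = a | b
    shared = a & b
    n = len(union)
    return {
        "n_pairs": n,
        "shared_fraction": len(shared) / n if n else np.nan,
        "specific_fraction": 1 - len(shared) / n if n else np.nan,
    }


def expression_breadth(
    tpm: pd.DataFrame, expressed_threshold: float = 3.0
) -> pd.Series:
    """Expression breadth: samples where quantile-normalized log2 TPM > 3.

    log2(TPM+1) per sample, then quantile normalization across samples
    (rank-mean substitution; ties get the mean of their rank positions).
    """
    if tpm.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    logt = np.log2(tpm + 1)
    ranks = logt.rank(method="average")
    means = np.sort(logt.to_numpy(), axis=0).mean(axis=1)
    # map average rank r to interpolated mean of sorted rows
    normed = pd.DataFrame(
        np.interp(ranks.to_numpy(), np.arange(1, len(tpm) + 1), means),
        index=tpm.index,
        columns=tpm.columns,
    )
    return (normed > expressed_threshold).sum(axis=1)


def expression_quartiles(rpkm: pd.Series) -> pd.Series:
    """low / mid / high / silent classes from non-zero RPKM quartiles.

    Quartiles Q1/Q3 are computed among genes with non-zero RPKM; genes
    with 0 < RPKM < Q1 are "low", RPKM > Q3 "high", zero "silent",
    everything else "mid".
    """
    nz = rpkm[rpkm > 0]
    if not len(nz):
        return pd.Series("silent", index=rpkm.index)
    q1, q3 = nz.quantile(0.25), nz.quantile(0.75)
    cls = pd.Series("mid", index=rpkm.index)
    cls[rpkm == 0] = "silent"
    cls[(rpkm > 0) & (rpkm < q1)] = "low"
    cls[rpkm > q3] = "high"
    return cls


def tss_contact_decay(
    cm: ContactMatrix,
    tss: pd.DataFrame,
    half_window_bp: int = 2_000_000,
    balanced: bool = False,
) -> dict:
    """Mean contact-count profile around TSS bins.

    For every TSS, the contact counts between its bin and all bins within
    +-half_window are extracted, aligned at the TSS and averaged.
    TSSs with a truncated window (matrix edge) are skipped and counted.
    """
    layout = cm.layout
    vals = cm.values(balanced=balanced)
    hw = half_window_bp // layout.bin_size
    stack = []
    truncated = 0
    for row in tss.itertuples(index=False):
        b = layout.bin_of(row.chrom, int(row.pos))
        sl = layout.chrom_slice(row.chrom)
        if b - hw < sl.start or b + hw + 1 > sl.stop:
            truncated += 1
            continue
        stack.append(vals[b, b - hw : b + hw + 1])
    if not stack:
        raise ValueError("no TSS with a complete window")
    return {
        "profile": np.nanmean(np.vstack(stack), axis=0),
        "offsets_bp": (np.arange(-hw, hw + 1) * layout.bin_size),
        "n": len(stack),
        "n_truncated": truncated,
    }
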