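"""Insulation, boundaries, domain/interval calculus and the IZ test.

Implements diamond insulation scores with local-minimum boundary calling,
boundary-centred aggregation, dot/dotless domain classification against a
loop list, Jaccard co-registration between interval annotations, rescaled
(stretched) pileups, and the compartment-matched resampling test for
replication initiation zones (IZs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import zoom as nd_zoom

from .contact import ContactMatrix

__all__ = [
    "InsulationTrack",
    "insulation_score",
    "call_boundaries",
    "aggregate_at_boundaries",
    "classify_dot_domains",
    "coregistration",
    "rescaled_pileup",
    "iz_resampling_test",
]


@dataclass
class InsulationTrack:
    raw: np.ndarray                 # diamond means, NaN where undefined
    log2_insulation: np.ndarray     # log2(raw / chromosome mean)
    window_bins: int


def insulation_score(
    cm: ContactMatrix,
    window_bins: int,
    ignore_diags: int = 2,
    balanced: bool = False,
) -> InsulationTrack:
    """Diamond insulation score per bin.

    For bin i the diamond is the (window x window) block of pairs
    (i-w..i-1) x (i..i+w-1) within the chromosome -- the contacts
    crossing the bin's left edge, so a domain boundary at bin b scores
    its minimum at b.  Diagonals closer than `ignore_diags` are
    excluded.  The reported track is log2 of the diamond mean over its
    chromosome-wide mean, so a uniform map scores exactly zero and
    scaling the map has no effect.
    """
    if window_bins < 2:
        raise ValueError("window must span at least 2 bins")
    vals = cm.values(balanced=balanced)
    n = cm.layout.n_bins
    raw = np.full(n, np.nan)
    w = window_bins
    for chrom in cm.layout.chroms:
        sl = cm.layout.chrom_slice(chrom)
        sub = vals[sl, sl]
        m = sub.shape[0]
        for i in range(m):
            r0, r1 = i - w, i
            c0, c1 = i, i + w
            if r0 < 0 or c1 > m:
                continue
            block = sub[r0:r1, c0:c1]
            rows = np.arange(r0, r1)[:, None]
            cols = np.arange(c0, c1)[None, :]
            keep = (cols - rows) >= ignore_diags
            v = block[keep & np.isfinite(block)]
            if v.size:
                raw[sl.start + i] = v.mean()
    log2ins = np.full(n, np.nan)
    for chrom in cm.layout.chroms:
        sl = cm.layout.chrom_slice(chrom)
        r = raw[sl]
        mean = np.nanmean(r) if np.isfinite(r).any() else np.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            log2ins[sl] = np.log2(r / mean)
    return InsulationTrack(raw=raw, log2_insulation=log2ins, window_bins=w)


def call_boundaries(
    ins: InsulationTrack,
    layout,
    min_strength: float = 0.1,
    other_tracks: list[np.ndarray] | None = None,
):
    """Boundaries = local minima of the insulation track.

    Strength is the topographic prominence of the minimum in log2 units;
    minima with prominence < `min_strength` are discarded.  The
    strong/weak split uses the mean insulation score across all supplied
    tracks (this track alone when none are given): strong boundaries sit
    below that mean.
    """
    track = ins.log2_insulation
    rows = []
    for c in range(layout.n_chroms):
        sl = layout.chrom_slice(c)
        t = track[sl]
        filled = np.where(np.isfinite(t), t, np.nanmax(t) if np.isfinite(t).any() else 0.0)
        peaks, props = signal.find_peaks(-filled, prominence=min_strength)
        for p, prom in zip(peaks, props["prominences"]):
            if not np.isfinite(t[p]):
                continue
            rows.append({"bin": sl.start + p, "chrom": layout.chroms[c],
                         "score": float(t[p]), "strength": float(prom)})
    df = pd.DataFrame(rows, columns=["bin", "chrom", "score", "strength"])
    pool = [track] + (other_tracks or [])
    mean_score = float(np.nanmean(np.concatenate([np.asarray(t, float) for t in pool])))
    if len(df):
        df["strong"] = df["score"] < mean_score
    else:
        df["strong"] = pd.Series(dtype=bool)
    return df


def aggregate_at_boundaries(
    track: np.ndarray, boundary_bins: np.ndarray, flank_bins: int, layout=None
) -> dict:
    """Mean profile of a per-bin track in windows centred on boundaries.

    Boundaries whose window would cross the track ends (or chromosome
    ends, if a layout is given) are skipped; the number of contributors
    is reported.
    """
    track = np.asarray(track, dtype=float)
    stack = []
    for b in np.asarray(boundary_bins, dtype=int):
        lo, hi = b - flank_bins, b + flank_bins + 1
        if lo < 0 or hi > len(track):
            continue
        if layout is not None:
            c = layout.bin_chrom[b]
            sl = layout.chrom_slice(int(c))
            if lo < sl.start or hi > sl.stop:
                continue
        stack.append(track[lo:hi])
    if not stack:
        return {"profile": np.zeros(2 * flank_bins + 1) * np.nan, "n": 0}
    arr = np.vstack(stack)
    return {"profile": np.nanmean(arr, axis=0), "n": arr.shape[0]}


def classify_dot_domains(domains: pd.DataFrame, loops: pd.DataFrame) -> np.ndarray:
    """Dot vs dotless domains by loop presence at the domain apex.

    A domain [s, e) is a dot domain iff some loop's anchor midpoints
    (m1, m2) satisfy |m1 - s| <= 0.2(e-s) and |m2 - e| <= 0.2(e-s) on the
    same chromosome.  Returns a boolean array (True = dot).
    """
    out = np.zeros(len(domains), dtype=bool)
    if not len(loops):
        return out
    lm1 = ((loops["start1"] + loops["end1"]) / 2).to_numpy()
    lm2 = ((loops["start2"] + loops["end2"]) / 2).to_numpy()
    lch = loops["chrom"].to_numpy()
    for k, row in enumerate(domains.itertuples(index=False)):
        size = row.end - row.start
        tol = 0.2 * size
        sel = (
            (lch == row.chrom)
            & (np.abs(lm1 - row.start) <= tol)
            & (np.abs(lm2 - row.end) <= tol)
        )
        out[k] = bool(sel.any())
    return out


def _jaccard(a0, a1, b0, b1) -> float:
    inter = max(0, min(a1, b1) - max(a0, b0))
    union = (a1 - a0) + (b1 - b0) - inter
    return inter / union if union > 0 else 0.0


def coregistration(
    a: pd.DataFrame, b: pd.DataFrame, jaccard: float = 0.70
) -> pd.DataFrame:
    """Relation of every a-interval to a second annotation.

    Labels: "co-register" if the best-overlap Jaccard index exceeds the
    threshold; otherwise "within" if fully contained in some b-interval,
    "encompass" if it fully contains one, else "other".  Containment
    includes equal endpoints.
    """
    labels = []
    best_j = []
    for row in a.itertuples(index=False):
        bs = b[b["chrom"] == row.chrom]
        jbest = 0.0
        within = encompass = False
        for o in bs.itertuples(index=False):
            if min(row.end, o.end) <= max(row.start, o.start):
                continue
            jbest = max(jbest, _jaccard(row.start, row.end, o.start, o.end))
            if o.start <= row.start and row.end <= o.end:
                within = True
            if row.start <= o.start and o.end <= row.end:
                encompass = True
        if jbest > jaccard:
            labels.append("co-register")
        elif within:
            labels.append("within")
        elif encompass:
            labels.append("encompass")
        else:
            labels.append("other")
        best_j.append(jbest)
    out = a.copy()
    out["relation"] = labels
    out["best_jaccard"] = best_j
    return out


def rescaled_pileup(
    source: np.ndarray,
    intervals: pd.DataFrame,
    layout,
    L: int = 50,
    flank_frac: float = 0.6,
    is_matrix: bool | None = None,
    reducer: str = "mean",
) -> np.ndarray:
    """Stacked average of interval windows stretched to a common length.

    Each interval is extended by `flank_frac` of its size on both sides
    and resampled (linear interpolation) to L bins -- L x L pixels for a
    matrix source, which is O/E-normalized by the caller.  `reducer` is
    "mean" or "median" per the signal type.
    """
    if L < 10:
        raise ValueError("L must be >= 10")
    source = np.asarray(source, dtype=float)
    if is_matrix is None:
        is_matrix = source.ndim == 2
    stacks = []
    for row in intervals.itertuples(index=False):
        c = layout.chroms.index(row.chrom)
        sl = layout.chrom_slice(c)
        b0 = sl.start + row.start // layout.bin_size
        b1 = sl.start + int(np.ceil(row.end / layout.bin_size))
        size = b1 - b0
        f = int(round(flank_frac * size))
        lo, hi = b0 - f, b1 + f
        if lo < sl.start or hi > sl.stop or size < 1:
            continue
        if is_matrix:
            win = source[lo:hi, lo:hi]
            if win.shape[0] < 2:
                continue
            z = L / win.shape[0]
            stacks.append(nd_zoom(np.nan_to_num(win), z, order=1, grid_mode=True, mode="nearest")[:L, :L])
        else:
            win = source[lo:hi]
            xp = np.linspace(0, 1, len(win))
            xq = np.linspace(0, 1, L)
            stacks.append(np.interp(xq, xp, np.nan_to_num(win)))
    if not stacks:
        raise ValueError("no usable intervals for pileup")
    arr = np.stack(stacks)
    return np.median(arr, axis=0) if reducer == "median" else arr.mean(axis=0)


def _intersects_any(starts, ends, cat_starts, cat_ends) -> np.ndarray:
    """Vectorized: does [start, end) overlap any sorted category interval."""
    idx = np.searchsorted(cat_ends, starts, side="right")
    ok = idx < len(cat_starts)
    hit = np.zeros(len(starts), dtype=bool)
    hit[ok] = cat_starts[idx[ok]] < ends[ok]
    return hit


def iz_resampling_test(
    izs: pd.DataFrame,
    target_sets: dict[str, pd.DataFrame],
    compartments: pd.DataFrame,
    n_resamples: int = 10_000,
    seed: int = 0,
) -> dict[str, dict]:
    """Compartment-matched resampling test for IZ/boundary intersection.

    The observed statistic per category is the proportion of IZs
    intersecting that category's intervals.  The null draws interval
    sets matched in number, size (resampled with replacement from the
    observed sizes) and A/B compartment composition, placed uniformly in
    the compartment-labelled mappable space.  One-tailed empirical
    p = (1 + #{null >= observed}) / (1 + n_resamples).

    `target_sets` must partition: overlapping categories are an error.
    `compartments` needs columns chrom, start, end, label (A/B); IZ
    compartment membership is taken at the IZ midpoint.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    # categories must not overlap each other
    allcat = pd.concat(
        [df.assign(_cat=name) for name, df in target_sets.items()], ignore_index=True
    ).sort_values(["chrom", "start"], kind="stable")
    for chrom, g in allcat.groupby("chrom", sort=False):
        e = g["end"].to_numpy()
        s = g["start"].to_numpy()
        if (s[1:] < e[:-1]).any():
            raise ValueError("target categories must partition (found overlap)")
    rng = np.random.default_rng(seed)
    # integer chromosome codes throughout (object comparisons are slow at
    # resampling scale)
    chrom_names = list(
        dict.fromkeys(
            list(compartments["chrom"]) + list(izs["chrom"])
            + [c for df in target_sets.values() for c in df["chrom"]]
        )
    )
    code = {c: k for k, c in enumerate(chrom_names)}

    # flatten compartment space per label into concatenated coordinate runs
    comp_space: dict[str, dict] = {}
    for label, g in compartments.groupby("label", sort=False):
        lens = (g["end"] - g["start"]).to_numpy(dtype=np.int64)
        comp_space[label] = {
            "chrom": g["chrom"].map(code).to_numpy(np.int64),
            "start": g["start"].to_numpy(np.int64),
            "len": lens,
            "cum": np.concatenate([[0], np.cumsum(lens)]),
        }

    # per-chromosome sorted category interval arrays
    cat_arrays = {
        name: {
            code[chrom]: (
                g.sort_values("start")["start"].to_numpy(np.int64),
                g.sort_values("start")["end"].to_numpy(np.int64),
            )
            for chrom, g in df.groupby("chrom", sort=False)
        }
        for name, df in target_sets.items()
    }

    def stat_hits(chroms, starts, ends, name) -> np.ndarray:
        hit = np.zeros(len(starts), dtype=bool)
        for chrom in np.unique(chroms):
            if chrom not in cat_arrays[name]:
                continue
            cs, ce = cat_arrays[name][chrom]
            m = chroms == chrom
            hit[m] = _intersects_any(starts[m], ends[m], cs, ce)
        return hit

    iz_chrom = izs["chrom"].map(code).to_numpy(np.int64)
    iz_start = izs["start"].to_numpy(np.int64)
    iz_end = izs["end"].to_numpy(np.int64)
    sizes = iz_end - iz_start
    mids = (iz_start + iz_end) // 2
    # A/B composition of the observed IZs (membership at the midpoint)
    iz_label = np.empty(len(izs), dtype=object)
    for label, sp in comp_space.items():
        for chrom in np.unique(iz_chrom):
            m = iz_chrom == chrom
            cm_m = sp["chrom"] == chrom
            if not cm_m.any():
                continue
            cs = sp["start"][cm_m]
            cl = sp["len"][cm_m]
            idx = np.searchsorted(cs, mids[m], side="right") - 1
            ok = (idx >= 0) & (mids[m] < cs[np.clip(idx, 0, None)] + cl[np.clip(idx, 0, None)])
            sub = np.flatnonzero(m)[ok]
            iz_label[sub] = label
    labels, label_counts = np.unique(iz_label[iz_label != None], return_counts=True)  # noqa: E711
    p_label = label_counts / label_counts.sum()

    observed = np.array(
        [stat_hits(iz_chrom, iz_start, iz_end, name).mean() for name in target_sets]
    )

    n_iz = len(izs)
    total = n_resamples * n_iz
    sz = rng.choice(sizes, size=total, replace=True)
    lab_idx = rng.choice(len(labels), size=total, p=p_label)
    starts = np.empty(total, dtype=np.int64)
    chroms = np.empty(total, dtype=np.int64)
    for li, label in enumerate(labels):
        m = lab_idx == li
        if not m.any():
            continue
        sp = comp_space[label]
        pos = rng.integers(0, sp["cum"][-1], size=int(m.sum()))
        iv = np.searchsorted(sp["cum"], pos, side="right") - 1
        starts[m] = sp["start"][iv] + (pos - sp["cum"][iv])
        chroms[m] = sp["chrom"][iv]
    ends = starts + sz
    null = np.zeros((n_resamples, len(target_sets)))
    for k, name in enumerate(target_sets):
        hit = stat_hits(chroms, starts, ends, name)
        null[:, k] = hit.reshape(n_resamples, n_iz).mean(axis=1)

    out = {}
    for k, name in enumerate(target_sets):
        p = (1 + int((null[:, k] >= observed[k]).sum())) / (1 + n_resamples)
        out[name] = {"observed": float(observed[k]), "p": float(p),
                     "null_mean": float(null[:, k].mean())}
    return out
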