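"""A/B compartment calling, saddle plots and preferential interactions.

Compartments are read per chromosome from the eigenvectors of the
Pearson-correlation matrix of the z-scored O/E map, oriented by an
external reference track (gene density or GC content).  Saddle analysis
sorts bins by eigenvector quantile and averages O/E within quantile
pairs; compartment strength is the top-20% corner ratio
top(AA)/(AB+BA) and top(BB)/(BA+AB).  The same sorting machinery applied
to an arbitrary nuclear-position track quantifies preferential
interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact import ContactMatrix, observed_over_expected

__all__ = [
    "CompartmentProfile",
    "SaddleResult",
    "compartment_eigenvector",
    "gam_compartments",
    "call_compartment_domains",
    "saddle",
    "saddle_result",
    "compartment_strength",
    "preferential_interactions",
]


@dataclass
class CompartmentProfile:
    eigenvector: np.ndarray            # NaN on bad bins
    labels: np.ndarray                 # +1 A / -1 B / 0 unlabelled
    component_index: dict[str, int]    # chosen component per chromosome
    reference_correlation: dict[str, float]


@dataclass
class SaddleResult:
    matrix: np.ndarray
    qrange: tuple[float, float]
    aa_strength: float
    bb_strength: float


def _corr_of_zscored_oe(oe_sub: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation matrix of the z-scored O/E submatrix.

    Off-diagonal O/E values are z-scored globally; rows that are constant
    or all-NaN are dropped (returned valid mask).
    """
    m = oe_sub.copy()
    np.fill_diagonal(m, np.nan)
    vals = m[np.isfinite(m)]
    if vals.size == 0:
        return np.zeros((0, 0)), np.zeros(m.shape[0], dtype=bool)
    z = (m - vals.mean()) / (vals.std() if vals.std() > 0 else 1.0)
    z = np.nan_to_num(z)
    valid = np.isfinite(oe_sub).any(axis=1) & (z.std(axis=1) > 0)
    zv = z[np.ix_(valid, valid)]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(zv)
    corr = np.nan_to_num(corr)
    return corr, valid


def _pick_and_orient(
    components: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, int, float]:
    """Among candidate components (rows), pick max |corr| with reference
    and flip its sign so that it correlates positively."""
    best, best_r = 0, 0.0
    for k in range(components.shape[0]):
        v = components[k]
        if v.std() == 0 or reference.std() == 0:
            continue
        r = float(np.corrcoef(v, reference)[0, 1])
        if abs(r) > abs(best_r):
            best, best_r = k, r
    ev = components[best] * (1.0 if best_r >= 0 else -1.0)
    return ev, best, best_r


def compartment_eigenvector(
    cm: ContactMatrix,
    reference_track: np.ndarray,
    n_components: int = 3,
    balanced: bool = False,
    component_override: dict[str, int] | None = None,
) -> CompartmentProfile:
    """Per-chromosome compartment eigenvector oriented by a reference.

    The O/E map is z-scored off-diagonal, turned into a Pearson
    correlation matrix, and eigendecomposed; among the top
    `n_components` eigenvectors the one with maximal |correlation| to
    the reference track is selected and sign-flipped so that positive
    values align with high reference (A = positive, B = negative).
    `component_override` forces the component index for named
    chromosomes (manual rescue for atypical chromosomes).
    """
    if reference_track is None:
        raise ValueError("a reference track is required for orientation")
    reference_track = np.asarray(reference_track, dtype=float)
    if len(reference_track) != cm.layout.n_bins:
        raise ValueError("reference track length disagrees with layout")
    oe = observed_over_expected(cm, balanced=balanced)
    n = cm.layout.n_bins
    ev_full = np.full(n, np.nan)
    comp_idx: dict[str, int] = {}
    ref_corr: dict[str, float] = {}
    for chrom in cm.layout.chroms:
        sl = cm.layout.chrom_slice(chrom)
        corr, valid = _corr_of_zscored_oe(oe[sl, sl])
        if corr.shape[0] < n_components + 1:
            continue
        w, v = np.linalg.eigh(corr)
        order = np.argsort(w)[::-1]
        comps = v[:, order[:n_components]].T
        ref = reference_track[sl][valid]
        if component_override and chrom in component_override:
            k = component_override[chrom]
            evc, _, r = _pick_and_orient(comps[k : k + 1], ref)
        else:
            evc, k, r = _pick_and_orient(comps, ref)
        sub = np.full(sl.stop - sl.start, np.nan)
        sub[valid] = evc
        ev_full[sl] = sub
        comp_idx[chrom] = k
        ref_corr[chrom] = r
    labels = np.zeros(n, dtype=int)
    labels[np.nan_to_num(ev_full) > 0] = 1
    labels[np.nan_to_num(ev_full) < 0] = -1
    labels[~np.isfinite(ev_full)] = 0
    return CompartmentProfile(ev_full, labels, comp_idx, ref_corr)


def gam_compartments(
    cm: ContactMatrix,
    reference_gc: np.ndarray,
    component_override: dict[str, int] | None = None,
) -> CompartmentProfile:
    """Compartments from a GAM co-segregation (or NPMI) matrix.

    O/E -> Pearson correlation matrix -> PCA on the first three
    components -> component with highest |correlation| to GC content,
    oriented so that A (positive) has high GC.  Algebraically this is
    the same correlation-matrix eigendecomposition used for ligation
    assays, so the implementation is shared.
    """
    return compartment_eigenvector(
        cm, reference_gc, n_components=3, component_override=component_override
    )


def call_compartment_domains(profile: CompartmentProfile, layout) -> "list[dict]":
    """Maximal runs of constant compartment sign, with sizes in bp."""
    out = []
    bins = layout.bins
    for chrom in layout.chroms:
        sl = layout.chrom_slice(chrom)
        lab = profile.labels[sl]
        start = None
        cur = 0
        for i in range(len(lab) + 1):
            v = lab[i] if i < len(lab) else 0
            if v != cur:
                if cur != 0 and start is not None:
                    out.append(
                        {
                            "chrom": chrom,
                            "start": int(bins["start"].iloc[sl.start + start]),
                            "end": int(bins["end"].iloc[sl.start + i - 1]),
                            "label": "A" if cur > 0 else "B",
                        }
                    )
                start = i
                cur = v
    for d in out:
        d["size"] = d["end"] - d["start"]
    return out


def saddle(
    cm: ContactMatrix,
    profile_values: np.ndarray,
    n_quantile_bins: int = 50,
    qrange: tuple[float, float] = (0.02, 0.98),
    balanced: bool = False,
) -> np.ndarray:
    """Quantile-binned mean O/E sorted by a per-bin profile.

    Bins are ranked by `profile_values` within `qrange` quantiles; the
    saddle matrix entry (p, q) is the mean cis O/E between bins of
    profile-quantile p and q.  First quantile = lowest profile
    (strongest B, top-left corner), last = highest (A, bottom-right).
    """
    if n_quantile_bins < 2:
        raise ValueError("n_quantile_bins must be >= 2")
    prof = np.asarray(profile_values, dtype=float)
    oe = observed_over_expected(cm, balanced=balanced)
    ok = np.isfinite(prof)
    lo, hi = np.quantile(prof[ok], qrange)
    sel = ok & (prof >= lo) & (prof <= hi)
    # rank-based quantile bins: equal occupancy even for discrete profiles,
    # ties broken by bin order (stable sort) for determinism
    qbin = np.full(len(prof), -1)
    sel_idx = np.flatnonzero(sel)
    order = sel_idx[np.argsort(prof[sel_idx], kind="stable")]
    ranks = np.empty(len(order), dtype=float)
    ranks[np.arange(len(order))] = np.arange(len(order))
    qbin[order] = np.minimum(
        (np.arange(len(order)) * n_quantile_bins) // max(1, len(order)), n_quantile_bins - 1
    )
    sums = np.zeros((n_quantile_bins, n_quantile_bins))
    cnts = np.zeros((n_quantile_bins, n_quantile_bins))
    for chrom in cm.layout.chroms:
        sl = cm.layout.chrom_slice(chrom)
        sub = oe[sl, sl]
        q = qbin[sl]
        good = q >= 0
        sub = sub[np.ix_(good, good)]
        qg = q[good]
        finite = np.isfinite(sub)
        np.add.at(sums, (qg[:, None].repeat(len(qg), 1)[finite], qg[None, :].repeat(len(qg), 0)[finite]), sub[finite])
        np.add.at(cnts, (qg[:, None].repeat(len(qg), 1)[finite], qg[None, :].repeat(len(qg), 0)[finite]), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cnts > 0, sums / cnts, np.nan)


def compartment_strength(
    saddle_matrix: np.ndarray, top_frac: float = 0.2
) -> tuple[float, float]:
    """Corner-ratio strengths from a saddle matrix.

    AA strength = mean(top-frac AA corner) / (mean(AB) + mean(BA))
    computed over the extreme `top_frac` quantile corners; BB likewise.
    On an all-ones saddle both strengths are 0.5.
    """
    n = saddle_matrix.shape[0]
    k = max(1, int(round(top_frac * n)))
    bb = np.nanmean(saddle_matrix[:k, :k])
    aa = np.nanmean(saddle_matrix[-k:, -k:])
    ba = np.nanmean(saddle_matrix[:k, -k:])
    ab = np.nanmean(saddle_matrix[-k:, :k])
    return float(aa / (ab + ba)), float(bb / (ba + ab))


def saddle_result(
    cm: ContactMatrix,
    profile: CompartmentProfile | np.ndarray,
    n_quantile_bins: int = 50,
    qrange: tuple[float, float] = (0.02, 0.98),
    top_frac: float = 0.2,
    balanced: bool = False,
) -> SaddleResult:
    vals = profile.eigenvector if isinstance(profile, CompartmentProfile) else profile
    mat = saddle(cm, vals, n_quantile_bins, qrange, balanced=balanced)
    aa, bb = compartment_strength(mat, top_frac)
    return SaddleResult(mat, qrange, aa, bb)


def preferential_interactions(
    cm: ContactMatrix,
    track: np.ndarray,
    n_quantile_bins: int = 50,
    qrange: tuple[float, float] = (0.02, 0.98),
    top_frac: float = 0.2,
    drop_zeros: bool = False,
    clip_quantile: float | None = None,
    balanced: bool = False,
) -> SaddleResult:
    """Track-sorted O/E saddle and top-20% preferential strength.

    For replication-timing-like tracks, `drop_zeros` removes bins with
    missing or zero values and `clip_quantile` (e.g. 0.98) removes
    outlier bins above that quantile before ranking.  The "preferential"
    strength is the high-track homotypic corner over the heterotypic
    corners (same algebra as compartment strength; AA slot = high track).
    """
    track = np.asarray(track, dtype=float).copy()
    if len(track) != cm.layout.n_bins:
        raise ValueError("track length disagrees with matrix layout")
    if drop_zeros:
        track[track == 0] = np.nan
    if clip_quantile is not None:
        hi = np.nanquantile(track, clip_quantile)
        track[track > hi] = np.nan
    finite = track[np.isfinite(track)]
    if finite.size == 0 or finite.std() == 0:
        raise ValueError("constant or empty track: no ranking possible")
    mat = saddle(cm, track, n_quantile_bins, qrange, balanced=balanced)
    aa, bb = compartment_strength(mat, top_frac)
    return SaddleResult(mat, qrange, aa, bb)
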