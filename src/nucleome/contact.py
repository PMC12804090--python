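"""Contact-matrix primitives.

Dense symmetric per-genome matrices are used throughout: the package
operates at desk scale (hundreds to a few thousand bins), where a dense
array is both faster and simpler than sparse plumbing.  Functions here
implement matrix balancing by iterative correction, the distance-decay
expected model and observed/expected ratios, contact-probability curves
P(s), the cis fraction, and the stratum-adjusted correlation coefficient
(SCC) used to compare maps from different assays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .layout import GenomeLayout

__all__ = [
    "ContactMatrix",
    "ice_balance",
    "expected_by_distance",
    "observed_over_expected",
    "contact_probability_curve",
    "cis_fraction",
    "scc",
]


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts with optional balancing weights.

    ``counts[i, j]`` is the observed interaction count between global bins
    i and j.  ``weights`` (if set) are multiplicative per-bin balancing
    factors; ``bad_bins`` marks bins excluded from normalization and all
    downstream statistics.
    """

    layout: GenomeLayout
    counts: np.ndarray
    weights: np.ndarray | None = None
    bad_bins: np.ndarray | None = None
    converged: bool | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be square")
        if c.shape[0] != self.layout.n_bins:
            raise ValueError("counts shape disagrees with layout")
        if (c < 0).any():
            raise ValueError("negative counts")
        if not np.allclose(c, c.T):
            raise ValueError("counts must be symmetric")
        self.counts = c
        if self.bad_bins is None:
            self.bad_bins = np.zeros(c.shape[0], dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def balanced(self) -> np.ndarray:
        """w_i * count(i,j) * w_j with NaN on bad bins."""
        if self.weights is None:
            raise ValueError("matrix is not balanced; call ice_balance first")
        w = self.weights
        out = self.counts * w[:, None] * w[None, :]
        out[self.bad_bins, :] = np.nan
        out[:, self.bad_bins] = np.nan
        return out

    def values(self, balanced: bool = False) -> np.ndarray:
        if balanced:
            return self.balanced()
        out = self.counts.copy()
        out[self.bad_bins, :] = np.nan
        out[:, self.bad_bins] = np.nan
        return out


def mark_bad_bins(counts: np.ndarray, min_nonzero_frac: float = 0.02) -> np.ndarray:
    """Bins with less than `min_nonzero_frac` non-zero-count coverage.

    Mirrors the removal of rows/columns with <2% non-zero counts before
    eigendecomposition; applied uniformly ahead of balancing.
    """
    n = counts.shape[0]
    nz = (counts > 0).sum(axis=1)
    return (nz < max(1, min_nonzero_frac * n)) | (counts.sum(axis=1) == 0)


def ice_balance(
    cm: ContactMatrix,
    tol: float = 1e-6,
    max_iter: int = 1000,
    min_nonzero_frac: float = 0.02,
) -> ContactMatrix:
    """Iterative correction: find weights equalizing matrix marginals.

    Returns a new ContactMatrix carrying ``weights`` such that the
    marginals of w_i·count(i,j)·w_j agree across non-bad bins to within
    `tol` (coefficient of variation).  Non-convergence raises a warning
    and the partial weights are flagged via ``converged=False``.
    """
    bad = mark_bad_bins(cm.counts, min_nonzero_frac)
    good = ~bad
    m = cm.counts[np.ix_(good, good)].astype(float)
    w = np.ones(m.shape[0])
    converged = False
    for _ in range(max_iter):
        s = (m * w[None, :]).sum(axis=1) * w
        mean = s[s > 0].mean() if (s > 0).any() else 0.0
        if mean == 0:
            break
        cv = s.std() / mean
        if cv < tol:
            converged = True
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(s > 0, w / np.sqrt(s / mean), w)
    if not converged:
        warnings.warn("iterative correction did not converge; partial weights returned")
    weights = np.full(cm.n_bins, np.nan)
    weights[good] = w
    return replace(cm, weights=weights, bad_bins=bad, converged=converged)


def _per_diag_mean(mat: np.ndarray) -> np.ndarray:
    """Mean per |i-j| diagonal, NaN-aware; length n."""
    n = mat.shape[0]
    out = np.full(n, np.nan)
    for d in range(n):
        v = np.diagonal(mat, offset=d)
        v = v[np.isfinite(v)]
        if v.size:
            out[d] = v.mean()
    return out


def expected_by_distance(cm: ContactMatrix, balanced: bool = False) -> dict[str, np.ndarray]:
    """Per-chromosome vector of mean contacts at each bin separation.

    E(i,j) depends only on |i-j| within a chromosome.  Empty chromosomes
    are skipped.
    """
    vals = cm.values(balanced=balanced)
    out: dict[str, np.ndarray] = {}
    for chrom in cm.layout.chroms:
        sl = cm.layout.chrom_slice(chrom)
        sub = vals[sl, sl]
        if sub.size == 0 or not np.isfinite(sub).any():
            continue
        out[chrom] = _per_diag_mean(sub)
    return out


def observed_over_expected(cm: ContactMatrix, balanced: bool = False) -> np.ndarray:
    """Cis O/E matrix (NaN off-chromosome, where E=0 or on bad bins)."""
    vals = cm.values(balanced=balanced)
    exp = expected_by_distance(cm, balanced=balanced)
    oe = np.full_like(vals, np.nan)
    for chrom in cm.layout.chroms:
        if chrom not in exp:
            continue
        sl = cm.layout.chrom_slice(chrom)
        n = sl.stop - sl.start
        idx = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        e = exp[chrom][idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            oe[sl, sl] = np.where(e > 0, vals[sl, sl] / e, np.nan)
    return oe


def contact_probability_curve(
    cm: ContactMatrix, log_bin_factor: float = 1.3, balanced: bool = False
):
    """P(s): normalized cis contact frequency on geometric distance strata.

    Returns a dict with stratum mid separations (bp), normalized P values
    (summing to 1), and the log-log finite-difference derivative.
    """
    if log_bin_factor <= 1:
        raise ValueError("log_bin_factor must be > 1")
    vals = cm.values(balanced=balanced)
    n_max = max(
        cm.layout.chrom_offsets[c + 1] - cm.layout.chrom_offsets[c]
        for c in range(cm.layout.n_chroms)
    )
    # pool per-separation sums over chromosomes
    sums = np.zeros(n_max)
    cnts = np.zeros(n_max)
    for chrom in cm.layout.chroms:
        sl = cm.layout.chrom_slice(chrom)
        sub = vals[sl, sl]
        for d in range(1, sub.shape[0]):
            v = np.diagonal(sub, offset=d)
            v = v[np.isfinite(v)]
            sums[d] += v.sum()
            cnts[d] += v.size
    edges = [1]
    while edges[-1] < n_max:
        edges.append(max(edges[-1] + 1, int(round(edges[-1] * log_bin_factor))))
    edges = np.asarray(edges)
    strata = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        c = cnts[lo:hi].sum()
        if c > 0:
            strata.append((np.sqrt(lo * (hi - 1)) * cm.layout.bin_size, sums[lo:hi].sum() / c))
    if len(strata) < 3:
        raise ValueError("fewer than 3 populated distance strata")
    s = np.array([x[0] for x in strata])
    p = np.array([x[1] for x in strata])
    p = p / p.sum()
    slope = np.gradient(np.log(p), np.log(s))
    return {"s_bp": s, "P": p, "slope": slope}


def cis_fraction(cm: ContactMatrix) -> float:
    """cis / (cis + trans) over all counted pairs."""
    cis_mask = cm.layout.same_chrom()
    total = cm.counts.sum()
    if total == 0:
        return 0.0
    return float(cm.counts[cis_mask].sum() / total)


def _smooth2d(mat: np.ndarray, h: int) -> np.ndarray:
    if h <= 0:
        return mat
    return ndimage.uniform_filter(mat, size=2 * h + 1, mode="nearest")


def scc(
    cm1: ContactMatrix,
    cm2: ContactMatrix,
    max_distance_bins: int | None = None,
    smooth_h: int = 1,
    balanced: bool = False,
) -> float:
    """Stratum-adjusted correlation coefficient between two cis maps.

    Both maps are optionally smoothed with a (2h+1)-square mean filter,
    then Pearson correlations r_k are computed within each genomic-distance
    stratum k and aggregated with weights w_k = N_k·sd_k(x)·sd_k(y).
    Zero-variance strata are excluded.
    """
    if cm1.layout.n_bins != cm2.layout.n_bins:
        raise ValueError("layouts disagree")
    num = 0.0
    den = 0.0
    for chrom in cm1.layout.chroms:
        sl = cm1.layout.chrom_slice(chrom)
        a = np.nan_to_num(cm1.values(balanced=balanced)[sl, sl])
        b = np.nan_to_num(cm2.values(balanced=balanced)[sl, sl])
        a = _smooth2d(a, smooth_h)
        b = _smooth2d(b, smooth_h)
        n = a.shape[0]
        dmax = n - 1 if max_distance_bins is None else min(max_distance_bins, n - 1)
        for d in range(1, dmax + 1):
            x = np.diagonal(a, offset=d)
            y = np.diagonal(b, offset=d)
            if x.size < 2:
                continue
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            w = x.size * sx * sy
            num += w * r
            den += w
    if den == 0:
        raise ValueError("no informative strata")
    return float(num / den)
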