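"""Genome architecture mapping (GAM) table primitives.

GAM detects loci through their presence in thin nuclear cryosections:
a segregation table records, per sequencing sample (one or more nuclear
profiles), which genomic windows were detected.  This module implements
window calling from per-window nucleotide coverage, per-sample quality
control, detection-frequency curation, and the co-segregation / NPMI
contact statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layout import GenomeLayout

__all__ = [
    "SegregationTable",
    "GamSampleQC",
    "gam_call_windows",
    "gam_sample_qc",
    "gam_wdf_curation",
    "gam_cosegregation",
    "gam_npmi",
]


@dataclass
class SegregationTable:
    """Boolean detection matrix (samples x windows) plus QC metadata."""

    layout: GenomeLayout
    detection: np.ndarray                       # bool (n_samples, n_bins)
    sample_ids: list[str] = field(default_factory=list)
    read_counts: np.ndarray | None = None       # uniquely mapped reads per sample
    mappability: np.ndarray | None = None       # per-window mean mappability
    plate: np.ndarray | None = None             # plate group id per sample
    mask: np.ndarray | None = None              # curation mask (True = excluded)

    def __post_init__(self) -> None:
        d = np.asarray(self.detection)
        if d.dtype != bool:
            raise ValueError("detection matrix must be boolean")
        if d.shape[1] != self.layout.n_bins:
            raise ValueError("window count disagrees with layout")
        self.detection = d
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(d.shape[0])]
        if self.mask is None:
            self.mask = np.zeros(d.shape[1], dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.detection.shape[0]

    def wdf(self) -> np.ndarray:
        """Window detection frequency across samples."""
        return self.detection.mean(axis=0)


@dataclass(frozen=True)
class GamSampleQC:
    sample_id: str
    orphan_fraction: float
    coverage_fraction: float
    reads: int
    contamination_jaccard: float
    passed: bool


def _orphan_fraction(pos: np.ndarray, layout: GenomeLayout) -> float:
    """Fraction of positive windows flanked by two negative windows.

    Chromosome boundaries count as negative neighbours, so a lone positive
    at a chromosome end is an orphan.
    """
    n_pos = int(pos.sum())
    if n_pos == 0:
        return 0.0
    orphans = 0
    for c in range(layout.n_chroms):
        p = pos[layout.chrom_slice(c)]
        padded = np.concatenate([[False], p, [False]])
        orphans += int((p & ~padded[:-2] & ~padded[2:]).sum())
    return orphans / n_pos


def gam_call_windows(coverage: np.ndarray, layout: GenomeLayout):
    """Call positive windows for one sample from nucleotide coverage.

    For every integer percentile (1-99) of the positive-coverage
    distribution, the orphan fraction of the resulting positive set is
    computed; the threshold is the coverage value at the percentile that
    minimizes it (ties resolved toward the lower percentile, retaining
    more windows).  Windows with coverage strictly above the threshold
    are positive.

    Returns (positive boolean vector, chosen threshold).
    """
    coverage = np.asarray(coverage, dtype=float)
    if (coverage < 0).any():
        raise ValueError("negative coverage")
    positive_cov = coverage[coverage > 0]
    if positive_cov.size == 0:
        return np.zeros_like(coverage, dtype=bool), np.inf
    best = None
    for pct in range(1, 100):
        thr = float(np.percentile(positive_cov, pct))
        pos = coverage > thr
        frac = _orphan_fraction(pos, layout)
        if best is None or frac < best[0]:
            best = (frac, pct, thr)
    _, _, thr = best
    return coverage > thr, thr


def gam_sample_qc(
    seg: SegregationTable,
    max_orphan: float = 0.40,
    max_coverage: float = 0.60,
    min_reads: int = 50_000,
    max_jaccard: float = 0.4,
) -> list[GamSampleQC]:
    """Per-sample QC: orphan windows, coverage, reads, cross-well Jaccard.

    A sample passes iff orphan <= 40%, genome coverage <= 60%, uniquely
    mapped reads > 50,000 (strict) and the maximum pairwise Jaccard index
    with another sample of the same collection plate < 0.4.
    """
    d = seg.detection
    reads = seg.read_counts if seg.read_counts is not None else np.full(seg.n_samples, np.inf)
    plate = seg.plate if seg.plate is not None else np.zeros(seg.n_samples, dtype=int)
    inter = (d.astype(int) @ d.astype(int).T).astype(float)
    sizes = d.sum(axis=1).astype(float)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / union, 0.0)
    np.fill_diagonal(jac, 0.0)
    out = []
    for i in range(seg.n_samples):
        same_plate = (plate == plate[i]) & (np.arange(seg.n_samples) != i)
        contam = float(jac[i, same_plate].max()) if same_plate.any() else 0.0
        orphan = _orphan_fraction(d[i], seg.layout)
        cov = float(d[i].mean())
        passed = (
            orphan <= max_orphan
            and cov <= max_coverage
            and reads[i] > min_reads
            and contam < max_jaccard
        )
        out.append(GamSampleQC(seg.sample_ids[i], orphan, cov, int(reads[i]), contam, passed))
    return out


def _running_mean(x: np.ndarray, w: int) -> np.ndarray:
    """Running mean with a symmetrically shrinking window at the edges."""
    h = w // 2
    out = np.empty_like(x, dtype=float)
    for i in range(len(x)):
        k = min(h, i, len(x) - 1 - i)
        out[i] = x[i - k : i + k + 1].mean()
    return out


def gam_wdf_curation(
    seg: SegregationTable,
    nd_fold: float = 5.0,
    smooth_windows: int = 11,
    flank: int = 2,
    min_mappability: float = 0.2,
) -> np.ndarray:
    """Curation mask from window detection frequency outliers.

    The WDF is smoothed per chromosome in stretches of 11 windows; the
    normalized delta ND = (raw - smoothed)/smoothed flags over-detected
    windows (ND > 5), which are masked together with 2 windows on each
    side.  Windows with mean mappability < 0.2 are masked regardless.
    """
    wdf = seg.wdf()
    mask = np.zeros(seg.layout.n_bins, dtype=bool)
    for c in range(seg.layout.n_chroms):
        sl = seg.layout.chrom_slice(c)
        raw = wdf[sl]
        smooth = _running_mean(raw, smooth_windows)
        with np.errstate(divide="ignore", invalid="ignore"):
            nd = np.where(smooth > 0, (raw - smooth) / smooth, 0.0)
        hits = np.flatnonzero(nd > nd_fold)
        sub = np.zeros(len(raw), dtype=bool)
        for h in hits:
            sub[max(0, h - flank) : h + flank + 1] = True
        mask[sl] = sub
    if seg.mappability is not None:
        mask |= seg.mappability < min_mappability
    return mask


def gam_cosegregation(seg: SegregationTable) -> np.ndarray:
    """Count of samples in which both windows are positive (masked -> NaN)."""
    d = seg.detection.astype(float)
    co = d.T @ d
    co[seg.mask, :] = np.nan
    co[:, seg.mask] = np.nan
    return co


def gam_npmi(seg: SegregationTable) -> np.ndarray:
    """Normalized pointwise mutual information between window pairs.

    NPMI(i,j) = ln(p(i,j) / (p(i)p(j))) / (-ln p(i,j)) with p the
    detection and co-detection frequencies across samples; bounded in
    [-1, 1].  Pairs never co-detected are NaN; windows detected in all
    samples (p = 1, degenerate normalizer) are excluded, as are masked
    windows.
    """
    n = seg.n_samples
    if n == 0:
        raise ValueError("empty segregation table")
    p = seg.wdf()
    co = (seg.detection.astype(float).T @ seg.detection.astype(float)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(co / (p[:, None] * p[None, :]))
        npmi = pmi / (-np.log(co))
    npmi[co == 0] = np.nan
    bad = seg.mask | (p == 0) | (p == 1)
    npmi[bad, :] = np.nan
    npmi[:, bad] = np.nan
    np.fill_diagonal(npmi, np.where(np.isfinite(np.diagonal(npmi)), 1.0, np.nan))
    return npmi
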