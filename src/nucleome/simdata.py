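"""Synthetic inputs with planted, recorded ground truth.

Every downstream stage of the package is exercised on data produced here:
distance-decay contact maps with planted A/B blocks, TADs and loop
spikes; confined biased-random-walk diploid structure populations;
GAM-style slab sampling; nuclear-position tracks tied to planted
speckle/lamina geometry; state-conditional Gaussian observation tracks;
loop sets with planted anchor-state signatures; and expression tables
with planted breadth.

The generators are statistical emulators, not physics: they are designed
so that each planted property is recoverable by the corresponding
analysis operation, with the truth recorded for the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contact import ContactMatrix
from .gam import SegregationTable
from .layout import GenomeLayout, make_genome  # noqa: F401  (re-export)

__all__ = [
    "NuclearGeometry",
    "PlantedTruth",
    "StructurePopulation",
    "make_genome",
    "plant_truth",
    "simulate_contact_map",
    "simulate_structures",
    "structures_to_contacts",
    "simulate_gam",
    "simulate_tracks",
    "plant_spin_states",
    "simulate_spin_observations",
    "simulate_loops_with_states",
    "simulate_expression",
]


@dataclass(frozen=True)
class NuclearGeometry:
    """Ellipsoidal nuclear envelope; a sphere is a == b == c."""

    a: float
    b: float
    c: float
    bead_radius: float = 118.0

    def __post_init__(self) -> None:
        if not (self.a >= self.b >= self.c > 0):
            raise ValueError("require a >= b >= c > 0")

    @classmethod
    def sphere(cls, radius: float, bead_radius: float = 118.0) -> "NuclearGeometry":
        return cls(radius, radius, radius, bead_radius)

    def semiaxes(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    def radial(self, xyz: np.ndarray) -> np.ndarray:
        """Normalized radial distance r with r=1 on the envelope."""
        return np.sqrt(((xyz / self.semiaxes()) ** 2).sum(axis=-1))


@dataclass
class PlantedTruth:
    """Ground truth recorded by the generators, consumed only by tests."""

    layout: GenomeLayout
    compartments: np.ndarray            # +1 = A, -1 = B per bin
    tad_boundaries: np.ndarray          # global bin ids
    loops: pd.DataFrame                 # bin1, bin2, factor
    spin_labels: np.ndarray | None = None
    spin_means: np.ndarray | None = None       # (K, d) emission means
    spin_sd: float | None = None
    expression_class: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.compartments) != self.layout.n_bins:
            raise ValueError("compartment labels must cover all bins")
        if len(self.loops) and (self.loops["factor"] < 1).any():
            raise ValueError("loop enrichment factors must be >= 1")
        if len(self.loops):
            ch = self.layout.bin_chrom
            if (ch[self.loops["bin1"]] != ch[self.loops["bin2"]]).any():
                raise ValueError("loops must lie within one chromosome")


@dataclass
class StructurePopulation:
    """S diploid structures of bead centres inside a nuclear envelope."""

    layout: GenomeLayout
    geometry: NuclearGeometry
    coords: np.ndarray                  # (S, n_beads, 3) nm
    bead_bin: np.ndarray                # global bin id per bead
    bead_allele: np.ndarray             # 0 / 1
    speckles: list[np.ndarray] = field(default_factory=list)   # per structure (k,3)
    nucleoli: list[np.ndarray] = field(default_factory=list)

    @property
    def n_structures(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    @property
    def bead_chrom(self) -> np.ndarray:
        return self.layout.bin_chrom[self.bead_bin]

    def radial(self) -> np.ndarray:
        """Normalized radial positions, shape (S, n_beads)."""
        return self.geometry.radial(self.coords)

    def allele_beads(self, bin_id: int) -> np.ndarray:
        return np.flatnonzero(self.bead_bin == bin_id)


def plant_truth(
    layout: GenomeLayout,
    block_bins: int = 25,
    tad_bins: int = 20,
    n_loops: int = 0,
    loop_factor: float = 3.0,
    loop_distance_bins: tuple[int, int] = (10, 60),
    seed: int = 0,
) -> PlantedTruth:
    """Default planted truth: alternating A/B blocks, regular TADs, loops."""
    rng = np.random.default_rng(seed)
    comp = np.empty(layout.n_bins, dtype=int)
    boundaries = []
    loops = []
    for c in range(layout.n_chroms):
        sl = layout.chrom_slice(c)
        n = sl.stop - sl.start
        idx = np.arange(n)
        comp[sl] = np.where((idx // block_bins) % 2 == 0, 1, -1)
        b = np.arange(tad_bins, n, tad_bins)
        boundaries.extend(b + sl.start)
        if n_loops:
            per_chrom = int(round(n_loops * n / layout.n_bins))
            lo, hi = loop_distance_bins
            for _ in range(per_chrom):
                d = int(rng.integers(lo, min(hi, n - 2) + 1))
                i = int(rng.integers(0, n - d))
                loops.append((sl.start + i, sl.start + i + d, loop_factor))
    loop_df = pd.DataFrame(loops, columns=["bin1", "bin2", "factor"]).astype(
        {"bin1": int, "bin2": int, "factor": float}
    )
    return PlantedTruth(
        layout=layout,
        compartments=comp,
        tad_boundaries=np.asarray(sorted(boundaries), dtype=int),
        loops=loop_df,
    )


def simulate_contact_map(
    layout: GenomeLayout,
    truth: PlantedTruth,
    depth: int,
    decay_exponent: float = 1.0,
    compartment_strength: float = 1.0,
    tad_strength: float = 1.0,
    trans_level: float = 0.01,
    seed: int = 0,
) -> ContactMatrix:
    """Multinomial block-model contact map with planted structure.

    Intensity lambda(i,j) ~ s^(-decay_exponent) x c(i,j) x t(i,j) x l(i,j)
    where c multiplies same-compartment pairs by `compartment_strength`,
    t multiplies within-TAD pairs by `tad_strength` and l multiplies the
    planted loop pixels by their factor.  Trans intensity is a constant:
    `trans_level` times the shortest-range cis intensity.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if compartment_strength < 1 or tad_strength < 1:
        raise ValueError("strengths must be >= 1")
    n = layout.n_bins
    lam = np.zeros((n, n))
    comp = truth.compartments
    for c in range(layout.n_chroms):
        sl = layout.chrom_slice(c)
        m = sl.stop - sl.start
        idx = np.arange(m)
        s = np.abs(idx[:, None] - idx[None, :]).astype(float)
        with np.errstate(divide="ignore"):
            base = np.where(s > 0, s ** (-decay_exponent), 0.0)
        same = comp[sl][:, None] == comp[sl][None, :]
        base = base * np.where(same, compartment_strength, 1.0)
        if tad_strength > 1:
            bnds = truth.tad_boundaries
            local = bnds[(bnds >= sl.start) & (bnds < sl.stop)] - sl.start
            tad_id = np.searchsorted(local, idx, side="right")
            base = base * np.where(tad_id[:, None] == tad_id[None, :], tad_strength, 1.0)
        lam[sl, sl] = base
    for _, row in truth.loops.iterrows():
        f = row["factor"]
        i, j = int(row["bin1"]), int(row["bin2"])
        lam[i, j] *= f
        lam[j, i] *= f
    trans = ~layout.same_chrom()
    lam[trans] = trans_level * 1.0  # shortest-range cis intensity is s=1 -> 1.0
    iu = np.triu_indices(n, k=1)
    p = lam[iu]
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(depth, p)
    counts = np.zeros((n, n))
    counts[iu] = draws
    counts = counts + counts.T
    return ContactMatrix(layout=layout, counts=counts)


def simulate_structures(
    layout: GenomeLayout,
    geometry: NuclearGeometry,
    truth: PlantedTruth,
    n_structures: int,
    seed: int = 0,
    step: float = 300.0,
    radial_bias: float = 0.3,
    n_speckles: int = 6,
    n_nucleoli: int = 2,
) -> StructurePopulation:
    """Biased confined random-walk diploid structure population.

    Each chromosome copy is a random walk of step length `step` (nm)
    confined to the envelope.  `radial_bias` (in normalized radial units
    per step) pushes B-labelled beads toward the envelope and A-labelled
    beads toward the interior; 0 removes the bias entirely.  Planted
    speckle and nucleolus points are drawn per structure: speckles in
    the interior (r < 0.7), nucleoli near the centre (r < 0.4).
    """
    if n_structures < 1:
        raise ValueError("n_structures must be >= 1")
    ax = geometry.semiaxes()
    if (ax <= geometry.bead_radius).any():
        raise ValueError("nuclear envelope too small for beads")
    rng = np.random.default_rng(seed)
    n_bins = layout.n_bins
    bead_bin = np.concatenate([np.arange(n_bins), np.arange(n_bins)])
    bead_allele = np.concatenate([np.zeros(n_bins, int), np.ones(n_bins, int)])
    coords = np.empty((n_structures, 2 * n_bins, 3))
    comp = truth.compartments

    def _draw_inside(r_max: float) -> np.ndarray:
        while True:
            u = rng.uniform(-1, 1, size=3)
            if (u**2).sum() <= r_max**2:
                return u * ax

    for s in range(n_structures):
        for allele in (0, 1):
            off = allele * n_bins
            for c in range(layout.n_chroms):
                sl = layout.chrom_slice(c)
                x = _draw_inside(0.8)
                for i in range(sl.start, sl.stop):
                    d = rng.normal(size=3)
                    d *= step / np.linalg.norm(d)
                    # radial bias in normalized coordinates
                    u = x / ax
                    r = np.linalg.norm(u)
                    if r > 1e-9 and radial_bias != 0:
                        sign = -1.0 if comp[i] > 0 else 1.0
                        d = d + sign * radial_bias * (u / r) * ax.mean()
                    nx = x + d
                    r_new = geometry.radial(nx)
                    if r_new >= 0.98:
                        nx = nx * (0.97 / r_new)
                    coords[s, off + i] = nx
                    x = nx
    pop = StructurePopulation(
        layout=layout,
        geometry=geometry,
        coords=coords,
        bead_bin=bead_bin,
        bead_allele=bead_allele,
    )
    for s in range(n_structures):
        pop.speckles.append(np.stack([_draw_inside(0.7) for _ in range(n_speckles)]))
        pop.nucleoli.append(np.stack([_draw_inside(0.4) for _ in range(n_nucleoli)]))
    return pop


def structures_to_contacts(pop: StructurePopulation, contact_radius: float) -> ContactMatrix:
    """Bin-level contact counts from pairwise bead distances.

    count(i,j) accumulates every (structure, bead-pair) event with centre
    distance <= radius; self-contacts (a bead with itself) are excluded,
    but the two alleles of one bin do contribute to the diagonal.
    """
    if contact_radius < 0:
        raise ValueError("contact_radius must be >= 0")
    n = pop.layout.n_bins
    upper = np.zeros((n, n))
    bb = pop.bead_bin
    for s in range(pop.n_structures):
        x = pop.coords[s]
        d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
        hit = d2 <= contact_radius**2
        np.fill_diagonal(hit, False)
        bi, bj = np.nonzero(np.triu(hit, k=1))
        lo = np.minimum(bb[bi], bb[bj])
        hi = np.maximum(bb[bi], bb[bj])
        np.add.at(upper, (lo, hi), 1.0)
    counts = upper + np.triu(upper, k=1).T
    return ContactMatrix(layout=pop.layout, counts=counts)


def simulate_gam(
    pop: StructurePopulation,
    slice_thickness: float,
    n_samples: int,
    profiles_per_sample: int = 1,
    seed: int = 0,
) -> SegregationTable:
    """GAM sampling: windows hit by random planar slabs through structures.

    Each sample is the union of `profiles_per_sample` nuclear profiles;
    a profile picks a random structure, a slab orientation uniform on the
    sphere and a slab offset uniform over the envelope extent along that
    orientation, and detects every window with a bead inside the slab.
    """
    if profiles_per_sample < 1:
        raise ValueError("profiles_per_sample must be >= 1")
    import warnings

    ax = pop.geometry.semiaxes()
    if slice_thickness > 2 * ax.max():
        warnings.warn("slab thicker than the nucleus: every window detected")
    rng = np.random.default_rng(seed)
    n_bins = pop.layout.n_bins
    det = np.zeros((n_samples, n_bins), dtype=bool)
    for k in range(n_samples):
        for _ in range(profiles_per_sample):
            s = int(rng.integers(pop.n_structures))
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            extent = np.sqrt(((ax * v) ** 2).sum())
            offset = rng.uniform(-extent, extent)
            proj = pop.coords[s] @ v
            inside = np.abs(proj - offset) <= slice_thickness / 2
            det[k, pop.bead_bin[inside]] = True
    return SegregationTable(layout=pop.layout, detection=det)


def simulate_tracks(
    truth: PlantedTruth,
    pop: StructurePopulation,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Nuclear-position 1D tracks derived from the structure population.

    speckle: decreasing monotone transform (negated mean distance, in um)
    of the mean distance to the nearest planted speckle; lamina:
    increasing in mean radial position.  Gaussian noise of `noise_sd`
    (track units) is added to both.
    """
    rng = np.random.default_rng(seed)
    n = pop.layout.n_bins
    sp_d = np.zeros(n)
    rad = np.zeros(n)
    for s in range(pop.n_structures):
        x = pop.coords[s]
        sp = pop.speckles[s] * 1.0
        d = np.sqrt(((x[:, None, :] - sp[None, :, :]) ** 2).sum(-1)).min(axis=1)
        r = pop.geometry.radial(x)
        for allele in (0, 1):
            sel = pop.bead_allele == allele
            sp_d[pop.bead_bin[sel]] += d[sel] / (2 * pop.n_structures)
            rad[pop.bead_bin[sel]] += r[sel] / (2 * pop.n_structures)
    speckle = -sp_d / 1000.0 + rng.normal(0, noise_sd, n)
    lamina = rad + rng.normal(0, noise_sd, n)
    return {"speckle": speckle, "lamina": lamina, "mean_speckle_distance": sp_d, "mean_radial": rad}


def simulate_spin_observations(
    truth: PlantedTruth,
    n_cell_types: int = 2,
    seed: int = 0,
) -> list[np.ndarray]:
    """Per-cell-type observation matrices from state-conditional Gaussians.

    Requires `truth.spin_labels`, `truth.spin_means` (K x d) and
    `truth.spin_sd` to be set.
    """
    if truth.spin_labels is None or truth.spin_means is None:
        raise ValueError("truth has no planted SPIN emission model")
    rng = np.random.default_rng(seed)
    mu = truth.spin_means[truth.spin_labels]
    return [
        mu + rng.normal(0, truth.spin_sd, size=mu.shape) for _ in range(n_cell_types)
    ]


def plant_spin_states(
    truth: PlantedTruth,
    n_states: int = 5,
    run_bins: int = 20,
    separation_sigma: float = 2.0,
    sd: float = 1.0,
    d: int = 2,
    seed: int = 0,
) -> PlantedTruth:
    """Attach planted SPIN labels (contiguous runs) and emission means.

    Means are placed on a circle in the first two observation dimensions
    so that the closest pair of states is `separation_sigma` x sd apart.
    """
    rng = np.random.default_rng(seed)
    n = truth.layout.n_bins
    n_runs = int(np.ceil(n / run_bins))
    labels = rng.integers(0, n_states, size=n_runs).repeat(run_bins)[:n]
    sep = separation_sigma * sd
    # chord between adjacent points on a circle of radius R: 2R sin(pi/K)
    radius = sep / (2 * np.sin(np.pi / n_states))
    ang = 2 * np.pi * np.arange(n_states) / n_states
    means = np.zeros((n_states, d))
    means[:, 0] = radius * np.cos(ang)
    means[:, 1] = radius * np.sin(ang)
    truth.spin_labels = labels
    truth.spin_means = means
    truth.spin_sd = sd
    return truth


def simulate_loops_with_states(
    layout: GenomeLayout,
    n_clusters: int = 4,
    loops_per_cluster: int = 250,
    state_alphabet: tuple[str, ...] = ("E1", "E2", "E3", "E4", "E5", "E6", "E7", "E8"),
    anchor_bp: int = 10_000,
    distance_bp: tuple[int, int] = (100_000, 1_000_000),
    seed: int = 0,
):
    """Loop set with planted per-cluster anchor-state signatures.

    Each cluster is assigned a disjoint unordered pair of chromatin
    states; its loops get anchors placed in segments carrying those
    states.  Returns (loops DataFrame, state segmentation DataFrame,
    planted cluster labels).
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if loops_per_cluster < 1:
        raise ValueError("loops_per_cluster must be >= 1")
    if len(state_alphabet) < 2 * n_clusters:
        raise ValueError("state alphabet too small for disjoint signatures")
    rng = np.random.default_rng(seed)
    signatures = [(state_alphabet[2 * c], state_alphabet[2 * c + 1]) for c in range(n_clusters)]
    loops = []
    segments = []
    labels = []
    # anchors occupy disjoint anchor_bp slots so every anchor carries
    # exactly its planted state
    used: set[tuple[int, int]] = set()
    for c in range(n_clusters):
        s1, s2 = signatures[c]
        for _ in range(loops_per_cluster):
            for _try in range(1000):
                ci = int(rng.integers(layout.n_chroms))
                clen = layout.lengths[ci]
                n_slots = clen // anchor_bp
                d_lo = max(1, distance_bp[0] // anchor_bp)
                d_hi = max(d_lo + 1, min(distance_bp[1] // anchor_bp, n_slots - 1))
                d = int(rng.integers(d_lo, d_hi))
                sl1 = int(rng.integers(0, n_slots - d))
                sl2 = sl1 + d
                if (ci, sl1) in used or (ci, sl2) in used:
                    continue
                used.add((ci, sl1))
                used.add((ci, sl2))
                break
            else:
                raise RuntimeError("could not place non-overlapping anchors")
            a1, a2 = sl1 * anchor_bp, sl2 * anchor_bp
            chrom = layout.chroms[ci]
            loops.append((chrom, a1, a1 + anchor_bp, a2, a2 + anchor_bp, c))
            segments.append((chrom, a1, a1 + anchor_bp, s1))
            segments.append((chrom, a2, a2 + anchor_bp, s2))
            labels.append(c)
    loop_df = pd.DataFrame(
        loops, columns=["chrom", "start1", "end1", "start2", "end2", "planted_cluster"]
    ).sort_values(["chrom", "start1", "start2"], kind="stable").reset_index(drop=True)
    seg_df = pd.DataFrame(segments, columns=["chrom", "start", "end", "state"])
    # drop duplicated/overlapping segment records, keep first (deterministic)
    seg_df = (
        seg_df.sort_values(["chrom", "start"], kind="stable")
        .drop_duplicates(subset=["chrom", "start"])
        .reset_index(drop=True)
    )
    planted = loop_df.pop("planted_cluster").to_numpy()
    return loop_df, seg_df, planted


def simulate_expression(
    n_genes: int,
    n_tissues: int,
    housekeeping_frac: float = 0.2,
    specific_tissues: int = 3,
    expressed_tpm: float = 50.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """TPM table across tissues with planted expression breadth.

    Housekeeping genes are expressed in every tissue, at a higher level
    (4x) than the tissue-specific genes, which are expressed in
    `specific_tissues` random tissues.  Returns the TPM table
    (genes x tissues) and the planted breadth per gene.
    """
    if n_tissues < 2:
        raise ValueError("n_tissues must be >= 2")
    rng = np.random.default_rng(seed)
    n_hk = int(round(housekeeping_frac * n_genes))
    tpm = np.zeros((n_genes, n_tissues))
    breadth = np.zeros(n_genes, dtype=int)
    for g in range(n_genes):
        if g < n_hk:
            on = np.arange(n_tissues)
            level = 4 * expressed_tpm
        else:
            on = rng.choice(n_tissues, size=min(specific_tissues, n_tissues), replace=False)
            level = expressed_tpm
        tpm[g, on] = level * rng.lognormal(0, 0.2, size=len(on))
        breadth[g] = len(on)
    if noise_sd > 0:
        tpm = np.maximum(tpm + rng.normal(0, noise_sd, tpm.shape), 0.0)
    df = pd.DataFrame(
        tpm,
        index=[f"gene{g}" for g in range(n_genes)],
        columns=[f"tissue{t}" for t in range(n_tissues)],
    )
    return df, breadth
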