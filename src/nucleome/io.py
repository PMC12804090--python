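"""Plain-text readers and writers for the formats the package exchanges.

All genomic coordinates are 0-based, half-open.  Contact matrices travel
as COO triplet TSV (bin1_id, bin2_id, count) next to a bin table; a dense
square TSV is also accepted for toy matrices.  Tracks are bedGraph,
intervals BED, loops BEDPE, segregation tables TSV (first column sample
id, header window ids), and structure populations a coordinate TSV with
a JSON geometry sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .contact import ContactMatrix
from .gam import SegregationTable
from .layout import GenomeLayout, make_genome
from .simdata import NuclearGeometry, StructurePopulation

__all__ = [
    "write_bin_table", "read_bin_table",
    "write_contacts_coo", "read_contacts_coo", "read_contacts_dense",
    "write_bedgraph", "read_bedgraph",
    "write_bed", "read_bed",
    "write_bedpe", "read_bedpe",
    "write_segregation", "read_segregation",
    "write_structures", "read_structures",
]


def write_bin_table(layout: GenomeLayout, path: str | Path) -> None:
    layout.bins.to_csv(path, sep="\t", index=False)


def read_bin_table(path: str | Path) -> GenomeLayout:
    bins = pd.read_csv(path, sep="\t")
    lengths: dict[str, int] = {}
    bin_size = int((bins["end"] - bins["start"]).max())
    for chrom, g in bins.groupby("chrom", sort=False):
        lengths[chrom] = int(g["end"].max())
    return make_genome(lengths, bin_size)


def write_contacts_coo(cm: ContactMatrix, path: str | Path) -> None:
    iu = np.triu_indices(cm.n_bins)
    c = cm.counts[iu]
    nz = c > 0
    pd.DataFrame({"bin1_id": iu[0][nz], "bin2_id": iu[1][nz], "count": c[nz]}).to_csv(
        path, sep="\t", index=False
    )


def read_contacts_coo(path: str | Path, layout: GenomeLayout) -> ContactMatrix:
    df = pd.read_csv(path, sep="\t")
    n = layout.n_bins
    counts = np.zeros((n, n))
    counts[df["bin1_id"], df["bin2_id"]] = df["count"]
    counts = np.triu(counts) + np.triu(counts, k=1).T
    return ContactMatrix(layout=layout, counts=counts)


def read_contacts_dense(path: str | Path, layout: GenomeLayout) -> ContactMatrix:
    counts = np.loadtxt(path, delimiter="\t")
    return ContactMatrix(layout=layout, counts=counts)


def write_bedgraph(layout: GenomeLayout, values: np.ndarray, path: str | Path) -> None:
    df = layout.bins.copy()
    df["value"] = values
    df.to_csv(path, sep="\t", index=False, header=False)


def read_bedgraph(path: str | Path, layout: GenomeLayout | None = None) -> pd.DataFrame | np.ndarray:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    if layout is None:
        return df
    vals = np.full(layout.n_bins, np.nan)
    for row in df.itertuples(index=False):
        vals[layout.bin_of(row.chrom, int(row.start))] = row.value
    return vals


def write_bed(df: pd.DataFrame, path: str | Path, cols: list[str] | None = None) -> None:
    cols = cols or [c for c in ("chrom", "start", "end", "label", "state") if c in df]
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path, names: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    base = ["chrom", "start", "end", "label"]
    df.columns = (names or base)[: df.shape[1]]
    return df


def write_bedpe(loops: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "chrom1": loops["chrom"], "start1": loops["start1"], "end1": loops["end1"],
            "chrom2": loops["chrom"], "start2": loops["start2"], "end2": loops["end2"],
        }
    )
    for extra in ("platform", "resolution"):
        if extra in loops:
            out[extra] = loops[extra]
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bedpe(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    names = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "platform", "resolution"]
    df.columns = names[: df.shape[1]]
    df = df.rename(columns={"chrom1": "chrom"}).drop(columns=[c for c in ("chrom2",) if c in df])
    return df


def write_segregation(seg: SegregationTable, path: str | Path) -> None:
    df = pd.DataFrame(seg.detection.astype(int), index=seg.sample_ids)
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def read_segregation(path: str | Path, layout: GenomeLayout) -> SegregationTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SegregationTable(
        layout=layout,
        detection=df.to_numpy().astype(bool),
        sample_ids=[str(s) for s in df.index],
    )


def write_structures(pop: StructurePopulation, prefix: str | Path) -> None:
    """Coordinate TSV (structure, bead, x, y, z) + bead table + JSON sidecar."""
    prefix = Path(prefix)
    S, N, _ = pop.coords.shape
    s_idx = np.repeat(np.arange(S), N)
    b_idx = np.tile(np.arange(N), S)
    flat = pop.coords.reshape(-1, 3)
    pd.DataFrame(
        {"structure": s_idx, "bead": b_idx, "x": flat[:, 0], "y": flat[:, 1], "z": flat[:, 2]}
    ).to_csv(prefix.with_suffix(".coords.tsv"), sep="\t", index=False)
    pd.DataFrame({"bead": np.arange(N), "bin": pop.bead_bin, "allele": pop.bead_allele}).to_csv(
        prefix.with_suffix(".beads.tsv"), sep="\t", index=False
    )
    sidecar = {
        "geometry": {"a": pop.geometry.a, "b": pop.geometry.b, "c": pop.geometry.c,
                     "bead_radius": pop.geometry.bead_radius},
        "n_structures": S,
        "n_beads": N,
        "speckles": [s.tolist() for s in pop.speckles],
        "nucleoli": [s.tolist() for s in pop.nucleoli],
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_structures(prefix: str | Path, layout: GenomeLayout) -> StructurePopulation:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    coords_df = pd.read_csv(prefix.with_suffix(".coords.tsv"), sep="\t")
    beads = pd.read_csv(prefix.with_suffix(".beads.tsv"), sep="\t")
    S, N = meta["n_structures"], meta["n_beads"]
    coords = coords_df[["x", "y", "z"]].to_numpy().reshape(S, N, 3)
    g = meta["geometry"]
    return StructurePopulation(
        layout=layout,
        geometry=NuclearGeometry(g["a"], g["b"], g["c"], g["bead_radius"]),
        coords=coords,
        bead_bin=beads["bin"].to_numpy(),
        bead_allele=beads["allele"].to_numpy(),
        speckles=[np.asarray(s) for s in meta.get("speckles", [])],
        nucleoli=[np.asarray(s) for s in meta.get("nucleoli", [])],
    )
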