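"""Binned genome representation shared by every module.

A :class:`GenomeLayout` carries the chromosome table and the derived bin
table (0-based, half-open intervals).  Bin ids are global: ordered by
chromosome, then by start.  The last bin of each chromosome may be short.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeLayout", "make_genome"]


@dataclass(frozen=True)
class GenomeLayout:
    chroms: tuple[str, ...]
    lengths: tuple[int, ...]
    bin_size: int
    bins: pd.DataFrame = field(repr=False)           # columns: chrom, start, end
    bin_chrom: np.ndarray = field(repr=False)        # int chrom index per bin
    chrom_offsets: np.ndarray = field(repr=False)    # first bin id per chrom, +sentinel

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def n_chroms(self) -> int:
        return len(self.chroms)

    def chrom_slice(self, chrom: str | int) -> slice:
        """Global-bin slice covering one chromosome."""
        c = chrom if isinstance(chrom, int) else self.chroms.index(chrom)
        return slice(int(self.chrom_offsets[c]), int(self.chrom_offsets[c + 1]))

    def bin_starts(self) -> np.ndarray:
        return self.bins["start"].to_numpy()

    def bin_mids(self) -> np.ndarray:
        return ((self.bins["start"] + self.bins["end"]) // 2).to_numpy()

    def bin_of(self, chrom: str, pos: int) -> int:
        """Global bin id containing position `pos` on `chrom`."""
        c = self.chroms.index(chrom)
        if not 0 <= pos < self.lengths[c]:
            raise ValueError(f"position {pos} outside {chrom}")
        return int(self.chrom_offsets[c]) + pos // self.bin_size

    def same_chrom(self) -> np.ndarray:
        """Boolean (n_bins, n_bins) matrix of cis bin pairs."""
        return self.bin_chrom[:, None] == self.bin_chrom[None, :]


def make_genome(
    lengths: list[int] | tuple[int, ...] | dict[str, int],
    bin_size: int,
    names: list[str] | None = None,
) -> GenomeLayout:
    """Build a deterministic binned genome layout.

    Parameters
    ----------
    lengths
        Chromosome lengths in bp, or a mapping name -> length.
    bin_size
        Bin width in bp; the final bin of each chromosome is truncated.
    """
    if isinstance(lengths, dict):
        names = list(lengths.keys())
        lengths = list(lengths.values())
    lengths = [int(x) for x in lengths]
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if any(l <= 0 for l in lengths):
        raise ValueError("chromosome lengths must be positive")
    if names is None:
        names = [f"chr{i + 1}" for i in range(len(lengths))]
    if len(names) != len(lengths):
        raise ValueError("names and lengths disagree")

    rows = []
    bin_chrom = []
    offsets = [0]
    for c, (name, length) in enumerate(zip(names, lengths)):
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        rows.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
        bin_chrom.append(np.full(len(starts), c, dtype=np.int64))
        offsets.append(offsets[-1] + len(starts))
    bins = pd.concat(rows, ignore_index=True)
    return GenomeLayout(
        chroms=tuple(names),
        lengths=tuple(lengths),
        bin_size=int(bin_size),
        bins=bins,
        bin_chrom=np.concatenate(bin_chrom),
        chrom_offsets=np.asarray(offsets, dtype=np.int64),
    )
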