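"""Fixed-width genomic binning.

The whole toolkit operates on a grid of adjacent, non-overlapping bins
(default 100 bp). Coordinates are 0-based half-open throughout; bin ``i``
of a chromosome covers ``[i*bin_size, min((i+1)*bin_size, length))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomeBins:
    """A genome-wide grid of fixed-width bins.

    Parameters
    ----------
    chrom_lengths:
        Mapping chromosome name -> length in bp. Chromosome order is the
        insertion order of this mapping and defines the flattened bin order.
    bin_size:
        Bin width in bp (default 100).
    """

    chrom_lengths: dict[str, int]
    bin_size: int = 100

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length")

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.chrom_lengths[chrom] / self.bin_size)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chrom_lengths)

    def bin_of(self, pos: int) -> int:
        """Bin index containing a 0-based position."""
        return pos // self.bin_size

    def bin_interval(self, chrom: str, idx: int) -> tuple[int, int]:
        """Half-open [start, end) of a bin, clipped at the chromosome end."""
        if not 0 <= idx < self.n_bins(chrom):
            raise IndexError(f"bin {idx} out of range for {chrom}")
        start = idx * self.bin_size
        return start, min(start + self.bin_size, self.chrom_lengths[chrom])

    def same_grid(self, other: "GenomeBins") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.chrom_lengths == other.chrom_lengths
        )
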