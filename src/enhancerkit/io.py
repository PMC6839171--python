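"""Plain-text format adapters: BED, bedGraph, chrom-sizes, expression TSV.

All intervals are 0-based half-open. Parsers raise errors that name the
offending file and line number.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GenomeBins
from .signal import BinnedTrack


class FormatError(ValueError):
    pass


def read_chrom_sizes(path: str) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{i}: expected 2 columns")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError:
                raise FormatError(f"{path}:{i}: length is not an integer") from None
    return sizes


def read_bed(path: str, min_cols: int = 3) -> pd.DataFrame:
    """Read a BED file into a DataFrame (chrom, start, end, [name, score, ...])."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < min_cols:
                raise FormatError(
                    f"{path}:{i}: expected at least {min_cols} columns, got {len(parts)}"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
            except (ValueError, IndexError):
                raise FormatError(f"{path}:{i}: malformed coordinates") from None
            if end <= start:
                raise FormatError(f"{path}:{i}: end must exceed start")
            rows.append([parts[0], start, end] + parts[3:])
    ncols = max((len(r) for r in rows), default=3)
    names = ["chrom", "start", "end", "name", "score", "strand"][:ncols]
    names += [f"col{j}" for j in range(len(names), ncols)]
    df = pd.DataFrame([r + [None] * (ncols - len(r)) for r in rows], columns=names)
    return df


def write_bed(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph_track(path: str, bins: GenomeBins, mark: str) -> BinnedTrack:
    """Load a 4-column bedGraph of binned values onto a bin grid.

    Each row's value is assigned to every bin it overlaps; rows aligned to
    the grid (the format this package writes) therefore round-trip exactly.
    """
    track = BinnedTrack.zeros(bins, mark)
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{i}: expected 4 columns")
            chrom = parts[0]
            if chrom not in bins.chrom_lengths:
                continue
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError:
                raise FormatError(f"{path}:{i}: malformed bedGraph row") from None
            first = bins.bin_of(start)
            last = bins.bin_of(max(start, end - 1))
            last = min(last, bins.n_bins(chrom) - 1)
            track.values[chrom][first : last + 1] = value
    return track


def write_bedgraph_track(track: BinnedTrack, path: str, skip_zero: bool = True) -> None:
    with open(path, "w") as fh:
        for chrom in track.bins.chroms:
            vals = track.values[chrom]
            for idx in range(len(vals)):
                v = vals[idx]
                if skip_zero and v == 0:
                    continue
                start, end = track.bins.bin_interval(chrom, idx)
                fh.write(f"{chrom}\t{start}\t{end}\t{v:g}\n")


def read_expression_tsv(path: str) -> pd.DataFrame:
    """Expression table: first column gene id, remaining columns samples."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected gene column plus at least one sample")
    return df.set_index(df.columns[0])
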