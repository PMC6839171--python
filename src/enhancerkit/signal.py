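"""Per-bin signal tracks: read counting, normalization, quantile mapping.

The classifier consumes three histone-mark tracks (H3K27ac, H3K4me1,
H3K4me3) plus an input/control track. Raw read counts per 100-bp bin are
input-normalized as ``log2(t+1) - log2(c+1)``; an additional
H3K4me1/H3K4me3 log-ratio track is derived after shifting both
input-normalized distributions to be non-negative. Before prediction,
input-normalized values are quantile-normalized to the distributions of
the data the model was trained on, which makes the classifier transferable
across samples of very different sequencing depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .genome import GenomeBins

log = logging.getLogger(__name__)

MARKS = ("H3K27ac", "H3K4me1", "H3K4me3")


@dataclass
class BinnedTrack:
    """One real value per genomic bin, stored per chromosome."""

    bins: GenomeBins
    mark: str
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom in self.bins.chroms:
            if chrom not in self.values:
                raise ValueError(f"track missing chromosome {chrom!r}")
            n = self.bins.n_bins(chrom)
            if len(self.values[chrom]) != n:
                raise ValueError(
                    f"{chrom}: expected {n} bins, got {len(self.values[chrom])}"
                )

    @classmethod
    def zeros(cls, bins: GenomeBins, mark: str, dtype=float) -> "BinnedTrack":
        return cls(
            bins, mark, {c: np.zeros(bins.n_bins(c), dtype=dtype) for c in bins.chroms}
        )

    def flat(self) -> np.ndarray:
        """All values concatenated in chromosome order."""
        return np.concatenate([self.values[c] for c in self.bins.chroms])

    def min(self) -> float:
        return float(self.flat().min())

    def total(self) -> float:
        return float(self.flat().sum())

    def with_values(self, values: dict[str, np.ndarray], mark: str | None = None):
        return BinnedTrack(self.bins, mark or self.mark, values)


@dataclass(frozen=True)
class QuantileReference:
    """Sorted subsample of a training distribution used as quantile target."""

    mark: str
    sorted_values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.sorted_values, dtype=float)
        if v.size == 0:
            raise ValueError("empty quantile reference")
        if np.any(np.diff(v) < 0):
            raise ValueError("reference values must be non-decreasing")
        object.__setattr__(self, "sorted_values", v)

    @classmethod
    def from_values(
        cls, values: np.ndarray, mark: str, size: int = 10_000
    ) -> "QuantileReference":
        """Summarize a distribution into ``size`` evenly spaced quantiles."""
        values = np.asarray(values, dtype=float)
        if values.size <= size:
            return cls(mark, np.sort(values))
        qs = np.linspace(0.0, 1.0, size)
        return cls(mark, np.quantile(values, qs))


def _check_grid(a: BinnedTrack, b: BinnedTrack) -> None:
    if not a.bins.same_grid(b.bins):
        raise ValueError("tracks are on different bin grids")


def bin_counts(
    alignments: str,
    bins: GenomeBins,
    mark: str = "signal",
    fragment_mode: bool = False,
) -> BinnedTrack:
    """Count aligned reads per bin from a SAM/BAM file.

    A read is assigned to the single bin containing its 5'-most aligned
    position (``reference_start`` on the forward strand, last aligned base
    on the reverse strand). Unmapped, secondary and supplementary records
    are skipped. With ``fragment_mode`` each properly paired fragment is
    counted once, at the midpoint of the template, using the first mate.
    Reads on chromosomes absent from ``bins`` are dropped with a logged
    count; if *every* mapped read is dropped the chromosome naming of the
    alignments and the bin grid do not overlap and an error is raised.
    """
    import pysam

    track = BinnedTrack.zeros(bins, mark)
    dropped = 0
    assigned = 0
    try:
        af = pysam.AlignmentFile(alignments)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read alignments from {alignments!r}: {exc}") from exc
    with af:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if fragment_mode:
                if not read.is_proper_pair or read.is_read2:
                    continue
                pos = read.reference_start + abs(read.template_length) // 2
            elif read.is_reverse:
                pos = read.reference_end - 1
            else:
                pos = read.reference_start
            chrom = read.reference_name
            if chrom not in bins.chrom_lengths:
                dropped += 1
                continue
            idx = min(bins.bin_of(pos), bins.n_bins(chrom) - 1)
            track.values[chrom][idx] += 1
            assigned += 1
    if dropped:
        log.warning("dropped %d reads on chromosomes absent from the bin grid", dropped)
    if dropped and not assigned:
        raise ValueError(
            "no overlap between alignment chromosomes and the bin grid "
            "(check chromosome naming)"
        )
    return track


def input_normalize(treatment: BinnedTrack, control: BinnedTrack) -> BinnedTrack:
    """log2 input normalization with pseudo-count 1: log2(t+1) - log2(c+1)."""
    _check_grid(treatment, control)
    out = {
        c: np.log2(treatment.values[c] + 1.0) - np.log2(control.values[c] + 1.0)
        for c in treatment.bins.chroms
    }
    return treatment.with_values(out)


def ratio_track(
    me1_norm: BinnedTrack,
    me3_norm: BinnedTrack,
    shift_me1: float | None = None,
    shift_me3: float | None = None,
) -> BinnedTrack:
    """log2 ratio of H3K4me1 over H3K4me3 after shifting both tracks to >= 0.

    Each input-normalized track is shifted by subtracting its genome-wide
    minimum so the minimum becomes 0; the ratio is then
    ``log2(me1'+1) - log2(me3'+1)``. Shifts computed at training time can be
    passed in so prediction uses identical constants; values that would fall
    below a stored shift are clipped at 0.
    """
    _check_grid(me1_norm, me3_norm)
    s1 = me1_norm.min() if shift_me1 is None else shift_me1
    s3 = me3_norm.min() if shift_me3 is None else shift_me3
    out = {}
    for c in me1_norm.bins.chroms:
        a = np.maximum(me1_norm.values[c] - s1, 0.0)
        b = np.maximum(me3_norm.values[c] - s3, 0.0)
        out[c] = np.log2(a + 1.0) - np.log2(b + 1.0)
    return me1_norm.with_values(out, mark="ratio")


def quantile_normalize(values: np.ndarray, reference: QuantileReference) -> np.ndarray:
    """Map input values onto the reference distribution by rank.

    The rank-r input value is replaced by the reference quantile at the same
    relative rank, with linear interpolation when the lengths differ and the
    average-rank convention for ties. Output order matches input order.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        return x.copy()
    ref = reference.sorted_values
    if ref.size == 1:
        return np.full_like(x, ref[0])
    ranks = rankdata(x, method="average")
    q = (ranks - 1.0) / (x.size - 1.0) if x.size > 1 else np.array([0.5])
    return np.interp(q, np.linspace(0.0, 1.0, ref.size), ref)


def quantile_normalize_track(
    track: BinnedTrack, reference: QuantileReference
) -> BinnedTrack:
    """Quantile-normalize a whole track genome-wide against a reference."""
    flat = quantile_normalize(track.flat(), reference)
    out, offset = {}, 0
    for c in track.bins.chroms:
        n = track.bins.n_bins(c)
        out[c] = flat[offset : offset + n]
        offset += n
    return track.with_values(out)


def input_normalize_marks(
    raw: dict[str, BinnedTrack], control: BinnedTrack
) -> dict[str, BinnedTrack]:
    """Input-normalize each mark of a sample against its control track."""
    return {m: input_normalize(t, control) for m, t in raw.items()}


def subsample_track(track: BinnedTrack, fraction: float, seed: int) -> BinnedTrack:
    """Binomially thin a raw count track to a fraction of its reads."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = {
        c: rng.binomial(track.values[c].astype(np.int64), fraction).astype(float)
        for c in track.bins.chroms
    }
    return track.with_values(out)
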