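"""Condition-specific enhancer calling by permutation testing.

Per-bin enhancer probabilities from all samples form a matrix
``A = (A_xi)`` (bins x samples), each sample belonging to one condition.
For every unordered condition pair the per-bin statistic

    T_x = (mu_C1 - mu_C2 - w0) / S_delta

is a weighted group-mean difference scaled by the pooled standard
deviation of the two groups; ``w0`` is the
minimum mean difference considered interesting (default 0.5, i.e. the
null is |mu_C1 - mu_C2| <= 0.5). Because replicate numbers are tiny, the
null distribution is obtained empirically: all matrix entries are
shuffled once and T recomputed per bin, so the smallest attainable
p-value is 1/(1 + number of bins). A bin is called more active in C1
than C2 if its own empirical p-value and those of its two neighbors on
each side are all <= P* (default 0.05) and the mean difference is
positive. Per-pair calls combine into an *activity pattern* over all
pairs; bins sharing a pattern within 2 kb merge into differential
regions, each carrying its lowest-p bin as peak.

No multiple-testing correction is applied beyond the raw empirical
threshold P*; see the methods note.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d

log = logging.getLogger(__name__)

EPS_POOLED_SD = 1e-8  # stands in for S_delta when a group has one member


@dataclass
class ProbabilityMatrix:
    """Bins x samples enhancer probabilities with a condition design.

    ``bins_meta`` has one row per matrix row with columns (chrom, bin, start).
    """

    A: np.ndarray
    samples: list[str]
    condition_of: dict[str, str]
    bins_meta: pd.DataFrame
    bin_size: int = 100

    def __post_init__(self) -> None:
        if self.A.ndim != 2 or self.A.shape[1] != len(self.samples):
            raise ValueError("matrix shape does not match sample list")
        missing = [s for s in self.samples if s not in self.condition_of]
        if missing:
            raise ValueError(f"samples without a condition: {missing}")
        if len(self.conditions) < 2:
            raise ValueError("need at least two conditions")
        if np.any((self.A < 0) | (self.A > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.condition_of[s], None)
        return list(seen)

    def columns_of(self, condition: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if self.condition_of[s] == condition]
        )

    @classmethod
    def from_tracks(
        cls, tracks: dict[str, "ProbabilityTrack"], condition_of: dict[str, str]
    ) -> "ProbabilityMatrix":
        """Assemble the matrix from per-sample genome-wide probability tracks."""
        samples = list(tracks)
        first = tracks[samples[0]]
        meta = []
        for chrom in first.bins.chroms:
            for idx in range(first.bins.n_bins(chrom)):
                meta.append((chrom, idx, idx * first.bins.bin_size))
        A = np.column_stack([tracks[s].flat("p_enhancer") for s in samples])
        return cls(
            A,
            samples,
            condition_of,
            pd.DataFrame(meta, columns=["chrom", "bin", "start"]),
            first.bins.bin_size,
        )


@dataclass
class PairTest:
    """Per-bin permutation-test results for one condition pair.

    The statistic is one-sided, so each unordered pair carries both ordered
    directions: ``p`` tests "more active in C1 than C2" and ``p_rev`` the
    reverse, both against nulls from the same global shuffle.
    """

    pair: tuple[str, str]
    w0: float
    T_true: np.ndarray
    mean_diff: np.ndarray  # mu_C1 - mu_C2 per bin
    p: np.ndarray
    p_rev: np.ndarray
    n_null: int


def _group_stats(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    n = rows.shape[1]
    mu = rows.mean(axis=1)
    var = rows.var(axis=1, ddof=1) if n > 1 else np.zeros(rows.shape[0])
    return mu, var, n


def _pooled_sd(var1, n1, var2, n2) -> np.ndarray:
    if n1 == 1 or n2 == 1:
        return np.full(np.broadcast(var1, var2).shape, EPS_POOLED_SD)
    s2 = ((n1 - 1) * var1 + (n2 - 1) * var2) / (n1 + n2 - 2) * (1 / n1 + 1 / n2)
    s = np.sqrt(s2)
    return np.maximum(s, EPS_POOLED_SD)


def _statistic_matrix(
    sub1: np.ndarray, sub2: np.ndarray, w0: float
) -> tuple[np.ndarray, np.ndarray]:
    mu1, var1, n1 = _group_stats(sub1)
    mu2, var2, n2 = _group_stats(sub2)
    s = _pooled_sd(var1, n1, var2, n2)
    diff = mu1 - mu2
    return (diff - w0) / s, diff


def test_statistic(A_row: np.ndarray, groups: tuple[np.ndarray, np.ndarray], w0: float) -> float:
    """The weighted, pooled-SD-scaled mean difference for a single bin.

    ``groups`` are index arrays into ``A_row`` for the two conditions. With a
    single-member group the pooled SD is replaced by a small positive
    constant (1e-8), making any difference beyond ``w0`` maximally extreme.
    """
    g1, g2 = (np.asarray(g) for g in groups)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    row = np.asarray(A_row, dtype=float)
    t, _ = _statistic_matrix(row[g1][None, :], row[g2][None, :], w0)
    return float(t[0])


def permutation_pvalues(
    matrix: ProbabilityMatrix,
    pair: tuple[str, str],
    w0: float = 0.5,
    seed: int = 0,
    rounds: int = 1,
) -> PairTest:
    """Empirical per-bin p-values for one condition pair.

    The null is built by globally shuffling all matrix entries and
    recomputing the statistic for every bin (``rounds`` shuffles give
    ``rounds * n_bins`` null values). p-values use the add-one convention
    ``(1 + #{T_null >= T_true}) / (1 + n_null)``, so the floor is
    ``1/(1 + n_null)``.
    """
    c1_cols = matrix.columns_of(pair[0])
    c2_cols = matrix.columns_of(pair[1])
    if c1_cols.size == 0 or c2_cols.size == 0:
        raise ValueError(f"no samples for one of {pair}")
    n_bins = matrix.A.shape[0]
    if n_bins < 2:
        raise ValueError("need at least two bins")
    T_true, diff = _statistic_matrix(matrix.A[:, c1_cols], matrix.A[:, c2_cols], w0)
    T_rev, _ = _statistic_matrix(matrix.A[:, c2_cols], matrix.A[:, c1_cols], w0)
    rng = np.random.default_rng(seed)
    null_fwd, null_rev = [], []
    for _ in range(rounds):
        shuffled = rng.permutation(matrix.A.ravel()).reshape(matrix.A.shape)
        t_f, _ = _statistic_matrix(shuffled[:, c1_cols], shuffled[:, c2_cols], w0)
        t_r, _ = _statistic_matrix(shuffled[:, c2_cols], shuffled[:, c1_cols], w0)
        null_fwd.append(t_f)
        null_rev.append(t_r)

    def empirical(null_parts: list[np.ndarray], t_true: np.ndarray) -> np.ndarray:
        null = np.sort(np.concatenate(null_parts))
        exceed = null.size - np.searchsorted(null, t_true, side="left")
        return (1.0 + exceed) / (1.0 + null.size)

    p = empirical(null_fwd, T_true)
    p_rev = empirical(null_rev, T_rev)
    return PairTest(pair, w0, T_true, diff, p, p_rev, len(null_fwd) * n_bins)


def pair_seed(seed: int, pair_index: int) -> int:
    """Deterministic sub-seed for the pair's shuffle, kept below 2**31."""
    return int(np.random.SeedSequence([seed, pair_index]).generate_state(1)[0] % (2**31))


def all_pair_tests(
    matrix: ProbabilityMatrix, w0: float = 0.5, seed: int = 0, rounds: int = 1
) -> list[PairTest]:
    """Permutation tests for every unordered condition pair."""
    pairs = condition_pairs(matrix.conditions)
    return [
        permutation_pvalues(matrix, pair, w0, pair_seed(seed, k), rounds)
        for k, pair in enumerate(pairs)
    ]


def condition_pairs(conditions: list[str]) -> list[tuple[str, str]]:
    return list(itertools.combinations(conditions, 2))


def enumerate_patterns(n_conditions: int) -> list[tuple[tuple[int, int], ...]]:
    """All informative activity patterns for ``n_conditions``.

    Each unordered pair takes one of {(1,0), (0,1), (0,0)}; the all-(0,0)
    pattern carries no differential information and is excluded, leaving
    ``3**C(n,2) - 1`` patterns.
    """
    if n_conditions < 2:
        raise ValueError("need at least two conditions")
    n_pairs = n_conditions * (n_conditions - 1) // 2
    states = [(1, 0), (0, 1), (0, 0)]
    return [
        p
        for p in itertools.product(states, repeat=n_pairs)
        if any(s != (0, 0) for s in p)
    ]


def assign_patterns(
    tests: list[PairTest],
    bins_meta: pd.DataFrame,
    pstar: float = 0.05,
) -> np.ndarray:
    """Per-bin activity pattern over all condition pairs.

    For each pair, a bin gets (1,0) if the empirical p-values of the bin
    and its two neighbors on each side are all <= ``pstar`` and the C1 mean
    exceeds the C2 mean; (0,1) for the opposite sign; (0,0) otherwise.
    The five-bin window never crosses a chromosome boundary: bins without
    two neighbors on both sides fail the condition. Returns an int8 array
    (n_bins, n_pairs) coded 0=(0,0), 1=(1,0), 2=(0,1).
    """
    n_bins = len(bins_meta)
    codes = np.zeros((n_bins, len(tests)), dtype=np.int8)
    chrom_codes, chrom_index = pd.factorize(bins_meta["chrom"])
    for j, t in enumerate(tests):
        for direction, pvals, code in ((1, t.p, 1), (2, t.p_rev, 2)):
            sig = np.zeros(n_bins, dtype=bool)
            for ci in range(len(chrom_index)):
                rows = np.flatnonzero(chrom_codes == ci)
                pmax = maximum_filter1d(pvals[rows], size=5, mode="constant", cval=np.inf)
                sig[rows] = pmax <= pstar
            want_sign = t.mean_diff > 0 if code == 1 else t.mean_diff < 0
            codes[sig & want_sign, j] = code
    return codes


@dataclass(frozen=True)
class DifferentialRegion:
    chrom: str
    start: int
    end: int
    pattern: tuple[int, ...]  # per-pair codes 0/1/2
    peak_bin: int
    peak_p: float

    @property
    def pattern_string(self) -> str:
        return ",".join({0: "00", 1: "10", 2: "01"}[c] for c in self.pattern)


def build_regions(
    tests: list[PairTest],
    bins_meta: pd.DataFrame,
    codes: np.ndarray,
    merge_gap: int = 2000,
    bin_size: int = 100,
) -> list[DifferentialRegion]:
    """Merge patterned bins into differential regions.

    Bins sharing the same non-zero pattern within ``merge_gap`` of one
    another merge into a region whose peak is its lowest-p bin (the p-value
    of a bin is the minimum over its significant pairs). Overlapping
    regions of different patterns are combined and labeled with the
    pattern of the lower peak p-value.
    """
    nonzero = np.flatnonzero((codes != 0).any(axis=1))
    if nonzero.size == 0:
        return []
    # direction-appropriate p per (bin, pair): p of the ordered test that fired
    p_stack = np.full(codes.shape, np.inf)
    for j, t in enumerate(tests):
        fwd, rev = codes[:, j] == 1, codes[:, j] == 2
        p_stack[fwd, j] = t.p[fwd]
        p_stack[rev, j] = t.p_rev[rev]
    chrom_arr = bins_meta["chrom"].to_numpy()
    start_arr = bins_meta["start"].to_numpy()
    bin_arr = bins_meta["bin"].to_numpy()
    groups: dict[tuple[str, tuple[int, ...]], list[int]] = {}
    for r in nonzero:
        key = (chrom_arr[r], tuple(int(c) for c in codes[r]))
        groups.setdefault(key, []).append(int(r))
    regions: list[DifferentialRegion] = []
    for (chrom, pattern), rows in groups.items():
        rows = sorted(rows, key=lambda r: start_arr[r])
        starts = np.array([start_arr[r] for r in rows])
        sig_cols = np.flatnonzero(np.array(pattern) != 0)
        block_start = 0
        for k in range(1, len(rows) + 1):
            if k == len(rows) or starts[k] - (starts[k - 1] + bin_size) > merge_gap:
                block = rows[block_start:k]
                block_p = p_stack[np.ix_(block, sig_cols)].min(axis=1)
                best = int(np.argmin(block_p))
                regions.append(
                    DifferentialRegion(
                        chrom,
                        int(starts[block_start]),
                        int(starts[k - 1] + bin_size),
                        pattern,
                        int(bin_arr[block[best]]),
                        float(block_p[best]),
                    )
                )
                block_start = k
    return _resolve_overlaps(regions)


def _resolve_overlaps(regions: list[DifferentialRegion]) -> list[DifferentialRegion]:
    out: list[DifferentialRegion] = []
    by_chrom: dict[str, list[DifferentialRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda r: r.start)
        current = ordered[0]
        for r in ordered[1:]:
            if r.start < current.end:  # overlap: combine, keep lower peak p
                winner = current if current.peak_p <= r.peak_p else r
                current = DifferentialRegion(
                    chrom,
                    min(current.start, r.start),
                    max(current.end, r.end),
                    winner.pattern,
                    winner.peak_bin,
                    winner.peak_p,
                )
            else:
                out.append(current)
                current = r
        out.append(current)
    return out
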