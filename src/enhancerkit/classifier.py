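"""Two-tier random-forest enhancer prediction.

Enhancers carry a characteristic chromatin anatomy: an accessible center
flanked by nucleosomes marked with H3K4me1 and H3K27ac, while active
promoters additionally carry H3K4me3. The predictor captures this with a
window of ``2N+1`` adjacent 100-bp bins (N=5, i.e. 1100 bp) and two binary
random forests of M=100 trees each:

* classifier 1 separates *active* regions (enhancers + active promoters)
  from inactive ones using H3K27ac alone (11 features);
* classifier 2 separates enhancers from active promoters using H3K27ac,
  H3K4me1, H3K4me3 and the H3K4me1/H3K4me3 ratio (44 features).

The final per-bin enhancer probability is the product

    P(bin = active enhancer) = P(bin = active) * P(bin = enhancer | active),

so promoters, which score high on classifier 1 but low on classifier 2,
are suppressed. Genome-wide probabilities are summarized into
non-overlapping 1100-bp peaks by a greedy sweep over supra-threshold
bins, and peaks within 12.5 kb are optionally merged into clusters
(super-enhancer-like groups).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .genome import GenomeBins
from .signal import (
    BinnedTrack,
    QuantileReference,
    quantile_normalize_track,
    ratio_track,
)
from .training import POSITIVE_LABELS, LabeledRegion

log = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

MARKS_C1 = ("H3K27ac",)
MARKS_C2 = ("H3K27ac", "H3K4me1", "H3K4me3", "ratio")


@dataclass(frozen=True)
class FeatureSpec:
    """Feature geometry: N flanking bins on each side of the center bin."""

    n_flank: int = 5
    bin_size: int = 100

    @property
    def window_bins(self) -> int:
        return 2 * self.n_flank + 1

    def n_features(self, task: str) -> int:
        marks = MARKS_C1 if task == "classifier1" else MARKS_C2
        return len(marks) * self.window_bins


@dataclass
class ProbabilityTrack:
    """Per-bin probabilities from both classifiers and their product."""

    bins: GenomeBins
    p_active: dict[str, np.ndarray]
    p_enh_given_active: dict[str, np.ndarray]
    p_enhancer: dict[str, np.ndarray]

    def flat(self, which: str = "p_enhancer") -> np.ndarray:
        d = getattr(self, which)
        return np.concatenate([d[c] for c in self.bins.chroms])


@dataclass
class EnhancerModel:
    """Trained two-classifier bundle plus the normalization state.

    Quantile references and ratio shifts captured at training time are part
    of the model so prediction-time normalization reproduces training-time
    normalization exactly.
    """

    forest_active: RandomForestClassifier
    forest_enh_vs_prom: RandomForestClassifier
    n_trees: int
    feature_spec: FeatureSpec
    quantile_refs: dict[str, QuantileReference]
    shifts: dict[str, float]
    provenance: dict = field(default_factory=dict)

    def save(self, path: str) -> None:
        joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": self}, path)

    @classmethod
    def load(cls, path: str) -> "EnhancerModel":
        payload = joblib.load(path)
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"incompatible model archive (format {payload.get('format_version')}, "
                f"expected {MODEL_FORMAT_VERSION})"
            )
        return payload["model"]


@dataclass(frozen=True)
class EnhancerPeak:
    chrom: str
    start: int
    end: int
    summit_bin: int
    summit_prob: float

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def _window_matrix(values: np.ndarray, centers: np.ndarray, n_flank: int) -> np.ndarray:
    """Rows of values[center-N .. center+N], zero-padded at chromosome ends."""
    padded = np.pad(values, n_flank)
    idx = centers[:, None] + np.arange(2 * n_flank + 1)[None, :]
    return padded[idx]


def build_features(
    tracks: dict[str, BinnedTrack],
    centers: list[tuple[str, int]],
    spec: FeatureSpec,
    task: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix for center bins: marks concatenated in fixed order.

    Returns ``(X, edge_flag)`` where ``edge_flag`` marks rows whose window
    ran off a chromosome end and was zero-padded.
    """
    marks = MARKS_C1 if task == "classifier1" else MARKS_C2
    for m in marks:
        if m not in tracks:
            raise ValueError(f"missing track for mark {m!r} (task {task})")
    bins = tracks[marks[0]].bins
    n = len(centers)
    X = np.empty((n, spec.n_features(task)))
    edge = np.zeros(n, dtype=bool)
    by_chrom: dict[str, list[int]] = {}
    for row, (chrom, idx) in enumerate(centers):
        if not 0 <= idx < bins.n_bins(chrom):
            raise IndexError(f"center bin {idx} out of range on {chrom}")
        by_chrom.setdefault(chrom, []).append(row)
    w = spec.window_bins
    for chrom, rows in by_chrom.items():
        rows = np.asarray(rows)
        cbins = np.asarray([centers[r][1] for r in rows])
        n_bins = bins.n_bins(chrom)
        edge[rows] = (cbins < spec.n_flank) | (cbins >= n_bins - spec.n_flank)
        for j, mark in enumerate(marks):
            X[rows, j * w : (j + 1) * w] = _window_matrix(
                tracks[mark].values[chrom], cbins, spec.n_flank
            )
    return X, edge


def _normalized_tracks_for_training(
    tracks: dict[str, BinnedTrack],
) -> tuple[dict[str, BinnedTrack], dict[str, float]]:
    shifts = {"H3K4me1": tracks["H3K4me1"].min(), "H3K4me3": tracks["H3K4me3"].min()}
    full = dict(tracks)
    full["ratio"] = ratio_track(
        tracks["H3K4me1"], tracks["H3K4me3"], shifts["H3K4me1"], shifts["H3K4me3"]
    )
    return full, shifts


def train(
    train_set_c1: list[LabeledRegion],
    train_set_c2: list[LabeledRegion],
    tracks: dict[str, BinnedTrack],
    spec: FeatureSpec | None = None,
    n_trees: int = 100,
    seed: int = 0,
    quantile_ref_size: int = 10_000,
) -> EnhancerModel:
    """Fit the two-forest model on input-normalized training tracks.

    ``tracks`` maps H3K27ac/H3K4me1/H3K4me3 to input-normalized tracks; the
    ratio track, its shifts and the quantile references are derived here and
    stored in the model. Forest hyperparameters other than the number of
    trees are library defaults, recorded in provenance.
    """
    spec = spec or FeatureSpec()
    full, shifts = _normalized_tracks_for_training(tracks)

    def fit(regions: list[LabeledRegion], task: str) -> RandomForestClassifier:
        centers = [(r.chrom, r.center_bin) for r in regions]
        X, _ = build_features(full, centers, spec, task)
        y = np.array([r.label in POSITIVE_LABELS[task] for r in regions], dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError(f"{task}: training set is single-class")
        forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        forest.fit(X, y)
        return forest

    refs = {
        m: QuantileReference.from_values(tracks[m].flat(), m, quantile_ref_size)
        for m in ("H3K27ac", "H3K4me1", "H3K4me3")
    }
    model = EnhancerModel(
        forest_active=fit(train_set_c1, "classifier1"),
        forest_enh_vs_prom=fit(train_set_c2, "classifier2"),
        n_trees=n_trees,
        feature_spec=spec,
        quantile_refs=refs,
        shifts=shifts,
        provenance={
            "seed": seed,
            "n_train_c1": len(train_set_c1),
            "n_train_c2": len(train_set_c2),
            "forest_params": RandomForestClassifier(n_estimators=n_trees).get_params(),
        },
    )
    return model


def _all_centers(bins: GenomeBins) -> list[tuple[str, int]]:
    return [(c, i) for c in bins.chroms for i in range(bins.n_bins(c))]


def predict(
    model: EnhancerModel,
    tracks: dict[str, BinnedTrack],
    normalize: bool = True,
) -> ProbabilityTrack:
    """Genome-wide enhancer probabilities for one sample.

    ``tracks`` are input-normalized marks; each is quantile-normalized to
    the model's training references (disable with ``normalize=False``),
    the ratio track is rebuilt with the stored shifts, and both forests
    are applied to every bin.
    """
    for m in ("H3K27ac", "H3K4me1", "H3K4me3"):
        if m not in tracks:
            raise ValueError(f"missing track for mark {m!r}")
    if normalize:
        tracks = {
            m: quantile_normalize_track(tracks[m], model.quantile_refs[m])
            for m in ("H3K27ac", "H3K4me1", "H3K4me3")
        }
    full = dict(tracks)
    full["ratio"] = ratio_track(
        tracks["H3K4me1"], tracks["H3K4me3"],
        model.shifts["H3K4me1"], model.shifts["H3K4me3"],
    )
    bins = tracks["H3K27ac"].bins
    centers = _all_centers(bins)
    X1, _ = build_features(full, centers, model.feature_spec, "classifier1")
    X2, _ = build_features(full, centers, model.feature_spec, "classifier2")
    p1 = model.forest_active.predict_proba(X1)[:, 1]
    p2 = model.forest_enh_vs_prom.predict_proba(X2)[:, 1]
    pa, pc, pe, offset = {}, {}, {}, 0
    for c in bins.chroms:
        n = bins.n_bins(c)
        pa[c] = p1[offset : offset + n]
        pc[c] = p2[offset : offset + n]
        pe[c] = pa[c] * pc[c]
        offset += n
    return ProbabilityTrack(bins, pa, pc, pe)


def train_single_forest(
    train_set: list[LabeledRegion],
    tracks: dict[str, BinnedTrack],
    spec: FeatureSpec | None = None,
    n_trees: int = 100,
    seed: int = 0,
) -> RandomForestClassifier:
    """One combined forest (enhancer vs. everything else) on the full
    four-mark feature set — the flat alternative to the two-tier model,
    kept for head-to-head comparisons."""
    spec = spec or FeatureSpec()
    full, _ = _normalized_tracks_for_training(tracks)
    centers = [(r.chrom, r.center_bin) for r in train_set]
    X, _ = build_features(full, centers, spec, "classifier2")
    y = np.array([r.label == "enhancer" for r in train_set], dtype=int)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(X, y)
    return forest


def predict_single_forest(
    forest: RandomForestClassifier,
    tracks: dict[str, BinnedTrack],
    spec: FeatureSpec | None = None,
) -> dict[str, np.ndarray]:
    spec = spec or FeatureSpec()
    full, _ = _normalized_tracks_for_training(tracks)
    bins = tracks["H3K27ac"].bins
    centers = _all_centers(bins)
    X, _ = build_features(full, centers, spec, "classifier2")
    p = forest.predict_proba(X)[:, 1]
    out, offset = {}, 0
    for c in bins.chroms:
        n = bins.n_bins(c)
        out[c] = p[offset : offset + n]
        offset += n
    return out


def call_peaks(
    prob: ProbabilityTrack, threshold: float = 0.5, flank: int = 5
) -> list[EnhancerPeak]:
    """Greedy non-overlapping peak calling on the enhancer-probability track.

    Bins with probability >= ``threshold`` are sorted by descending
    probability (ties: lower genomic coordinate first) and each emits a
    window of the center bin +/- ``flank`` bins (1100 bp at defaults);
    any later candidate whose window overlaps an emitted window is
    discarded. Returns a probability-sorted list of peaks carrying their
    summit bin and summit probability.
    """
    candidates = []
    for ci, chrom in enumerate(prob.bins.chroms):
        p = prob.p_enhancer[chrom]
        for idx in np.flatnonzero(p >= threshold):
            candidates.append((-p[idx], ci, int(idx)))
    candidates.sort()
    occupied = {c: np.zeros(prob.bins.n_bins(c), dtype=bool) for c in prob.bins.chroms}
    peaks = []
    for negp, ci, idx in candidates:
        chrom = prob.bins.chroms[ci]
        n_bins = prob.bins.n_bins(chrom)
        lo = max(0, idx - flank)
        hi = min(n_bins, idx + flank + 1)
        if occupied[chrom][lo:hi].any():
            continue
        occupied[chrom][lo:hi] = True
        start = lo * prob.bins.bin_size
        end = min(hi * prob.bins.bin_size, prob.bins.chrom_lengths[chrom])
        peaks.append(EnhancerPeak(chrom, start, end, idx, float(-negp)))
    return peaks


def cluster_peaks(
    peaks: list[EnhancerPeak], max_gap: int = 12_500
) -> tuple[list[list[EnhancerPeak]], list[EnhancerPeak]]:
    """Single-linkage merge of peaks whose edge-to-edge gap is <= ``max_gap``.

    Returns ``(clusters, singletons)``; clusters have >= 2 members.
    """
    by_chrom: dict[str, list[EnhancerPeak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    clusters, singletons = [], []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda p: p.start)
        group = [ordered[0]]
        for p in ordered[1:]:
            if p.start - group[-1].end <= max_gap:
                group.append(p)
            else:
                (clusters if len(group) > 1 else singletons).extend(
                    [group] if len(group) > 1 else group
                )
                group = [p]
        (clusters if len(group) > 1 else singletons).extend(
            [group] if len(group) > 1 else group
        )
    return clusters, singletons


def spatial_resolution(
    peaks: list[EnhancerPeak],
    open_regions: "pd.DataFrame",
    max_distance: int = 1000,
) -> float:
    """Median distance from peak centers to the nearest accessible region.

    ``open_regions`` is a BED-like frame; a ``summit`` column, when present,
    is the reference point, otherwise the nearest interval boundary is used.
    Peaks farther than ``max_distance`` from any open region are excluded.
    Returns NaN (with a warning) when every peak is excluded.
    """
    import pandas as pd  # noqa: F811

    if not peaks or len(open_regions) == 0:
        raise ValueError("peaks and open_regions must be non-empty")
    has_summit = "summit" in open_regions.columns
    refs_by_chrom: dict[str, np.ndarray] = {}
    for chrom, g in open_regions.groupby("chrom"):
        if has_summit:
            pts = g["summit"].to_numpy(dtype=float)
        else:
            pts = np.concatenate([g["start"].to_numpy(float), g["end"].to_numpy(float)])
        refs_by_chrom[chrom] = np.sort(pts)
    dists = []
    for p in peaks:
        pts = refs_by_chrom.get(p.chrom)
        if pts is None:
            continue
        d = float(np.min(np.abs(pts - p.center)))
        if d <= max_distance:
            dists.append(d)
    if not dists:
        log.warning("all peaks farther than %d bp from open regions", max_distance)
        return float("nan")
    return float(np.median(dists))
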