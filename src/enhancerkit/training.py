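"""Curation of labeled training regions.

Training regions fall into five classes — enhancer, active promoter,
inactive promoter, intragenic and intergenic background — and the two
classifiers draw stratified samples with fixed genome-like composition:
classifier 1 (active vs. inactive regions) uses 10% enhancers, 5% active
promoters, 5% inactive promoters, 10% intragenic and 70% intergenic
regions (1000 total by default); classifier 2 (enhancer vs. active
promoter) uses 2/3 enhancers and 1/3 active promoters (150 total).

Enhancer candidates (e.g. bidirectional-transcription calls) are
re-centered on chromatin-accessibility peaks, and promoters are labeled
active/inactive from per-replicate FPKM values at their TSS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeBins

log = logging.getLogger(__name__)

LABELS = ("enhancer", "active_promoter", "inactive_promoter", "intragenic", "intergenic")

# stratified composition per classifier: label -> fraction
COMPOSITION_C1 = {
    "enhancer": 0.10,
    "active_promoter": 0.05,
    "inactive_promoter": 0.05,
    "intragenic": 0.10,
    "intergenic": 0.70,
}
COMPOSITION_C2 = {"enhancer": 2.0 / 3.0, "active_promoter": 1.0 / 3.0}

POSITIVE_LABELS = {
    "classifier1": {"enhancer", "active_promoter"},
    "classifier2": {"enhancer"},
}


@dataclass(frozen=True)
class LabeledRegion:
    chrom: str
    start: int
    end: int
    label: str
    center_bin: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @classmethod
    def at_position(
        cls, chrom: str, pos: int, label: str, bins: GenomeBins
    ) -> "LabeledRegion":
        """The single bin containing ``pos``, labeled."""
        idx = bins.bin_of(pos)
        start, end = bins.bin_interval(chrom, idx)
        return cls(chrom, start, end, label, idx)


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def curate_enhancers(
    candidates: pd.DataFrame, accessibility_peaks: pd.DataFrame, bins: GenomeBins
) -> list[LabeledRegion]:
    """Re-center enhancer candidates on accessibility peaks.

    Each candidate is centered on the midpoint of the accessibility peak it
    overlaps most (ties broken toward the leftmost peak); candidates without
    any overlapping peak are discarded.
    """
    if len(candidates) == 0:
        log.warning("empty enhancer candidate set")
        return []
    out = []
    peaks_by_chrom = {
        c: g.sort_values("start").reset_index(drop=True)
        for c, g in accessibility_peaks.groupby("chrom")
    }
    for cand in candidates.itertuples(index=False):
        peaks = peaks_by_chrom.get(cand.chrom)
        if peaks is None:
            continue
        best, best_ov = None, 0
        for p in peaks.itertuples(index=False):
            ov = _overlap(cand.start, cand.end, p.start, p.end)
            if ov > best_ov:
                best, best_ov = p, ov
        if best is None:
            continue
        center = (best.start + best.end) // 2
        out.append(LabeledRegion.at_position(cand.chrom, center, "enhancer", bins))
    return out


def label_promoters(
    tss: pd.DataFrame,
    expression: pd.DataFrame,
    accessibility_peaks: pd.DataFrame,
    bins: GenomeBins,
    active_fpkm: float = 2.0,
) -> list[LabeledRegion]:
    """Label promoter bins active or inactive from FPKM at the TSS.

    ``tss`` has columns (gene, chrom, pos); ``expression`` is gene x replicate
    FPKM. A promoter is *active* if FPKM > ``active_fpkm`` in every replicate
    and its 100-bp TSS bin overlaps an accessibility peak; *inactive* if FPKM
    is 0 in every replicate. Genes with intermediate expression in any
    replicate are excluded from both classes.
    """
    peaks_by_chrom = {c: g[["start", "end"]].to_numpy() for c, g in accessibility_peaks.groupby("chrom")}
    out = []
    for row in tss.itertuples(index=False):
        if row.gene not in expression.index:
            log.warning("gene %s has a TSS but no expression; skipped", row.gene)
            continue
        if row.chrom not in bins.chrom_lengths:
            continue
        fpkm = expression.loc[row.gene].to_numpy(dtype=float)
        region = LabeledRegion.at_position(row.chrom, row.pos, "intergenic", bins)
        if np.all(fpkm > active_fpkm):
            peaks = peaks_by_chrom.get(row.chrom)
            if peaks is not None and np.any(
                (peaks[:, 0] < region.end) & (peaks[:, 1] > region.start)
            ):
                out.append(
                    LabeledRegion(
                        region.chrom, region.start, region.end,
                        "active_promoter", region.center_bin,
                    )
                )
        elif np.all(fpkm == 0):
            out.append(
                LabeledRegion(
                    region.chrom, region.start, region.end,
                    "inactive_promoter", region.center_bin,
                )
            )
    return out


def _largest_remainder(fracs: dict[str, float], n_total: int) -> dict[str, int]:
    raw = {k: f * n_total for k, f in fracs.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n_total - sum(counts.values())
    if short:
        log.info("composition rounded by largest remainder (%d leftover)", short)
        by_rem = sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)
        for k in by_rem[:short]:
            counts[k] += 1
    return counts


def assemble_training_set(
    pool: list[LabeledRegion],
    task: str,
    n_total: int | None = None,
    seed: int = 0,
) -> list[LabeledRegion]:
    """Draw a stratified training sample with the fixed class composition.

    ``task`` is ``"classifier1"`` or ``"classifier2"``; sampling is without
    replacement and reproducible by seed.
    """
    if task == "classifier1":
        comp, n_total = COMPOSITION_C1, n_total or 1000
    elif task == "classifier2":
        comp, n_total = COMPOSITION_C2, n_total or 150
    else:
        raise ValueError(f"unknown task {task!r}")
    counts = _largest_remainder(comp, n_total)
    by_label: dict[str, list[LabeledRegion]] = {}
    for r in pool:
        by_label.setdefault(r.label, []).append(r)
    rng = np.random.default_rng(seed)
    sample: list[LabeledRegion] = []
    for label, n in counts.items():
        avail = by_label.get(label, [])
        if len(avail) < n:
            raise ValueError(
                f"training pool has only {len(avail)} {label!r} regions, need {n}"
            )
        idx = rng.choice(len(avail), size=n, replace=False)
        sample.extend(avail[i] for i in idx)
    return sample


def train_test_split_regions(
    pool: list[LabeledRegion], test_fraction: float, seed: int
) -> tuple[list[LabeledRegion], list[LabeledRegion]]:
    """Disjoint train/test partition of a region pool, stratified by label."""
    rng = np.random.default_rng(seed)
    train, test = [], []
    by_label: dict[str, list[LabeledRegion]] = {}
    for r in pool:
        by_label.setdefault(r.label, []).append(r)
    for regions in by_label.values():
        perm = rng.permutation(len(regions))
        n_test = int(round(test_fraction * len(regions)))
        test.extend(regions[i] for i in perm[:n_test])
        train.extend(regions[i] for i in perm[n_test:])
    return train, test
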