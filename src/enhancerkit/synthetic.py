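"""Synthetic multi-condition ChIP-seq / RNA-seq genomes with planted truth.

The generator emulates the data structures the rest of the toolkit
consumes, at desk scale (default 2 chromosomes x 1 Mb at 100-bp bins):

* background read noise per bin drawn from a negative-binomial
  (gamma-Poisson) model, exercising depth normalization;
* planted enhancers: bimodal Gaussian-profile enrichment of H3K4me1 and
  H3K27ac at +/- 200 bp around an accessible center (the
  nucleosome-flanked anatomy the 11-bin feature window targets), with no
  added signal at the center itself;
* planted promoters: central H3K4me3 + H3K27ac enrichment, active or
  silent;
* a condition design with replicates — condition-specific enhancers add
  signal only in samples of their active condition;
* TADs tiling the genome, and gene expression counts whose means scale
  with the activity of the planted enhancer sharing their TAD, plus
  condition-independent decoy genes.

Every draw flows from a single seed, so a fixed ``SimConfig`` reproduces
byte-identical tracks, truth tables and counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeBins
from .signal import BinnedTrack
from .training import LabeledRegion

_KINDS = ("enhancer", "active_promoter", "inactive_promoter")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic genome."""

    chrom_lengths: tuple[tuple[str, int], ...] = (("chr1", 1_000_000), ("chr2", 1_000_000))
    bin_size: int = 100
    conditions: tuple[str, ...] = ("cond1", "cond2")
    replicates: int = 2
    n_shared_enhancers: int = 60
    n_specific_enhancers: int = 25  # per condition
    n_active_promoters: int = 60
    n_inactive_promoters: int = 60
    background_rate: float = 5.0  # expected reads per 100-bp bin
    enhancer_strength: float = 8.0  # peak enrichment over background
    flank_offset: int = 200  # bp from element center to each signal bump
    signal_sd: float = 150.0  # bp, width of each Gaussian bump
    dispersion: float = 0.1  # NB overdispersion (var = mu + disp*mu^2)
    min_separation: int = 5_000  # bp between planted element centers
    tad_size: int = 100_000
    n_decoy_genes: int = 40
    expression_base_mean: float = 200.0
    expression_effect: float = 4.0  # fold boost of a target gene when active
    seed: int = 0

    @property
    def bins(self) -> GenomeBins:
        return GenomeBins(dict(self.chrom_lengths), self.bin_size)

    @property
    def samples(self) -> list[str]:
        return [f"{c}_rep{r+1}" for c in self.conditions for r in range(self.replicates)]

    @property
    def condition_of(self) -> dict[str, str]:
        return {f"{c}_rep{r+1}": c for c in self.conditions for r in range(self.replicates)}


@dataclass
class SimResult:
    """Tracks, truth, TADs and expression for one synthetic genome."""

    cfg: SimConfig
    raw_tracks: dict[str, dict[str, BinnedTrack]]  # sample -> mark -> raw counts
    input_tracks: dict[str, BinnedTrack]  # sample -> control track
    truth: pd.DataFrame  # kind, chrom, center, active_in, strength
    tads: list  # of targets.TAD
    genes: pd.DataFrame | None = None  # gene, chrom, tss, start, end, target_of
    counts: pd.DataFrame | None = None  # gene x sample raw counts


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-12)
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam).astype(float)


def _place_elements(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw non-colliding element centers; rejection-sample until separated."""
    counts = {
        "enhancer_shared": cfg.n_shared_enhancers,
        **{f"enhancer_{c}": cfg.n_specific_enhancers for c in cfg.conditions},
        "active_promoter": cfg.n_active_promoters,
        "inactive_promoter": cfg.n_inactive_promoters,
    }
    n_total = sum(counts.values())
    chroms = [c for c, _ in cfg.chrom_lengths]
    lengths = np.array([l for _, l in cfg.chrom_lengths], dtype=float)
    margin = 2 * cfg.flank_offset + 1_000
    placed: dict[str, list[int]] = {c: [] for c in chroms}
    rows = []
    labels = [k for k, n in counts.items() for _ in range(n)]
    rng.shuffle(labels)
    for label in labels:
        for _ in range(10_000):
            ci = rng.integers(len(chroms))
            chrom = chroms[ci]
            pos = int(rng.integers(margin, int(lengths[ci]) - margin))
            pos = (pos // cfg.bin_size) * cfg.bin_size + cfg.bin_size // 2
            if all(abs(pos - q) >= cfg.min_separation for q in placed[chrom]):
                placed[chrom].append(pos)
                break
        else:
            raise ValueError(
                f"cannot place {n_total} elements with min_separation="
                f"{cfg.min_separation} on this genome"
            )
        if label.startswith("enhancer"):
            kind = "enhancer"
            active = list(cfg.conditions) if label == "enhancer_shared" else [label[9:]]
        elif label == "active_promoter":
            kind, active = "active_promoter", list(cfg.conditions)
        else:
            kind, active = "inactive_promoter", []
        rows.append(
            {
                "kind": kind,
                "chrom": chrom,
                "center": pos,
                "active_in": ",".join(active),
                "strength": cfg.enhancer_strength,
            }
        )
    cols = ["kind", "chrom", "center", "active_in", "strength"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["chrom", "center"]).reset_index(drop=True)


def _bump_profile(
    bins: GenomeBins, chrom: str, center: int, offsets: list[int], sd: float, amp: float
) -> np.ndarray:
    """Expected added reads per bin for Gaussian bumps at center+offsets."""
    n = bins.n_bins(chrom)
    starts = np.arange(n) * bins.bin_size + bins.bin_size / 2.0
    prof = np.zeros(n)
    for off in offsets:
        prof += amp * np.exp(-0.5 * ((starts - (center + off)) / sd) ** 2)
    return prof


def simulate_tracks(cfg: SimConfig) -> SimResult:
    """Generate raw per-sample histone-mark and input tracks plus truth.

    Enhancers active in a sample's condition add bimodal H3K4me1 + H3K27ac
    enrichment flanking their center; active promoters add central
    H3K4me3 + H3K27ac; inactive promoters add nothing. Input tracks carry
    background only.
    """
    from .targets import TAD

    rng = np.random.default_rng(cfg.seed)
    bins = cfg.bins
    truth = _place_elements(cfg, rng)

    # per-mark expected-signal templates per condition
    amp = cfg.enhancer_strength * cfg.background_rate
    cond_means: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    for cond in cfg.conditions:
        marks = {
            m: {c: np.full(bins.n_bins(c), cfg.background_rate) for c in bins.chroms}
            for m in ("H3K27ac", "H3K4me1", "H3K4me3")
        }
        for el in truth.itertuples(index=False):
            active = cond in el.active_in.split(",") if el.active_in else False
            if el.kind == "enhancer" and active:
                bump = _bump_profile(
                    bins, el.chrom, el.center,
                    [-cfg.flank_offset, cfg.flank_offset], cfg.signal_sd, amp,
                )
                marks["H3K4me1"][el.chrom] += bump
                marks["H3K27ac"][el.chrom] += bump
            elif el.kind == "active_promoter" and active:
                bump = _bump_profile(bins, el.chrom, el.center, [0], cfg.signal_sd, amp)
                marks["H3K4me3"][el.chrom] += bump
                marks["H3K27ac"][el.chrom] += bump
        cond_means[cond] = marks

    raw_tracks: dict[str, dict[str, BinnedTrack]] = {}
    input_tracks: dict[str, BinnedTrack] = {}
    for sample in cfg.samples:
        cond = cfg.condition_of[sample]
        raw_tracks[sample] = {}
        for mark in ("H3K27ac", "H3K4me1", "H3K4me3"):
            vals = {
                c: _nb_counts(rng, cond_means[cond][mark][c], cfg.dispersion)
                for c in bins.chroms
            }
            raw_tracks[sample][mark] = BinnedTrack(bins, mark, vals)
        input_tracks[sample] = BinnedTrack(
            bins,
            "input",
            {
                c: _nb_counts(
                    rng, np.full(bins.n_bins(c), cfg.background_rate), cfg.dispersion
                )
                for c in bins.chroms
            },
        )

    tads = [
        TAD(chrom, s, min(s + cfg.tad_size, length), f"tad_{chrom}_{s // cfg.tad_size}")
        for chrom, length in cfg.chrom_lengths
        for s in range(0, length, cfg.tad_size)
    ]
    return SimResult(cfg, raw_tracks, input_tracks, truth, tads)


def activity_vector(el_active_in: str, cfg: SimConfig) -> np.ndarray:
    """Per-sample 0/1 activity of an element from its ``active_in`` field."""
    active = set(el_active_in.split(",")) if el_active_in else set()
    return np.array(
        [1.0 if cfg.condition_of[s] in active else 0.0 for s in cfg.samples]
    )


def simulate_expression(result: SimResult) -> SimResult:
    """Add gene models and an expression count matrix to a simulation.

    Every planted enhancer gets a target gene with its TSS placed elsewhere
    in the same TAD; the gene's expected count scales with the enhancer's
    per-condition activity by ``expression_effect``. Decoy genes have
    condition-independent means. Counts are negative-binomial.
    """
    cfg = result.cfg
    rng = np.random.default_rng(cfg.seed + 1)
    genes, mean_rows = [], []
    enhancers = result.truth[result.truth["kind"] == "enhancer"].reset_index(drop=True)
    tads_by_chrom: dict[str, list] = {}
    for t in result.tads:
        tads_by_chrom.setdefault(t.chrom, []).append(t)
    for i, el in enumerate(enhancers.itertuples(index=False)):
        tad = next(
            t for t in tads_by_chrom[el.chrom] if t.contains(el.chrom, el.center)
        )
        # TSS placed in the same TAD, away from the enhancer center
        for _ in range(1000):
            tss = int(rng.integers(tad.start + 500, tad.end - 500))
            if abs(tss - el.center) > 2_000:
                break
        gene = f"gene_target_{i}"
        genes.append(
            {
                "gene": gene, "chrom": el.chrom, "tss": tss,
                "start": tss, "end": min(tss + 10_000, tad.end),
                "target_of": f"{el.chrom}:{el.center}",
            }
        )
        act = activity_vector(el.active_in, cfg)
        mean_rows.append(cfg.expression_base_mean * (1.0 + cfg.expression_effect * act))
    chroms = [c for c, _ in cfg.chrom_lengths]
    lengths = dict(cfg.chrom_lengths)
    for i in range(cfg.n_decoy_genes):
        chrom = chroms[rng.integers(len(chroms))]
        tss = int(rng.integers(1_000, lengths[chrom] - 11_000))
        genes.append(
            {
                "gene": f"gene_decoy_{i}", "chrom": chrom, "tss": tss,
                "start": tss, "end": tss + 10_000, "target_of": "",
            }
        )
        mean_rows.append(np.full(len(cfg.samples), cfg.expression_base_mean))
    means = np.vstack(mean_rows)
    counts = _nb_counts(rng, means, cfg.dispersion).astype(int)
    result.genes = pd.DataFrame(genes)
    result.counts = pd.DataFrame(
        counts, index=[g["gene"] for g in genes], columns=cfg.samples
    )
    return result


def training_pool_from_truth(
    result: SimResult,
    n_background: int = 2_000,
    seed: int = 0,
) -> list[LabeledRegion]:
    """Build a five-class labeled-region pool from the planted truth.

    Planted elements provide the enhancer/promoter classes; intragenic and
    intergenic background bins are sampled at least 1 kb away from any
    planted element (and inside/outside gene bodies respectively when gene
    models exist).
    """
    cfg = result.cfg
    bins = cfg.bins
    rng = np.random.default_rng(seed)
    pool = [
        LabeledRegion.at_position(el.chrom, el.center, el.kind, bins)
        for el in result.truth.itertuples(index=False)
    ]
    element_pos = {
        c: result.truth[result.truth["chrom"] == c]["center"].to_numpy()
        for c in bins.chroms
    }
    gene_spans: dict[str, np.ndarray] = {}
    if result.genes is not None:
        for c, g in result.genes.groupby("chrom"):
            gene_spans[c] = g[["start", "end"]].to_numpy()
    chroms = bins.chroms
    n_each = n_background // 2
    for label in ("intragenic", "intergenic"):
        added = 0
        for _ in range(200_000):
            if added >= n_each:
                break
            chrom = chroms[rng.integers(len(chroms))]
            pos = int(rng.integers(0, bins.chrom_lengths[chrom]))
            if np.any(np.abs(element_pos[chrom] - pos) < 1_000):
                continue
            spans = gene_spans.get(chrom)
            inside = spans is not None and bool(
                np.any((spans[:, 0] <= pos) & (pos < spans[:, 1]))
            )
            if (label == "intragenic") != inside:
                continue
            pool.append(LabeledRegion.at_position(chrom, pos, label, bins))
            added += 1
        if added < n_each:
            raise ValueError(f"could not sample enough {label} background bins")
    return pool


def match_peaks(
    peaks: list,
    truth: pd.DataFrame,
    condition: str | None = None,
    tol_bp: int = 200,
) -> tuple[float, float]:
    """Recall and precision of called peaks against planted enhancer centers.

    A planted enhancer counts as recovered if some peak center lies within
    ``tol_bp`` of it; a peak is a true positive if it recovers any planted
    enhancer. ``condition`` restricts the truth to enhancers active there.
    """
    enh = truth[truth["kind"] == "enhancer"]
    if condition is not None:
        enh = enh[enh["active_in"].str.split(",").apply(lambda a: condition in a)]
    centers = {c: g["center"].to_numpy() for c, g in enh.groupby("chrom")}
    n_truth = len(enh)
    hit = {c: np.zeros(len(v), dtype=bool) for c, v in centers.items()}
    tp = 0
    for p in peaks:
        pts = centers.get(p.chrom)
        if pts is None or pts.size == 0:
            continue
        d = np.abs(pts - p.center)
        if d.min() <= tol_bp:
            hit[p.chrom][np.argmin(d)] = True
            tp += 1
    recall = sum(h.sum() for h in hit.values()) / n_truth if n_truth else float("nan")
    precision = tp / len(peaks) if peaks else float("nan")
    return float(recall), float(precision)


def match_differential_regions(
    regions: list,
    truth: pd.DataFrame,
    cfg: SimConfig,
    tol_bp: int = 1_000,
) -> float:
    """Sensitivity of differential-region calls for condition-specific
    planted enhancers: fraction whose center lies within ``tol_bp`` of a
    region with the correct direction for at least one affected pair."""
    specific = truth[
        (truth["kind"] == "enhancer")
        & (truth["active_in"] != ",".join(cfg.conditions))
        & (truth["active_in"] != "")
    ]
    n_spec = len(specific)
    if n_spec == 0:
        return float("nan")
    from .dynamics import condition_pairs

    pairs = condition_pairs(list(cfg.conditions))
    recovered = 0
    for el in specific.itertuples(index=False):
        active = set(el.active_in.split(","))
        ok = False
        for r in regions:
            if r.chrom != el.chrom:
                continue
            mid_ok = r.start - tol_bp <= el.center <= r.end + tol_bp
            if not mid_ok:
                continue
            for j, (c1, c2) in enumerate(pairs):
                code = r.pattern[j]
                if code == 1 and c1 in active and c2 not in active:
                    ok = True
                if code == 2 and c2 in active and c1 not in active:
                    ok = True
            if ok:
                break
        recovered += ok
    return recovered / n_spec
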