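"""Feature construction, two-forest prediction, peak calling, clustering."""

import numpy as np
import pandas as pd
import pytest

import enhancerkit as ek
from enhancerkit.classifier import (
    EnhancerModel,
    EnhancerPeak,
    FeatureSpec,
    build_features,
    call_peaks,
    cluster_peaks,
    spatial_resolution,
    train,
)
from enhancerkit.signal import BinnedTrack, input_normalize_marks

from conftest import make_probability_track


def brute_force_peaks(p, threshold=0.5, flank=5):
    """Independent greedy oracle: sorted candidates, O(n^2) overlap scan."""
    cands = sorted(
        [(float(p[i]), int(i)) for i in np.flatnonzero(p >= threshold)],
        key=lambda t: (-t[0], t[1]),
    )
    accepted = []
    for prob, i in cands:
        lo, hi = i - flank, i + flank
        if all(hi < a_lo or lo > a_hi for _, a_lo, a_hi in accepted):
            accepted.append((i, lo, hi))
    return [i for i, _, _ in accepted]


@pytest.fixture
def tracks_1chrom():
    bins = ek.GenomeBins({"chr1": 5000}, bin_size=100)
    rng = np.random.default_rng(0)
    return {
        m: BinnedTrack(bins, m, {"chr1": rng.normal(size=50)})
        for m in ("H3K27ac", "H3K4me1", "H3K4me3", "ratio")
    }


class TestBuildFeatures:
    @pytest.mark.parametrize(
        "n_flank,task,ncols", [(5, "classifier1", 11), (5, "classifier2", 44),
                               (0, "classifier1", 1), (0, "classifier2", 4)]
    )
    def test_feature_dimensions(self, tracks_1chrom, n_flank, task, ncols):
        spec = FeatureSpec(n_flank=n_flank)
        X, _ = build_features(tracks_1chrom, [("chr1", 25)], spec, task)
        assert X.shape == (1, ncols)

    def test_edge_padding_flagged(self, tracks_1chrom):
        spec = FeatureSpec(n_flank=5)
        X, edge = build_features(tracks_1chrom, [("chr1", 2), ("chr1", 25)], spec, "classifier1")
        assert edge.tolist() == [True, False]
        # bins -3..-1 fall off the chromosome start and are zero
        np.testing.assert_array_equal(X[0, :3], 0.0)
        np.testing.assert_array_equal(
            X[0, 3:], tracks_1chrom["H3K27ac"].values["chr1"][0:8]
        )

    def test_missing_mark_raises(self, tracks_1chrom):
        del tracks_1chrom["ratio"]
        with pytest.raises(ValueError, match="ratio"):
            build_features(tracks_1chrom, [("chr1", 25)], FeatureSpec(), "classifier2")


class TestTrainPredict:
    def test_probability_product_identity(self, predictions):
        for prob in predictions.values():
            for chrom in prob.bins.chroms:
                np.testing.assert_allclose(
                    prob.p_enhancer[chrom],
                    prob.p_active[chrom] * prob.p_enh_given_active[chrom],
                )
                assert np.all((prob.p_enhancer[chrom] >= 0) & (prob.p_enhancer[chrom] <= 1))

    def test_seeded_training_reproducible(self, training_sets, train_marks, model):
        _, set1, set2 = training_sets
        again = train(set1, set2, train_marks, seed=3)
        for a, b in zip(
            model.forest_active.estimators_, again.forest_active.estimators_
        ):
            assert a.tree_.node_count == b.tree_.node_count

    def test_single_class_training_raises(self, training_sets, train_marks):
        _, set1, _ = training_sets
        enh_only = [r for r in set1 if r.label == "enhancer"]
        with pytest.raises(ValueError, match="single-class"):
            train(enh_only, enh_only, train_marks, seed=0)

    def test_single_tree_probabilities_coarse(self, training_sets, train_marks, sim_test):
        _, set1, set2 = training_sets
        m1 = train(set1, set2, train_marks, n_trees=1, seed=0)
        s = sim_test.cfg.samples[0]
        marks = input_normalize_marks(sim_test.raw_tracks[s], sim_test.input_tracks[s])
        prob = ek.predict(m1, marks)
        vals = prob.flat("p_active")
        assert set(np.unique(vals)) <= {0.0, 1.0}

    def test_model_roundtrip_and_version_guard(self, model, tmp_path):
        path = tmp_path / "model.joblib"
        model.save(str(path))
        loaded = EnhancerModel.load(str(path))
        assert loaded.n_trees == model.n_trees
        assert loaded.shifts == model.shifts
        import joblib

        joblib.dump({"format_version": 999, "model": None}, path)
        with pytest.raises(ValueError, match="incompatible"):
            EnhancerModel.load(str(path))

    def test_missing_mark_at_predict_raises(self, model, sim_test):
        s = sim_test.cfg.samples[0]
        marks = input_normalize_marks(sim_test.raw_tracks[s], sim_test.input_tracks[s])
        del marks["H3K4me3"]
        with pytest.raises(ValueError, match="H3K4me3"):
            ek.predict(model, marks)


class TestCallPeaks:
    def bins(self, n=100):
        return ek.GenomeBins({"chr1": n * 100}, bin_size=100)

    def test_single_bin_gives_1100bp_peak(self):
        bins = self.bins()
        p = np.zeros(100)
        p[50] = 0.9
        (peak,) = call_peaks(make_probability_track(bins, {"chr1": p}))
        assert peak.end - peak.start == 1100
        assert peak.summit_bin == 50
        assert peak.summit_prob == 0.9

    def test_nearby_lower_candidate_suppressed(self):
        bins = self.bins()
        p = np.zeros(100)
        p[50], p[53] = 0.9, 0.8
        peaks = call_peaks(make_probability_track(bins, {"chr1": p}))
        assert [pk.summit_bin for pk in peaks] == [50]

    def test_all_below_threshold_empty(self):
        bins = self.bins()
        peaks = call_peaks(make_probability_track(bins, {"chr1": np.full(100, 0.4)}))
        assert peaks == []

    def test_output_non_overlapping_and_sorted(self):
        bins = self.bins(500)
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, 500)
        peaks = call_peaks(make_probability_track(bins, {"chr1": p}))
        probs = [pk.summit_prob for pk in peaks]
        assert probs == sorted(probs, reverse=True)
        spans = sorted((pk.start, pk.end) for pk in peaks)
        assert all(a_end <= b_start for (_, a_end), (b_start, _) in zip(spans, spans[1:]))

    def test_matches_brute_force_oracle(self):
        bins = self.bins(2000)
        rng = np.random.default_rng(7)
        for _ in range(25):
            p = rng.uniform(0, 0.45, 2000)
            hot = rng.choice(2000, 60, replace=False)
            p[hot] = rng.uniform(0.5, 1.0, 60)
            peaks = call_peaks(make_probability_track(bins, {"chr1": p}))
            assert [pk.summit_bin for pk in peaks] == brute_force_peaks(p)


class TestClusterPeaks:
    def peak(self, start, prob=0.9):
        return EnhancerPeak("chr1", start, start + 1100, start // 100 + 5, prob)

    def test_within_12500_merged(self):
        clusters, singles = cluster_peaks([self.peak(0), self.peak(1100 + 12_400)])
        assert len(clusters) == 1 and len(clusters[0]) == 2 and not singles

    def test_beyond_12500_separate(self):
        clusters, singles = cluster_peaks([self.peak(0), self.peak(1100 + 13_000)])
        assert not clusters and len(singles) == 2

    def test_single_peak_is_singleton(self):
        clusters, singles = cluster_peaks([self.peak(0)])
        assert not clusters and len(singles) == 1


class TestSpatialResolution:
    def open_regions(self, summits):
        return pd.DataFrame(
            [("chr1", s - 50, s + 50, s) for s in summits],
            columns=["chrom", "start", "end", "summit"],
        )

    def peak_at(self, center):
        return EnhancerPeak("chr1", center - 550, center + 550, center // 100, 0.9)

    def test_exact_summit_contributes_zero(self):
        assert spatial_resolution([self.peak_at(5000)], self.open_regions([5000])) == 0

    def test_median_of_distances(self):
        peaks = [self.peak_at(5000 + d) for d in (100, 200, 300)]
        assert spatial_resolution(peaks, self.open_regions([5000])) == 200

    def test_far_peaks_excluded(self):
        peaks = [self.peak_at(5100), self.peak_at(30_000)]
        assert spatial_resolution(peaks, self.open_regions([5000])) == 100

    def test_all_excluded_gives_nan(self):
        assert np.isnan(
            spatial_resolution([self.peak_at(30_000)], self.open_regions([5000]))
        )


def test_planted_enhancer_recovery(predictions, sim_test):
    """Peaks recover planted enhancer centers within 200 bp at high precision."""
    from enhancerkit.synthetic import match_peaks

    for cond in sim_test.cfg.conditions:
        prob = predictions[f"{cond}_rep1"]
        recall, precision = match_peaks(call_peaks(prob), sim_test.truth, condition=cond)
        assert recall >= 0.9
        assert precision >= 0.9
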