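"""GFP, peak sampling, polarity-invariant clustering, backfitting, parameters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegfuse.microstate import (
    assign_canonical_labels,
    backfit,
    canonical_reference_maps,
    cluster_microstates,
    compute_parameters,
    find_gfp_peaks,
    gev_score,
    gfp,
    sample_peak_maps,
)
from eegfuse.synthetic import DEFAULT_CHANNELS_17, make_templates
from eegfuse.types import GFPSeries, Recording, Segmentation, TemplateSet


class TestGFP:
    def test_equal_channels_give_zero(self):
        rec = Recording("s", "HC", ["a", "b", "c"], 250.0,
                        np.full((3, 5), 3.7))
        assert np.allclose(gfp(rec).values, 0.0)

    def test_two_channel_hand_value(self):
        rec = Recording("s", "HC", ["a", "b"], 250.0,
                        np.array([[1.0], [-1.0]]))
        assert gfp(rec).values[0] == pytest.approx(1.0)

    def test_matches_population_std(self, rng):
        data = rng.standard_normal((17, 50))
        rec = Recording("s", "HC", [f"c{i}" for i in range(17)], 250.0, data)
        expected = np.sqrt(((data - data.mean(axis=0)) ** 2).sum(axis=0) / 17)
        assert np.allclose(gfp(rec).values, expected)

    def test_single_channel_rejected(self):
        rec = Recording("s", "HC", ["a"], 250.0, np.ones((1, 5)))
        with pytest.raises(ValueError):
            gfp(rec)


class TestPeaks:
    def test_enumerated_maxima(self):
        g = GFPSeries(np.array([0, 1, 0, 2, 0.0]), 250.0)
        assert set(find_gfp_peaks(g).tolist()) == {1, 3}

    def test_constant_series_has_no_peaks(self):
        g = GFPSeries(np.ones(100), 250.0)
        assert find_gfp_peaks(g).size == 0

    def test_rectified_carrier_peak_count(self):
        # |sin| at 10 Hz has two envelope humps per cycle -> 20 peaks in 1 s
        t = np.arange(250) / 250.0
        g = GFPSeries(np.abs(np.sin(2 * np.pi * 10 * t)), 250.0)
        assert find_gfp_peaks(g).size == 20


class TestSamplePeakMaps:
    def _rec(self, rng, n=4000):
        return Recording("s", "HC", [f"c{i}" for i in range(6)], 250.0,
                         rng.standard_normal((6, n)))

    def test_caps_at_available_peaks(self, rng):
        rec = self._rec(rng)
        peaks = np.arange(1, 801)
        maps = sample_peak_maps(rec, peaks, n_maps=1000, seed=0)
        assert maps.shape == (800, 6)

    def test_requested_count_and_zero_mean(self, rng):
        rec = self._rec(rng)
        peaks = np.arange(1, 1501)
        maps = sample_peak_maps(rec, peaks, n_maps=1000, seed=0)
        assert maps.shape == (1000, 6)
        assert np.allclose(maps.mean(axis=1), 0, atol=1e-12)

    def test_seed_determinism(self, rng):
        rec = self._rec(rng)
        peaks = np.arange(1, 1000)
        a = sample_peak_maps(rec, peaks, 100, seed=7)
        b = sample_peak_maps(rec, peaks, 100, seed=7)
        assert np.array_equal(a, b)

    def test_no_peaks_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_peak_maps(self._rec(rng), np.array([]), 10, seed=0)


class TestClustering:
    def test_noiseless_polarity_invariant_recovery(self, rng):
        gen = make_templates(17, 4, seed=3)
        signs = rng.choice([-1.0, 1.0], size=40)
        maps = gen[np.repeat(np.arange(4), 10)] * signs[:, None]
        ts = cluster_microstates(maps, k=4, n_restarts=10, seed=0)
        corr = np.abs(ts.maps @ gen.T)
        # each recovered template matches exactly one distinct generator
        assert np.allclose(np.sort(corr.max(axis=1)), 1.0, atol=1e-8)
        assert sorted(corr.argmax(axis=1).tolist()) == [0, 1, 2, 3]

    def test_best_restart_by_gev(self, rng):
        maps = rng.standard_normal((30, 8))
        ts, det = cluster_microstates(maps, k=4, n_restarts=8, seed=1,
                                      return_details=True)
        assert ts.gev >= max(det["restart_gevs"]) - 1e-12

    def test_gev_recomputation_oracle(self, rng):
        maps = rng.standard_normal((30, 8))
        maps -= maps.mean(axis=1, keepdims=True)
        ts, det = cluster_microstates(maps, k=4, n_restarts=5, seed=2,
                                      return_details=True)
        # brute-force re-evaluation, written independently with loops
        num = 0.0
        den = 0.0
        for x, a in zip(maps, det["assignments"]):
            num += float(np.dot(x, ts.maps[a])) ** 2
            den += float(np.dot(x, x))
        assert ts.gev == pytest.approx(num / den, abs=1e-10)

    def test_gev_monotone_within_restart(self, rng):
        maps = rng.standard_normal((60, 10))
        _, det = cluster_microstates(maps, k=4, n_restarts=3, seed=3,
                                     return_details=True)
        hist = det["gev_history"]
        assert all(b >= a - 1e-10 for a, b in zip(hist[:-1], hist[1:]))

    def test_too_few_maps_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_microstates(rng.standard_normal((3, 8)), k=4)


class TestCanonicalLabels:
    def test_shuffled_references_restored(self):
        refs = canonical_reference_maps(DEFAULT_CHANNELS_17)
        perm = [2, 0, 3, 1]
        ts = TemplateSet(refs[perm], ["1", "2", "3", "4"],
                         list(DEFAULT_CHANNELS_17))
        out = assign_canonical_labels(ts)
        assert out.labels == ["A", "B", "C", "D"]
        assert np.allclose(out.maps, refs, atol=1e-12)

    def test_polarity_invariance(self):
        refs = canonical_reference_maps(DEFAULT_CHANNELS_17)
        ts = TemplateSet(-refs[[1, 0, 3, 2]], ["1", "2", "3", "4"],
                         list(DEFAULT_CHANNELS_17))
        out = assign_canonical_labels(ts)
        assert np.allclose(np.abs(out.maps), np.abs(refs), atol=1e-12)

    def test_random_templates_bijective(self):
        maps = make_templates(17, 4, seed=9)
        ts = TemplateSet(maps, ["1", "2", "3", "4"], list(DEFAULT_CHANNELS_17))
        out = assign_canonical_labels(ts)
        assert out.labels == ["A", "B", "C", "D"]
        # output rows are a permutation of the input rows
        matches = np.abs(out.maps @ maps.T)
        assert sorted(matches.argmax(axis=1).tolist()) == [0, 1, 2, 3]

    def test_unknown_channels_fall_back(self):
        maps = make_templates(6, 4, seed=1)
        ts = TemplateSet(maps, ["1", "2", "3", "4"],
                         [f"x{i}" for i in range(6)])
        out = assign_canonical_labels(ts)
        assert out.labels == ["A", "B", "C", "D"]
        assert np.array_equal(out.maps, maps)


class TestBackfit:
    def _two_template_recording(self, block=100, n_blocks=10):
        gen = make_templates(8, 2, seed=5)
        labels = np.repeat(np.arange(n_blocks) % 2, block)
        data = gen[labels].T
        rec = Recording("s", "HC", [f"c{i}" for i in range(8)], 250.0, data)
        ts = TemplateSet(gen, ["A", "B"], rec.channel_names)
        return rec, ts, labels

    def test_single_template_single_segment(self):
        gen = make_templates(8, 2, seed=5)
        data = np.tile(gen[0][:, None], (1, 300))
        rec = Recording("s", "HC", [f"c{i}" for i in range(8)], 250.0, data)
        ts = TemplateSet(gen, ["A", "B"], rec.channel_names)
        seg = backfit(rec, ts)
        assert len(seg.segments) == 1 and seg.segments[0] == (0, 300, 0)

    def test_polarity_invariance(self):
        rec, ts, _ = self._two_template_recording()
        flipped = Recording(rec.subject_id, rec.group_label,
                            rec.channel_names, rec.sampling_rate, -rec.data)
        assert np.array_equal(backfit(rec, ts).labels,
                              backfit(flipped, ts).labels)

    def test_alternating_blocks_segment_lengths(self):
        rec, ts, labels = self._two_template_recording()
        seg = backfit(rec, ts)
        assert np.array_equal(seg.labels, labels)
        assert all(e - s == 100 for s, e, _ in seg.segments)
        f = compute_parameters(seg, n_classes=2)
        assert np.allclose(f.mean_duration_ms, 400.0)

    def test_amplitude_scale_invariance(self):
        rec, ts, _ = self._two_template_recording()
        scaled = Recording(rec.subject_id, rec.group_label,
                           rec.channel_names, rec.sampling_rate,
                           rec.data * 37.5)
        assert np.array_equal(backfit(rec, ts).labels,
                              backfit(scaled, ts).labels)

    def test_zero_variance_sample_carries_forward(self):
        rec, ts, labels = self._two_template_recording()
        rec.data[:, 150] = 5.0  # flat topography at one sample
        seg = backfit(rec, ts)
        assert seg.labels[150] == seg.labels[149]


class TestComputeParameters:
    def test_hand_enumerated_example(self):
        labels = np.concatenate([
            np.zeros(50), np.ones(50), np.zeros(50), np.ones(100),
        ]).astype(int)
        seg = Segmentation(labels=labels, sampling_rate=250.0)
        f = compute_parameters(seg, n_classes=4)
        assert f.coverage_fraction[0] == pytest.approx(0.4)
        assert f.occurrence_per_s[0] == pytest.approx(2.0)
        assert f.mean_duration_ms[0] == pytest.approx(200.0)
        # transitions: A->B twice, B->A once
        names = dict(zip(["AB", "AC", "AD", "BA", "BC", "BD",
                          "CA", "CB", "CD", "DA", "DB", "DC"],
                         f.transition_prob))
        assert names["AB"] == pytest.approx(1.0)
        assert names["BA"] == pytest.approx(1.0)

    def test_single_class(self):
        seg = Segmentation(labels=np.zeros(100, dtype=int), sampling_rate=250.0)
        f = compute_parameters(seg)
        assert f.coverage_fraction[0] == pytest.approx(1.0)
        assert np.all(f.transition_prob == 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_parameters(
                Segmentation(labels=np.array([], dtype=int),
                             sampling_rate=250.0)
            )

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 3), min_size=1, max_size=300))
    def test_coverage_sums_to_one_and_identity(self, raw):
        seg = Segmentation(labels=np.array(raw), sampling_rate=250.0)
        f = compute_parameters(seg)
        assert f.coverage_fraction.sum() == pytest.approx(1.0)
        prod = f.occurrence_per_s * f.mean_duration_ms / 1000.0
        assert np.allclose(prod, f.coverage_fraction, atol=1e-12)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 3), min_size=2, max_size=200))
    def test_outgoing_transitions_sum_to_one(self, raw):
        seg = Segmentation(labels=np.array(raw), sampling_rate=250.0)
        f = compute_parameters(seg)
        tp = np.zeros((4, 4))
        tp[~np.eye(4, dtype=bool)] = f.transition_prob
        sums = tp.sum(axis=1)
        for row_sum in sums:
            assert row_sum == pytest.approx(1.0) or row_sum == pytest.approx(0.0)


def test_gev_score_zero_for_empty_energy():
    assert gev_score(np.zeros((3, 4)), np.ones((2, 4)), np.zeros(3, dtype=int)) == 0.0
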