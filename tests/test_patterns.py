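"""Cell traces, spike-triggered averages, repeatability, perturbations."""

import numpy as np
import pytest

from astroca.dynamics import ParameterSet
from astroca.morphology import AVFMap, encode_template
from astroca.patterns import (
    ablate_region,
    activity_fraction_map,
    cellwise_traces,
    detect_spikes,
    flatten_avf,
    perturb_template,
    repeatability_score,
    spike_triggered_average,
    unlink_cells,
)
from astroca.solver import Recording, compile

from test_events import synthetic_recording


def labelled_recording(movie, labels, r=0.5, frame_dt=0.5, baseline=0.05):
    T, h, w = movie.shape
    rmap = np.where(labels > 0, r, 0.0)
    tpl = encode_template(AVFMap(r=rmap, pixel_size=1.0), labels)
    grid = compile(tpl, ParameterSet())
    ca = (movie + baseline).reshape(T, -1)[:, grid.mask_idx]
    return Recording(times=frame_dt * np.arange(T),
                     fields={"ca_c": ca.astype(np.float32),
                             "ip3": ca.astype(np.float32)},
                     grid=grid, params=ParameterSet())


class TestCellTraces:
    def test_single_domain_is_global_weighted_mean(self):
        labels = np.ones((4, 4), dtype=int)
        movie = np.random.default_rng(0).random((10, 4, 4))
        rec = labelled_recording(movie, labels)
        traces = cellwise_traces(rec, spike_threshold=10.0)
        assert len(traces) == 1
        # uniform r: AVF weighting reduces to the plain mean
        expected = rec.fields["ca_c"].mean(axis=1)
        assert np.allclose(traces[0].ca, expected, atol=1e-6)

    def test_constant_recording_no_spikes(self):
        labels = np.ones((3, 3), dtype=int)
        rec = labelled_recording(np.zeros((20, 3, 3)), labels)
        tr = cellwise_traces(rec, spike_threshold=0.5)[0]
        assert tr.spike_times.size == 0

    def test_three_pulses_three_spikes(self):
        labels = np.ones((3, 3), dtype=int)
        movie = np.zeros((100, 3, 3))
        for onset in (10, 40, 70):
            movie[onset:onset + 4] = 1.0
        rec = labelled_recording(movie, labels)
        tr = cellwise_traces(rec, spike_threshold=0.5)[0]
        assert tr.spike_times.size == 3
        assert np.allclose(tr.spike_times, [5.0, 20.0, 35.0])

    def test_avf_weighting(self):
        labels = np.ones((1, 2), dtype=int)
        rmap = np.array([[1.0, 0.5]])
        tpl = encode_template(AVFMap(r=rmap, pixel_size=1.0), labels)
        grid = compile(tpl, ParameterSet())
        ca = np.array([[1.0, 4.0]], dtype=np.float32)
        rec = Recording(times=np.array([0.0]), fields={"ca_c": ca, "ip3": ca},
                        grid=grid, params=ParameterSet())
        tr = cellwise_traces(rec, spike_threshold=10)[0]
        # weights proportional to r: (1*1 + 0.5*4) / 1.5 = 2
        # (up to red-channel quantization of r)
        assert tr.ca[0] == pytest.approx(2.0, abs=0.01)


class TestActivityFraction:
    def test_extremes_and_half(self):
        movie = np.zeros((10, 1, 3))
        movie[:, 0, 0] = 1.0          # always above
        movie[:5, 0, 1] = 1.0         # half the frames
        rec = synthetic_recording(movie, baseline=0.0)
        # baseline 0 would break detection but not this map
        rec.fields["ca_c"] = rec.fields["ca_c"] + 0.0
        amap = activity_fraction_map(rec, level=0.5)
        assert amap[0, 0] == 1.0
        assert amap[0, 1] == 0.5
        assert amap[0, 2] == 0.0


class TestSTA:
    def test_single_spike_average_is_that_window(self):
        rng = np.random.default_rng(1)
        raster = rng.random((100, 4))
        times = 0.5 * np.arange(100)
        sta, n = spike_triggered_average(raster, times,
                                         np.array([25.0]), window=10.0)
        assert n == 1
        i = 50 - 10  # centred 20-frame window
        assert np.allclose(sta, raster[i:i + 20])

    def test_fixed_lag_follower_peaks_at_lag(self):
        T = 2000
        times = 0.5 * np.arange(T)
        seed_spikes = np.arange(100.0, 900.0, 50.0)
        raster = np.zeros((T, 2))
        lag = 5.0
        for ts in seed_spikes:
            raster[int(ts / 0.5), 0] = 1.0
            raster[int((ts + lag) / 0.5), 1] = 1.0
        sta, n = spike_triggered_average(raster, times, seed_spikes,
                                         window=30.0)
        assert n == len(seed_spikes)
        peak_frame = sta[:, 1].argmax()
        assert (peak_frame - 30) * 0.5 == pytest.approx(lag, abs=0.5)
        assert sta[:, 1].max() == pytest.approx(1.0)

    def test_random_lag_follower_averages_down(self):
        """Unlocked follower amplitude shrinks like 1/n_spikes (impulses)."""
        rng = np.random.default_rng(2)
        T = 4000
        times = 0.5 * np.arange(T)
        seed_spikes = np.arange(100.0, 1900.0, 50.0)
        raster = np.zeros((T, 2))
        for ts in seed_spikes:
            raster[int(ts / 0.5), 0] = 1.0
            t_rand = rng.uniform(50.0, 1950.0)
            raster[int(t_rand / 0.5), 1] = 1.0
        sta, n = spike_triggered_average(raster, times, seed_spikes,
                                         window=30.0)
        assert sta[:, 1].max() <= 1.0 / np.sqrt(n) + raster[:, 1].mean() + 0.1

    def test_no_complete_window_rejected(self):
        raster = np.zeros((10, 1))
        times = 0.5 * np.arange(10)
        with pytest.raises(ValueError):
            spike_triggered_average(raster, times, np.array([0.0]), window=20.0)


class TestRepeatability:
    def make_cascade(self, deterministic=True, seed=0, n_spikes=14):
        """Raster movie where patch B follows patch A at a fixed lag."""
        rng = np.random.default_rng(seed)
        T, h, w = 1600, 6, 12
        movie = np.zeros((T, h, w))
        onsets = np.arange(100, 1500, 100)
        for t0 in onsets:
            movie[t0:t0 + 8, :, :6] = 1.0       # seed patch spikes
            if deterministic:
                movie[t0 + 10:t0 + 18, :, 6:] = 1.0
            else:
                tr = rng.integers(60, 1500)
                movie[tr:tr + 8, :, 6:] = 1.0
        return synthetic_recording(movie, pixel_size=1.0, baseline=0.05)

    def test_deterministic_cascade_scores_high(self):
        rec = self.make_cascade(deterministic=True)
        rmap = repeatability_score(rec, patch=6.0, stride=6.0, min_spikes=10,
                                   spike_level=0.5, window=40.0,
                                   point_level=0.2)
        assert rmap.patch_scores
        # every spike in A is followed by B: both patches light up in the
        # averaged window.  Maximum attainable for this geometry: 8 pulse
        # frames per patch out of an 80-frame window over 2 patches = 0.10
        assert max(rmap.patch_scores.values()) == pytest.approx(0.10,
                                                                abs=0.02)

    def test_uncorrelated_follower_scores_near_self_share(self):
        rec = self.make_cascade(deterministic=False)
        rmap = repeatability_score(rec, patch=6.0, stride=6.0, min_spikes=10,
                                   spike_level=0.5, window=40.0,
                                   point_level=0.2)
        det = repeatability_score(self.make_cascade(True), patch=6.0,
                                  stride=6.0, min_spikes=10,
                                  spike_level=0.5, window=40.0,
                                  point_level=0.2)
        assert max(rmap.patch_scores.values()) < max(det.patch_scores.values())

    def test_subthreshold_recording_empty_map(self):
        movie = np.zeros((200, 6, 6))
        rec = synthetic_recording(movie, baseline=0.05)
        rmap = repeatability_score(rec, patch=3.0, stride=3.0, min_spikes=1,
                                   spike_level=0.5)
        assert not rmap.patch_scores
        assert np.all(np.isnan(rmap.score))

    def test_score_invariant_to_nonseed_shuffling(self):
        """Scores depend on the raster content, not patch ordering."""
        rec = self.make_cascade(deterministic=True)
        a = repeatability_score(rec, patch=6.0, stride=6.0, min_spikes=10)
        b = repeatability_score(rec, patch=6.0, stride=6.0, min_spikes=10)
        assert a.patch_scores == b.patch_scores


class TestPerturbations:
    def two_cell_template(self):
        labels = np.zeros((4, 6), dtype=int)
        labels[:, :3] = 1
        labels[:, 3:] = 2
        rng = np.random.default_rng(0)
        r = np.where(labels > 0, rng.uniform(0.2, 0.9, labels.shape), 0.0)
        return encode_template(AVFMap(r=r, pixel_size=1.0), labels)

    def test_unlink_all_cells_removes_interdomain_edges(self, params):
        tpl = self.two_cell_template()
        grid = unlink_cells(tpl, params, cells=[1, 2])
        lab = grid.cell_labels
        i, j = grid.edges
        assert np.all(lab[i] == lab[j])
        full = compile(tpl, params)
        n_border = 4  # 4 rows crossing the column-3 boundary
        assert full.edges[0].size - grid.edges[0].size == n_border

    def test_unlink_missing_cell_rejected(self, params):
        with pytest.raises(ValueError):
            unlink_cells(self.two_cell_template(), params, cells=[9])

    def test_flatten_uniform_region_is_identity(self):
        labels = np.ones((3, 3), dtype=int)
        r = np.full((3, 3), 0.4)
        tpl = encode_template(AVFMap(r=r, pixel_size=1.0), labels)
        out = flatten_avf(tpl, np.ones((3, 3), dtype=bool))
        assert np.array_equal(out.rgb, tpl.rgb)

    def test_flatten_sets_regional_mean(self):
        tpl = self.two_cell_template()
        region = np.zeros((4, 6), dtype=bool)
        region[:, :3] = True
        from astroca.morphology import decode_template

        before, _ = decode_template(tpl)
        out = flatten_avf(tpl, region)
        after, _ = decode_template(out)
        assert np.allclose(after.r[region], before.r[region].mean(),
                           atol=1 / 255)
        assert np.array_equal(after.r[~region], before.r[~region])

    def test_ablate_reduces_mask_by_region_size(self):
        tpl = self.two_cell_template()
        region = np.zeros((4, 6), dtype=bool)
        region[1:3, 1:3] = True
        out = ablate_region(tpl, region)
        assert tpl.mask.sum() - out.mask.sum() == region.sum()
        assert np.all(out.domain_labels[region] == 0)

    def test_dispatcher(self, params):
        tpl = self.two_cell_template()
        grid = perturb_template(tpl, "unlink", params=params, cells=[1])
        assert grid.severed_cells == frozenset({1})
        with pytest.raises(ValueError):
            perturb_template(tpl, "bogus")
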