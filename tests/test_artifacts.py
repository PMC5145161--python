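"""Pre-sorting event rejection and post-sorting cluster flagging."""

import numpy as np
import pytest

from oracles import brute_concurrent_masks, brute_double_mask, brute_rate_mask
from spikeblocks.artifacts import (flag_artifact_cluster, mask_concurrent,
                                   mask_high_amplitude, mask_high_rate,
                                   reject_events, resolve_double_detections)
from spikeblocks.containers import SpikeSet
from spikeblocks.params import ArtifactParams

RATE = 24000.0


class TestHighRate:
    def test_overfull_bin_removed(self, rng):
        """101 events inside one 500 ms bin: rate cap is 100, all go."""
        times = np.sort(rng.uniform(100.0, 220.0, 101))
        keep = mask_high_rate(times)
        assert not keep.any()

    def test_exactly_100_events_kept(self, rng):
        times = np.sort(rng.uniform(2000.0, 2240.0, 100))
        keep = mask_high_rate(times)
        assert keep.all()

    def test_empty_input(self):
        assert mask_high_rate(np.empty(0)).size == 0

    def test_matches_bruteforce_on_random_grids(self, rng):
        p = ArtifactParams(rate_bin=50.0, rate_overlap=25.0, rate_max_events=5)
        for _ in range(200):
            n = rng.integers(0, 60)
            times = np.sort(rng.uniform(0, 400.0, n))
            keep = mask_high_rate(times, p)
            expect = brute_rate_mask(times, 50.0, 25.0, 5)
            np.testing.assert_array_equal(keep, expect)


class TestHighAmplitude:
    @pytest.mark.parametrize("peak,kept", [(1100.0, False), (1000.0, True),
                                           (100.0, True)])
    def test_threshold_is_strict(self, peak, kept):
        wave = np.zeros((1, 48))
        wave[0, 10] = peak
        assert mask_high_amplitude(wave)[0] == kept

    def test_negative_extremum_counts(self):
        wave = np.zeros((1, 48))
        wave[0, 10] = -1200.0
        assert not mask_high_amplitude(wave)[0]


class TestDoubleDetections:
    def waveset(self, maxima):
        waves = np.zeros((len(maxima), 8))
        waves[:, 3] = maxima
        return waves

    def test_close_pair_keeps_larger(self):
        keep = resolve_double_detections(np.array([10.0, 11.0]),
                                         self.waveset([50.0, 80.0]))
        np.testing.assert_array_equal(keep, [False, True])

    def test_distant_pair_kept(self):
        keep = resolve_double_detections(np.array([10.0, 12.0]),
                                         self.waveset([50.0, 80.0]))
        assert keep.all()

    def test_chain_matches_greedy_sweep(self):
        times = np.array([0.0, 1.0, 2.0])
        maxima = [50.0, 80.0, 60.0]
        keep = resolve_double_detections(times, self.waveset(maxima))
        expect = brute_double_mask(times, np.array(maxima))
        np.testing.assert_array_equal(keep, expect)
        np.testing.assert_array_equal(keep, [False, True, False])

    def test_random_chains_match_oracle(self, rng):
        for _ in range(200):
            n = rng.integers(0, 20)
            times = np.sort(rng.uniform(0, 20.0, n))
            maxima = rng.uniform(10, 100, n)
            keep = resolve_double_detections(times, self.waveset(maxima))
            np.testing.assert_array_equal(
                keep, brute_double_mask(times, maxima))


class TestConcurrent:
    def test_transient_on_half_the_channels_removed(self, rng):
        times = {f"c{i}": (np.array([500.0]) if i < 8 else np.empty(0))
                 for i in range(16)}
        keep = mask_concurrent(times)
        for i in range(8):
            assert not keep[f"c{i}"].any()

    def test_single_channel_event_kept(self):
        times = {f"c{i}": (np.array([500.0]) if i == 0 else np.empty(0))
                 for i in range(16)}
        keep = mask_concurrent(times)
        assert keep["c0"].all()

    def test_disabled_below_min_channels(self):
        times = {f"c{i}": np.array([500.0]) for i in range(6)}
        keep = mask_concurrent(times)
        assert all(m.all() for m in keep.values())

    def test_random_grids_match_oracle(self, rng):
        for _ in range(100):
            times = {f"c{i}": np.sort(rng.uniform(0, 60.0,
                                                  rng.integers(0, 15)))
                     for i in range(12)}
            keep = mask_concurrent(times)
            expect = brute_concurrent_masks(times)
            for c in times:
                np.testing.assert_array_equal(keep[c], expect[c])


class TestRejectionPipeline:
    def test_masks_never_reorder_survivors(self, rng):
        times = np.sort(rng.uniform(0, 1e4, 300))
        waves = rng.normal(0, 50, (300, 48))
        ss = SpikeSet(waves, times)
        report = reject_events({"ch0": ss})
        surv = times[report.keep("ch0")]
        assert np.all(np.diff(surv) >= 0)
        counts = report.removed_counts("ch0")
        for crit, mask in report.masks["ch0"].items():
            assert counts[crit] == int((~mask).sum())

    def test_artifact_free_input_barely_touched(self, short_run):
        """True spikes lost to pre-sorting stay < 1% (event coverage)."""
        from spikeblocks.evaluate import match_spike_times

        truth = short_run["truth"]
        detected = short_run["detected"]
        keep = short_run["keep"]
        cov_all = (match_spike_times(truth.times, detected.times, 0.5)
                   >= 0).mean()
        cov_kept = (match_spike_times(truth.times, detected.times[keep], 0.5)
                    >= 0).mean()
        assert (cov_all - cov_kept) / cov_all < 0.01


class TestClusterFlagging:
    def test_sinusoid_cluster_flagged_by_maxima_count(self):
        """High-frequency sinusoidal 'spikes' show >5 local maxima."""
        t = np.arange(64) / 32000.0
        wave = 50 * np.sin(2 * np.pi * 3500.0 * t)  # 7 maxima in 2 ms
        waves = np.tile(wave, (20, 1))
        is_art, fired = flag_artifact_cluster(waves, 32000.0)
        assert is_art and "maxima" in fired

    def test_clean_unimodal_cluster_passes(self, rng):
        from spikeblocks.simulate import make_template

        tpl = make_template(RATE, peak_uv=80.0)
        peak = int(np.argmax(tpl))
        win = tpl[peak - 12:peak + 36]
        waves = win[None, :] + rng.normal(0, 1.0, (200, win.size))
        is_art, fired = flag_artifact_cluster(waves, RATE)
        assert not is_art and not fired

    def test_two_comparable_peaks_fire_ratio_criterion(self):
        """Maxima 0.5 ms apart at 60 and 40 uV: ratio 1.5 < 2."""
        k, rate = 48, 24000.0
        wave = np.zeros(k)
        i = np.arange(k)
        wave += 60 * np.exp(-0.5 * ((i - 12) / 2.0) ** 2)
        wave += 40 * np.exp(-0.5 * ((i - 24) / 2.0) ** 2)  # 0.5 ms later
        is_art, fired = flag_artifact_cluster(np.tile(wave, (10, 1)), rate)
        assert is_art and "peak_ratio" in fired

    def test_close_secondary_maximum_ignored(self):
        """A comparable maximum closer than 0.3 ms does not count."""
        k, rate = 48, 24000.0
        i = np.arange(k)
        wave = 60 * np.exp(-0.5 * ((i - 12) / 1.5) ** 2)
        wave += 40 * np.exp(-0.5 * ((i - 17) / 1.5) ** 2)  # 0.21 ms later
        _, fired = flag_artifact_cluster(np.tile(wave, (10, 1)), rate)
        assert "peak_ratio" not in fired

    def test_tail_range_criterion(self):
        wave = np.zeros(48)
        wave[10] = 50.0          # global maximum in first half
        wave[30] = 40.0
        wave[34] = -40.0         # second-half range 80 > 50
        is_art, fired = flag_artifact_cluster(np.tile(wave, (5, 1)), RATE)
        assert is_art and "tail_range" in fired

    def test_sem_criterion(self, rng):
        wave = np.zeros(48)
        wave[12] = 60.0
        waves = wave[None, :] + rng.normal(0, 12.0, (30, 48))
        is_art, fired = flag_artifact_cluster(waves, RATE)
        assert "sem" in fired
        tight = wave[None, :] + rng.normal(0, 1.0, (30, 48))
        _, fired = flag_artifact_cluster(tight, RATE)
        assert "sem" not in fired

    def test_single_spike_cluster_skips_sem_with_warning(self):
        wave = np.zeros((1, 48))
        wave[0, 12] = 60.0
        with pytest.warns(UserWarning, match="SEM"):
            is_art, fired = flag_artifact_cluster(wave, RATE)
        assert "sem" not in fired
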