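import math

import numpy as np
import pytest

from spikecircuit import (SpikeRaster, TraceSpec, generate_trace,
                          bandpass_and_notch, detect_spikes, spike_rate,
                          isi_statistics, fano_factor, active_sources,
                          detect_burstlets, detect_network_bursts,
                          interburst_intervals)

FS = 20_000.0


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

class TestFiltering:
    def test_dc_removed(self):
        x = np.full(int(FS), 3.3e-5)
        y = bandpass_and_notch(x, FS)
        assert np.abs(y[2000:-2000]).max() < 1e-7

    def test_mains_hum_attenuated_20db(self):
        t = np.arange(int(2 * FS)) / FS
        x = np.sin(2 * np.pi * 60.0 * t)
        y = bandpass_and_notch(x, FS)
        mid = slice(int(0.5 * FS), int(1.5 * FS))
        atten = 20 * np.log10(np.abs(x[mid]).max() / np.abs(y[mid]).max())
        assert atten >= 20.0

    def test_passband_gain_within_5pct(self):
        t = np.arange(int(2 * FS)) / FS
        x = np.sin(2 * np.pi * 500.0 * t)
        y = bandpass_and_notch(x, FS)
        mid = slice(int(0.5 * FS), int(1.5 * FS))
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_sampling_below_nyquist_errors(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_and_notch(np.zeros(1000), 3000.0)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

class TestDetection:
    def test_flat_trace_zero_spikes(self):
        raster = detect_spikes(np.zeros((1, int(12 * FS))), FS)
        assert raster.n_spikes == 0

    def test_nan_samples_error(self):
        x = np.zeros(int(12 * FS))
        x[5] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            detect_spikes(x, FS)

    def test_planted_spike_recovery(self, planted_trace):
        raster = detect_spikes(planted_trace)
        truth = planted_trace.true_spike_times[0]
        det = raster[0]
        hits = sum(np.abs(det - t).min() <= 0.001 for t in truth)
        assert hits / truth.size >= 0.99           # recall
        close = sum(np.abs(truth - t).min() <= 0.001 for t in det)
        assert close / det.size >= 0.99            # precision
        assert np.all(np.diff(det) > 0.002)        # no duplicates

    def test_two_crossings_1ms_apart_yield_one_spike(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1e-6, int(12 * FS))
        i = int(5 * FS)
        x[i] = 1e-4
        x[i + 20] = 9e-5                            # 1 ms later
        raster = detect_spikes(x, FS)
        near = raster[0][np.abs(raster[0] - 5.0) < 0.01]
        assert near.size == 1

    def test_notch_restores_no_hum_detection(self):
        # 60 Hz hum at 5x the noise SD lies inside the 20-2000 Hz passband;
        # after the notch the detector must behave as if the hum were never
        # there (same detections as the identical hum-free trace)
        kw = dict(true_spike_times=((),), duration=12.0, noise_sd=5e-6,
                  seed=1)
        hum = generate_trace(TraceSpec(mains_hum=25e-6, **kw))
        clean = generate_trace(TraceSpec(mains_hum=0.0, **kw))
        det_hum = detect_spikes(bandpass_and_notch(hum.data, 20_000.0),
                                20_000.0)[0]
        det_clean = detect_spikes(bandpass_and_notch(clean.data, 20_000.0),
                                  20_000.0)[0]
        assert det_hum.size == det_clean.size
        if det_hum.size:
            assert np.allclose(det_hum, det_clean, atol=2e-3)

    def test_recall_degrades_toward_threshold(self):
        rng = np.random.default_rng(8)
        times = tuple(np.cumsum(rng.uniform(0.05, 0.15, size=80)) + 0.5)
        recalls = []
        for amp in (50e-6, 12e-6):                 # 10x vs 2.4x noise SD
            tr = generate_trace(TraceSpec(true_spike_times=(times,),
                                          duration=12.0, noise_sd=5e-6,
                                          amplitude=amp, seed=8))
            det = detect_spikes(tr)[0]
            truth = tr.true_spike_times[0]
            recalls.append(np.mean([np.abs(det - t).min() <= 0.001
                                    if det.size else False for t in truth]))
        assert recalls[0] > recalls[1]


# ---------------------------------------------------------------------------
# train statistics
# ---------------------------------------------------------------------------

class TestTrainStats:
    @pytest.mark.parametrize("n,dur,expect", [(0, 300.0, 0.0),
                                              (600, 300.0, 2.0)])
    def test_spike_rate_quotient(self, n, dur, expect):
        assert spike_rate(np.linspace(0, dur, n), dur) == expect

    def test_poisson_rate_within_4sd(self, poisson_raster):
        r = spike_rate(poisson_raster.spike_times[0], 300.0)
        assert abs(r - 5.0) < 4 * math.sqrt(5.0 / 300.0)

    def test_regular_train_cv_zero(self):
        mean, cv = isi_statistics(np.arange(100, dtype=float))
        assert mean == pytest.approx(1.0)
        assert cv == pytest.approx(0.0, abs=1e-12)

    def test_poisson_cv_near_one(self, poisson_raster):
        _, cv = isi_statistics(poisson_raster.spike_times[1])
        assert cv == pytest.approx(1.0, abs=0.15)

    def test_bursty_cv_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        bursts = np.cumsum(rng.exponential(2.0, size=50))
        t = np.sort(np.concatenate(
            [bursts + k * 0.01 for k in range(5)]))
        mean, cv = isi_statistics(t)
        isi = np.diff(t)
        assert cv > 1.0
        assert mean == pytest.approx(isi.mean())
        assert cv == pytest.approx(isi.std(ddof=1) / isi.mean())

    def test_too_few_spikes_flagged_nan(self):
        mean, cv = isi_statistics(np.array([1.0]))
        assert math.isnan(mean) and math.isnan(cv)
        _, cv2 = isi_statistics(np.array([1.0, 2.0]))
        assert math.isnan(cv2)

    def test_regular_train_fano_zero(self):
        t = np.arange(0.5, 100.0, 1.0)             # one spike per 1-s bin
        assert fano_factor(t, 100.0, 1.0) == pytest.approx(0.0)

    def test_poisson_fano_near_one(self, poisson_raster):
        ff = fano_factor(poisson_raster.spike_times[2], 300.0, 1.0)
        # FF of a Poisson train: mean 1, SD ~ sqrt(2/n_bins)
        assert abs(ff - 1.0) < 4 * math.sqrt(2.0 / 300.0)

    def test_hand_computed_fano(self):
        # counts per 1-s bin: [0, 2, 1, 3, 0, 2, 1, 3, 0, 2]
        counts = [0, 2, 1, 3, 0, 2, 1, 3, 0, 2]
        t = np.concatenate([np.linspace(i + 0.1, i + 0.9, c)
                            for i, c in enumerate(counts) if c])
        t = np.sort(t)
        # by hand: mean = 1.4, sample variance = 12.4/9
        assert fano_factor(t, 10.0, 1.0) == pytest.approx(
            (12.4 / 9.0) / 1.4)

    def test_zero_spikes_fano_nan(self):
        assert math.isnan(fano_factor(np.array([]), 100.0, 1.0))

    def test_ff_cv_translation_invariant(self, poisson_raster):
        t = poisson_raster.spike_times[3]
        t = t[t < 200.0]
        shifted = t + 50.0
        assert fano_factor(t, 200.0, 1.0) == pytest.approx(
            fano_factor(shifted - 50.0, 200.0, 1.0))
        assert isi_statistics(t)[1] == pytest.approx(
            isi_statistics(shifted)[1])

    def test_mean_isi_inverse_rate_for_poisson(self, poisson_raster):
        t = poisson_raster.spike_times[4]
        mean, _ = isi_statistics(t)
        assert mean == pytest.approx(1.0 / 5.0, rel=0.15)


# ---------------------------------------------------------------------------
# active sources
# ---------------------------------------------------------------------------

class TestActiveSources:
    def test_all_equal_rates_all_active(self):
        assert active_sources([2.0] * 6).size == 6

    def test_linear_interpolation_percentile(self):
        # 75th percentile of 1..8 = 6.25 -> rates 7 and 8 qualify
        assert list(active_sources([1, 2, 3, 4, 5, 6, 7, 8])) == [6, 7]

    def test_single_source_active(self):
        assert list(active_sources([0.1])) == [0]


# ---------------------------------------------------------------------------
# burstlets
# ---------------------------------------------------------------------------

def burstlet_oracle(t, rate, min_spikes=4, core_cap=0.1, peri_cap=0.2):
    """Independent O(n^2) scan: greedy maximal cores, then extension."""
    core_thr = min(core_cap, 1.0 / (4 * rate))
    peri_thr = min(peri_cap, 1.0 / (3 * rate))
    events = []
    used = -1
    i = 0
    while i < len(t):
        j = i
        while j + 1 < len(t) and t[j + 1] - t[j] <= core_thr:
            j += 1
        if j - i + 1 >= min_spikes:
            a, b = i, j
            while a - 1 > used and t[a] - t[a - 1] <= peri_thr:
                a -= 1
            while b + 1 < len(t) and t[b + 1] - t[b] <= peri_thr:
                b += 1
            events.append((a, b))
            used = b
            i = b + 1
        else:
            i = j + 1
    return events


class TestBurstlets:
    def test_below_minimum_no_burstlet(self):
        t = np.array([0.0, 0.01, 0.02])
        assert detect_burstlets(t, 1.0) == []

    def test_five_spikes_at_10ms(self):
        t = np.arange(5) * 0.01
        ev = detect_burstlets(t, 1.0)     # core threshold min(0.1, 0.25)
        assert len(ev) == 1 and ev[0].n_spikes == 5

    def test_peripheral_spike_appended(self):
        t = np.concatenate([np.arange(5) * 0.01, [0.04 + 0.15]])
        ev = detect_burstlets(t, 1.0)     # peripheral min(0.2, 1/3) = 0.2
        assert len(ev) == 1 and ev[0].n_spikes == 6

    def test_high_rate_shrinks_thresholds(self):
        # at 10 Hz the core threshold is 1/(4*10) = 25 ms
        t = np.arange(5) * 0.05           # 50-ms ISIs: no core at 10 Hz
        assert detect_burstlets(t, 10.0) == []
        assert len(detect_burstlets(t, 1.0)) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_oracle_on_random_trains(self, seed):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 30, size=400))
        rate = t.size / 30.0
        got = [(e.spike_indices[0], e.spike_indices[-1])
               for e in detect_burstlets(t, rate)]
        assert got == burstlet_oracle(t, rate)


# ---------------------------------------------------------------------------
# network bursts
# ---------------------------------------------------------------------------

def network_burst_oracle(pooled, min_spikes=50, window=0.05):
    """Collect every qualifying min_spikes-consecutive-spike span, then
    merge spans that share at least one spike."""
    n = len(pooled)
    spans = [(i, i + min_spikes - 1) for i in range(n - min_spikes + 1)
             if pooled[i + min_spikes - 1] - pooled[i] <= window]
    events = []
    for a, b in spans:
        if events and a <= events[-1][1]:
            events[-1] = (events[-1][0], b)
        else:
            events.append((a, b))
    return [(pooled[a], pooled[b], b - a + 1) for a, b in events]


class TestNetworkBursts:
    def test_49_spikes_no_burst(self):
        t = np.linspace(0, 0.049, 49)
        r = SpikeRaster([t], [0], 1.0)
        assert detect_network_bursts(r) == []

    def test_60_spikes_in_40ms_one_burst(self):
        t = np.linspace(0.1, 0.14, 60)
        r = SpikeRaster([t], [0], 1.0)
        ev = detect_network_bursts(r)
        assert len(ev) == 1 and ev[0].n_spikes == 60

    def test_two_packets_give_ibi_of_one_second(self):
        t = np.concatenate([np.linspace(0.1, 0.14, 60),
                            np.linspace(1.1, 1.14, 60)])
        r = SpikeRaster([np.sort(t)], [0], 2.0)
        ev = detect_network_bursts(r)
        assert len(ev) == 2
        ibi = interburst_intervals(ev)
        assert ibi == pytest.approx([1.0], abs=0.01)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_window_oracle(self, seed):
        rng = np.random.default_rng(seed + 100)
        # bursty pooled train: background + dense packets
        packets = [rng.uniform(k, k + 0.04, size=rng.integers(30, 90))
                   for k in range(5)]
        pooled = np.sort(np.concatenate(
            [rng.uniform(0, 6, size=300)] + packets))
        r = SpikeRaster([pooled], [0], 6.5)
        got = [(e.start, e.end, e.n_spikes)
               for e in detect_network_bursts(r)]
        expect = network_burst_oracle(pooled)
        assert len(got) == len(expect)
        for g, e in zip(got, expect):
            assert g[0] == pytest.approx(e[0])
            assert g[1] == pytest.approx(e[1])
            assert g[2] == e[2]
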