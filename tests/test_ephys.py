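import numpy as np
import pytest

from amirkit import (
    EphysConfig,
    Recording,
    RecordingPlan,
    UnitPlan,
    autocorrelogram,
    bandpass,
    biphasic_template,
    burstiness,
    classify_unit,
    cluster_waveforms,
    detect_spikes,
    firing_rate,
    isi,
    make_recording,
    poisson_train,
    rasterize,
    read_recording,
    trough_to_peak,
    write_recording,
)
from amirkit.ephys import extract_waveforms

from conftest import acg_paircount

RATE = 20000.0


def sine(freq, duration_s=1.0, rate=RATE):
    t = np.arange(int(duration_s * rate)) / rate
    return np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_in_band_tone_preserved(self):
        rec = Recording(sine(1000.0), RATE)
        out = bandpass(rec)
        mid = out.samples[5000:15000]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_out_of_band_tone_attenuated(self):
        rec = Recording(sine(50.0), RATE)
        out = bandpass(rec)
        mid = out.samples[5000:15000]
        assert 20 * np.log10(np.abs(mid).max()) < -20.0

    def test_dc_removed(self):
        rec = Recording(np.full(20000, 3.7), RATE)
        out = bandpass(rec)
        assert np.abs(out.samples).max() < 1e-6

    def test_band_edge_beyond_nyquist_rejected(self):
        rec = Recording(sine(100.0), 13000.0)
        with pytest.raises(ValueError, match="band"):
            bandpass(rec, EphysConfig(band=(300.0, 7000.0)))


class TestDetect:
    def test_planted_spikes_recovered(self, rng):
        n = int(10 * RATE)
        x = rng.normal(0, 1.0, n)
        template = biphasic_template(400.0, RATE, amplitude=10.0)
        planted_ms = np.linspace(500, 9500, 10)
        pre = int(round(0.6 * RATE / 1000))
        for t in planted_ms:
            i = int(t * RATE / 1000) - pre
            x[i : i + len(template)] += template
        times = detect_spikes(Recording(x, RATE))
        assert len(times) == 10
        assert np.abs(times - planted_ms).max() <= 0.2

    def test_pure_noise_near_zero_false_positives(self, rng):
        x = rng.normal(0, 1.0, int(10 * RATE))
        assert len(detect_spikes(Recording(x, RATE))) <= 2

    def test_empty_and_flat_inputs(self):
        assert len(detect_spikes(Recording(np.array([]), RATE))) == 0
        with pytest.warns(UserWarning, match="zero-variance"):
            assert len(detect_spikes(Recording(np.zeros(1000), RATE))) == 0

    def test_absolute_mode_catches_positive_spikes(self, rng):
        x = rng.normal(0, 1.0, int(2 * RATE))
        x[20000] = 20.0  # positive-going event
        assert len(detect_spikes(Recording(x, RATE))) == 0
        cfg = EphysConfig(detect_mode="absolute")
        assert len(detect_spikes(Recording(x, RATE), cfg)) == 1

    def test_refractory_merges_close_events(self, rng):
        x = rng.normal(0, 0.01, int(RATE))
        x[1000] = x[1010] = -5.0  # 0.5 ms apart
        times = detect_spikes(Recording(x, RATE))
        assert len(times) == 1


class TestWaveformClassification:
    def test_two_shapes_clustered_correctly(self, rng):
        narrow = biphasic_template(300.0, RATE, amplitude=8.0)
        broad = biphasic_template(550.0, RATE, amplitude=12.0)
        wfs, truth = [], []
        for _ in range(100):
            wfs.append(narrow + rng.normal(0, 0.3, narrow.size))
            truth.append(0)
            wfs.append(broad + rng.normal(0, 0.3, broad.size))
            truth.append(1)
        labels = cluster_waveforms(np.array(wfs), k=2)
        truth = np.array(truth)
        agreement = max(np.mean(labels == truth), np.mean(labels == 1 - truth))
        assert agreement >= 0.95

    def test_cluster_seeded_deterministic(self, rng):
        wfs = rng.normal(size=(40, 33))
        assert np.array_equal(cluster_waveforms(wfs, 2), cluster_waveforms(wfs, 2))

    def test_bad_k_rejected(self, rng):
        wfs = rng.normal(size=(10, 33))
        with pytest.raises(ValueError):
            cluster_waveforms(wfs, 1)
        with pytest.raises(ValueError):
            cluster_waveforms(wfs, 11)

    def test_trough_to_peak_constructed(self):
        # trough and peak exactly 8 samples = 400 us apart on the grid
        y = np.zeros(40)
        y[10] = -1.0
        y[18] = 1.0
        assert trough_to_peak(y, RATE, refine=False) == pytest.approx(400.0)

    def test_trough_to_peak_flat_or_monotone_undefined(self):
        assert np.isnan(trough_to_peak(np.zeros(20), RATE))
        assert np.isnan(trough_to_peak(np.arange(20.0), RATE))

    def test_sweep_recovered_within_one_sample(self):
        for ttp in range(300, 601, 25):
            wf = biphasic_template(float(ttp), RATE)
            measured = trough_to_peak(wf, RATE)
            assert abs(measured - ttp) <= 1e6 / RATE

    @pytest.mark.parametrize(
        "ttp, label", [(441.0, "pPYR"), (440.0, "pIN"), (200.0, "pIN"), (float("nan"), "unclassified")]
    )
    def test_classification_boundary_strict(self, ttp, label):
        assert classify_unit(ttp) == label


class TestTrainMetrics:
    def test_raster_binary_collapse(self):
        r = rasterize([0.4, 0.6], duration_ms=10.0)
        assert r.sum() == 1 and r[0] == 1

    def test_raster_conserves_separated_spikes(self):
        times = np.arange(0.5, 100.0, 2.0)
        assert rasterize(times, 100.0).sum() == len(times)

    def test_raster_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rasterize([5.0], duration_ms=5.0)

    def test_firing_rate_and_isi(self):
        times = np.arange(0, 60000, 500.0)  # 120 spikes over 60 s
        assert firing_rate(times, 60.0) == pytest.approx(2.0)
        assert len(isi([3.0])) == 0
        assert np.allclose(isi(np.arange(0, 100, 10.0)), 10.0)

    def test_acg_periodic_train(self):
        times = np.arange(0.5, 1000.0, 10.0)
        acg = autocorrelogram(rasterize(times, 1000.0))
        peaks = np.flatnonzero(acg > 0) + 1
        assert list(peaks) == [10, 20, 30, 40, 50]

    def test_acg_single_spike_all_zero(self):
        assert autocorrelogram(rasterize([5.0], 1000.0)).sum() == 0

    def test_acg_equals_pair_counting_oracle(self, rng):
        times = np.sort(rng.uniform(0, 5000.0, size=400))
        raster = rasterize(times, 5000.0)
        acg = autocorrelogram(raster)
        assert np.array_equal(acg, acg_paircount(np.flatnonzero(raster)))

    def test_short_raster_warns(self):
        with pytest.warns(UserWarning, match="shorter"):
            autocorrelogram(np.array([1, 0, 1]), max_lag_ms=50)


class TestBurstiness:
    def test_uniform_acg_is_half(self):
        assert burstiness(np.ones(50)) == pytest.approx(0.5)

    def test_all_mass_at_lag_one(self):
        acg = np.zeros(50)
        acg[0] = 7
        assert burstiness(acg) == pytest.approx(0.98)

    def test_empty_acg_undefined(self):
        assert np.isnan(burstiness(np.zeros(50)))

    def test_bi_non_increasing_in_dt(self):
        values = []
        for dt in range(1, 51):
            acg = np.zeros(50)
            acg[dt - 1] = 1
            values.append(burstiness(acg))
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_bi_range(self, rng):
        for _ in range(50):
            acg = rng.integers(0, 20, size=50)
            if acg.sum() == 0:
                continue
            assert 0.0 <= burstiness(acg) <= 0.98


class TestIO:
    def test_binary_roundtrip_with_sidecar(self, tmp_path, rng):
        rec = Recording(rng.normal(size=1000), 25000.0)
        p = tmp_path / "trace.f32"
        write_recording(rec, p)
        back = read_recording(p)
        assert back.rate == 25000.0
        assert np.allclose(back.samples, rec.samples, atol=1e-6)

    def test_csv_input(self, tmp_path, rng):
        x = rng.normal(size=100)
        p = tmp_path / "trace.csv"
        np.savetxt(p, x)
        back = read_recording(p, rate=20000.0)
        assert np.allclose(back.samples, x, atol=1e-12)

    def test_missing_sidecar_and_rate_rejected(self, tmp_path):
        p = tmp_path / "raw.f32"
        np.zeros(10, dtype="<f4").tofile(p)
        with pytest.raises(FileNotFoundError):
            read_recording(p)
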