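import numpy as np
import pytest

from synscale.bursts import (
    BurstConfig,
    ConditioningConfig,
    burst_metrics,
    condition_neurogram,
    detect_bursts,
    epoch_compare,
    leaky_integrate,
    respiratory_bursts,
)
from synscale.synthetic import generate_neurogram
from synscale.trace_io import Trace

EPOCHS = {"baseline": (0.0, 120.0), "drug": (120.0, 240.0)}


def half_sine_trace(onsets, height=3.0, dur=1.0, baseline=1.0, fs=100.0,
                    duration=240.0, role="neurogram_cnx"):
    y = np.full(int(duration * fs), baseline)
    for t in onsets:
        i0 = int(t * fs)
        n = int(dur * fs)
        y[i0:i0 + n] += height * np.sin(np.pi * np.arange(n) / n)
    return Trace(y, fs, channel_role=role)


class TestConditioning:
    def test_zero_input_zero_output(self):
        tr = Trace(np.zeros(10_000), 5000.0, channel_role="neurogram_cnx")
        out = condition_neurogram(tr)
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_integrator_time_constant(self):
        """Unit step reaches 1 - 1/e of its plateau at one time constant."""
        fs, tau = 5000.0, 60.0
        x = np.ones(int(fs))
        y = leaky_integrate(x, fs, tau)
        at_tau = y[int(0.060 * fs) - 1]
        assert at_tau == pytest.approx(1 - np.exp(-1), rel=0.01)

    def test_noise_step_envelope_rises_with_tau(self):
        """Full chain on white-noise steps: mean output at t=tau is 63% of
        the plateau (averaged over realizations, +-5%)."""
        fs = 5000.0
        rng = np.random.default_rng(8)
        outs = []
        for _ in range(40):
            raw = Trace(rng.normal(0, 1, int(2 * fs)), fs,
                        channel_role="neurogram_cnx")
            outs.append(condition_neurogram(raw).samples)
        mean_out = np.mean(outs, axis=0)
        plateau = mean_out[int(1.0 * fs):].mean()
        assert mean_out[int(0.060 * fs)] / plateau == pytest.approx(
            1 - np.exp(-1), abs=0.05)

    def test_out_of_band_attenuation(self):
        """50 Hz (below band) attenuated >= 20 dB relative to 300 Hz."""
        fs = 5000.0
        t = np.arange(int(2 * fs)) / fs
        levels = {}
        for f0 in (50.0, 300.0):
            tr = Trace(np.sin(2 * np.pi * f0 * t), fs,
                       channel_role="neurogram_cnx")
            levels[f0] = condition_neurogram(tr).samples[int(fs):].mean()
        assert levels[50.0] < levels[300.0] / 10.0

    def test_band_above_nyquist_rejected(self):
        tr = Trace(np.zeros(10_000), 2000.0, channel_role="neurogram_cnx")
        with pytest.raises(ValueError, match="Nyquist"):
            condition_neurogram(tr, ConditioningConfig(band=(100.0, 1000.0)))

    def test_low_rate_rejected(self):
        tr = Trace(np.zeros(1000), 500.0, channel_role="neurogram_cnx")
        with pytest.raises(ValueError):
            condition_neurogram(tr)


class TestBurstMetrics:
    def test_half_sine_amplitude_and_area(self):
        """Height-3 half-sine over baseline 1: amplitude 3, area 2h*d/pi."""
        tr = half_sine_trace([50.0], height=3.0, dur=1.0, baseline=1.0)
        amp, area, flagged = burst_metrics(tr, 50.0, 51.0)
        assert amp == pytest.approx(3.0, rel=1e-3)
        assert area == pytest.approx(2 * 3.0 * 1.0 / np.pi, rel=0.01)
        assert not flagged

    def test_flat_window_zero(self):
        tr = half_sine_trace([], baseline=1.0)
        amp, area, _ = burst_metrics(tr, 50.0, 51.0)
        assert amp == 0.0 and area == 0.0

    def test_offset_invariance(self):
        t1 = half_sine_trace([50.0])
        t2 = Trace(t1.samples + 11.0, t1.sampling_rate, channel_role=t1.channel_role)
        assert burst_metrics(t1, 50.0, 51.0)[:2] == pytest.approx(
            burst_metrics(t2, 50.0, 51.0)[:2])

    def test_short_prefix_flagged(self):
        tr = half_sine_trace([0.3], dur=0.5)
        _, _, flagged = burst_metrics(tr, 0.3, 0.8)
        assert flagged


class TestDetectBursts:
    def test_noiseless_coincident_bursts_all_found(self):
        cnx, snii, truth = generate_neurogram(
            burst_rate=15.0, epochs=EPOCHS, noise_sd=0.0,
            amp_jitter_sigma=0.0, channel_lag=0.1, seed=1)
        bursts = detect_bursts(cnx, snii)
        resp = respiratory_bursts(bursts)
        true_onsets = truth.burst_windows["cnx"][:, 0]
        assert len(resp) == true_onsets.size
        np.testing.assert_allclose(
            [b.onset for b in resp], true_onsets, atol=3 / cnx.sampling_rate)

    def test_solo_cnx_burst_excluded_from_respiratory(self):
        cnx, snii, _ = generate_neurogram(
            burst_rate=10.0, epochs=EPOCHS, solo_bursts_cnx=[60.3], seed=2)
        bursts = detect_bursts(cnx, snii)
        solo = [b for b in bursts if abs(b.onset - 60.3) < 0.3]
        assert len(solo) == 1 and not solo[0].coincident
        assert all(b.coincident for b in bursts if b not in solo)

    def test_overlong_envelope_rejected(self):
        fs = 100.0
        cnx = half_sine_trace([30.0, 100.0], dur=1.0, fs=fs)
        # replace the second burst with a 5 s envelope
        y = cnx.samples.copy()
        n = int(5.0 * fs)
        y[int(100 * fs):int(100 * fs) + n] = \
            1.0 + 3.0 * np.sin(np.pi * np.arange(n) / n)
        cnx = Trace(y, fs, channel_role="neurogram_cnx")
        snii = half_sine_trace([30.0, 100.0], role="neurogram_snii")
        onsets = [b.onset for b in detect_bursts(cnx, snii)]
        assert len(onsets) == 1 and abs(onsets[0] - 30.0) < 0.2

    def test_lag_sign_symmetry(self):
        counts = []
        for lag in (-0.2, 0.2):
            cnx, snii, _ = generate_neurogram(
                burst_rate=12.0, epochs=EPOCHS, channel_lag=lag,
                noise_sd=0.0, amp_jitter_sigma=0.0, seed=7)
            counts.append(len(respiratory_bursts(detect_bursts(cnx, snii))))
        assert counts[0] == counts[1]

    def test_non_overlapping_traces_rejected(self):
        a = half_sine_trace([10.0], duration=60.0)
        b = half_sine_trace([10.0], duration=60.0, role="neurogram_snii")
        b.t0 = 100.0
        with pytest.raises(ValueError):
            detect_bursts(a, b)


class TestEpochCompare:
    def _bursts(self, onsets, amp=3.0):
        from synscale.bursts import Burst
        return [Burst(channel="neurogram_cnx", onset=t, offset=t + 1.0,
                      amplitude=amp, area=amp * 0.6, coincident=True)
                for t in onsets]

    def test_identical_epochs_all_100(self):
        bursts = (self._bursts(np.arange(5.0, 115.0, 10.0))
                  + self._bursts(np.arange(125.0, 235.0, 10.0)))
        for s in epoch_compare(bursts, EPOCHS):
            assert all(v == pytest.approx(100.0)
                       for v in s.percent_of_baseline.values())

    def test_amplitude_and_frequency_factors(self):
        bursts = (self._bursts(np.arange(5.0, 115.0, 10.0), amp=5.0)
                  + self._bursts(np.arange(125.0, 235.0, 50.0), amp=3.0))
        by_epoch = {s.epoch: s for s in epoch_compare(bursts, EPOCHS)}
        assert by_epoch["drug"].percent_of_baseline["amplitude"] == pytest.approx(60.0)
        assert by_epoch["drug"].percent_of_baseline["frequency"] == pytest.approx(
            100.0 * (3 / 11))  # 3 drug bursts vs 11 baseline bursts

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError):
            epoch_compare([], {"drug": (0.0, 60.0)})

    def test_empty_baseline_flagged(self):
        bursts = self._bursts([130.0, 150.0])
        for s in epoch_compare(bursts, EPOCHS):
            assert s.flagged
            assert s.percent_of_baseline["amplitude"] is None

    def test_generator_recovery_epoch_factors(self):
        """Recovered drug-epoch multipliers track the generator's (pilot;
        the unbiasedness Monte-Carlo lives in the acceptance suite)."""
        effects = {"baseline": {"amplitude": 1.0, "frequency": 1.0},
                   "drug": {"amplitude": 0.6, "frequency": 0.5}}
        ratios_a, ratios_f = [], []
        for s in range(12):
            cnx, snii, _ = generate_neurogram(
                burst_rate=20.0, epochs=EPOCHS, epoch_effects=effects, seed=s)
            resp = respiratory_bursts(detect_bursts(cnx, snii))
            by_epoch = {e.epoch: e for e in epoch_compare(resp, EPOCHS)}
            ratios_a.append(by_epoch["drug"].percent_of_baseline["amplitude"])
            ratios_f.append(by_epoch["drug"].percent_of_baseline["frequency"])
        assert np.mean(ratios_a) == pytest.approx(60.0, abs=5.0)
        assert np.mean(ratios_f) == pytest.approx(50.0, abs=10.0)
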