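"""Simulator correctness: geometry helper, templates, point processes, signals."""

import math

import numpy as np
import pytest
from scipy import special

from oracles import von_mises_rejection
from thetasort import detect, dsp, phase, synth
from thetasort.core import read_recording


class TestElectrodeArea:
    def test_default_probe_tip(self):
        # half-cylinder of 5 µm diameter, 7.5 µm exposed height
        area = synth.electrode_exposed_area(5.0, 7.5)
        assert area == pytest.approx(math.pi * 2.5 * 7.5)
        assert area == pytest.approx(58.8, rel=0.01)

    def test_linearity_in_width(self):
        assert synth.electrode_exposed_area(10.0, 7.5) == pytest.approx(
            2 * synth.electrode_exposed_area(5.0, 7.5)
        )

    def test_vanishes_with_height(self):
        assert synth.electrode_exposed_area(5.0, 1e-9) < 1e-7

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            synth.electrode_exposed_area(0.0, 7.5)


class TestTemplate:
    def test_peak_to_peak_matches_request(self):
        w = synth.make_template(100.0, 0.3, 0.6, 24414.0)
        assert np.ptp(w) == pytest.approx(100.0, rel=0.01)

    def test_linear_in_amplitude(self):
        w1 = synth.make_template(50.0, 0.3, 0.6, 24414.0)
        w2 = synth.make_template(100.0, 0.3, 0.6, 24414.0)
        np.testing.assert_allclose(w2, 2 * w1, atol=1e-9)

    def test_trough_at_alignment_index(self):
        rate = 24414.0
        w = synth.make_template(80.0, 0.3, 0.6, rate)
        assert int(np.argmin(w)) == int(round(0.0008 * rate))

    def test_biphasic_shape(self):
        w = synth.make_template(100.0, 0.3, 0.6, 24414.0)
        assert w.min() < 0 < w.max()
        assert np.argmin(w) < np.argmax(w)  # trough then rebound

    def test_rejects_widths_exceeding_window(self):
        with pytest.raises(ValueError, match="window"):
            synth.make_template(100.0, 2.0, 4.0, 24414.0)


class TestSpikeTrain:
    def test_poisson_count_no_modulation(self):
        # kappa=0, gain 1: count ~ Poisson(rT) less a small refractory loss
        r, T = 20.0, 50.0
        for seed in range(10):
            unit = synth.UnitSpec("ch1", base_rate=r, refractory=0.002)
            times = synth.simulate_spike_train(unit, None, None, T, seed)
            assert abs(len(times) - r * T) < 4 * math.sqrt(r * T)

    def test_refractory_enforced(self):
        unit = synth.UnitSpec("ch1", base_rate=80.0, refractory=0.003)
        times = synth.simulate_spike_train(unit, None, None, 20.0, 1)
        assert np.diff(times).min() >= 0.003

    def test_phase_locked_mean_matches_rejection_oracle(self):
        # kappa=8 concentration: both the simulator and an independent
        # rejection sampler should centre on mu = 330 within a few degrees
        mu, kappa = 330.0, 8.0
        unit = synth.UnitSpec("ch1", base_rate=10.0, preferred_phase=mu,
                              kappa=kappa, refractory=0.001)
        phase_fn = lambda t: 2 * math.pi * 6.0 * np.asarray(t)
        times = synth.simulate_spike_train(unit, phase_fn, None, 120.0, 3)
        assert len(times) >= 500
        angles = np.degrees(phase_fn(times)) % 360.0
        mean, _ = phase.circular_stats(angles)
        assert abs((mean - mu + 180) % 360 - 180) < 5.0
        oracle = von_mises_rejection(mu, kappa, 2000, np.random.default_rng(3))
        mean_o, _ = phase.circular_stats(oracle)
        assert abs((mean - mean_o + 180) % 360 - 180) < 5.0

    def test_von_mises_factor_normalized(self):
        # empirical mean of exp(k cos)/I0(k) over a uniform phase grid is 1
        for kappa in (0.5, 2.0, 8.0):
            theta = np.linspace(0, 2 * math.pi, 100001)[:-1]
            factor = np.exp(kappa * np.cos(theta)) / special.i0(kappa)
            assert factor.mean() == pytest.approx(1.0, abs=1e-3)

    def test_state_gain_modulates_rate(self):
        import pandas as pd

        from thetasort.core import EventTable

        events = EventTable(pd.DataFrame(
            [("running", 0.0, 100.0), ("standstill", 100.0, 200.0)],
            columns=["label", "t_start", "t_end"],
        ))
        unit = synth.UnitSpec("ch1", base_rate=5.0,
                              state_gain={"running": 4.0})
        times = synth.simulate_spike_train(unit, None, events, 200.0, 0)
        n_run = ((times >= 0) & (times < 100)).sum()
        n_still = (times >= 100).sum()
        assert 3.0 < n_run / n_still < 5.0


class TestRecording:
    def test_noise_only_spike_band_rms(self):
        # broadband white noise of rms 15 µV: the 500-3000 Hz band carries
        # rms 15*sqrt(B_eff/nyquist) ≈ 6.4 µV (B_eff measured by filtering
        # a long white-noise run through the actual filter)
        rec, _ = synth.simulate_recording(
            ["ch1"], {}, synth.LfpSpec(pink_rms=0.0, theta_amp=0.0), None,
            10.0, noise_rms=15.0, rate=24414.0, seed=2,
        )
        filtered = dsp.bandpass(rec, dsp.SPIKE_BAND)
        assert filtered.channel("ch1").std() == pytest.approx(6.42, rel=0.10)

    def test_noiseless_troughs_at_ground_truth(self):
        units = {"u1": synth.UnitSpec("ch1", base_rate=5.0, amplitude=100.0)}
        rec, gt = synth.simulate_recording(
            ["ch1"], units, synth.LfpSpec(pink_rms=0.0, theta_amp=0.0), None,
            10.0, noise_rms=0.0, rate=24414.0, seed=0,
        )
        train = detect.detect_spikes(rec.channel("ch1"), rec.rate)
        expected = np.round(gt.spike_times["u1"] * rec.rate).astype(int)
        np.testing.assert_array_equal(
            np.round(train.spike_times * rec.rate).astype(int), expected
        )

    def test_theta_delay_constructed(self):
        lfp = synth.LfpSpec(theta_freq=6.0, delays={"ch2": 0.020}, pink_rms=0.0)
        rec, _ = synth.simulate_recording(
            ["ch1", "ch2"], {}, lfp, None, 10.0, noise_rms=0.0,
            rate=24414.0, seed=0,
        )
        d = phase.theta_delay(rec.channel("ch1"), rec.channel("ch2"),
                              rec.rate, 0.05)
        assert d == pytest.approx(0.020, abs=1.0 / rec.rate)

    def test_energy_additivity(self):
        # residual (recording minus noise-free part) carries the white rms
        rec, gt = synth.simulate_recording(
            ["ch1"],
            {"u1": synth.UnitSpec("ch1", base_rate=5.0, amplitude=100.0)},
            synth.LfpSpec(pink_rms=0.0), None, 12.0,
            noise_rms=15.0, rate=20000.0, seed=4,
        )
        residual = rec.samples - gt.clean
        assert np.sqrt((residual**2).mean()) == pytest.approx(15.0, rel=0.10)

    def test_determinism(self):
        kw = dict(
            channel_ids=["ch1"],
            units={"u1": synth.UnitSpec("ch1", base_rate=5.0)},
            lfp=synth.LfpSpec(),
            events=None,
            duration=3.0,
            seed=11,
        )
        a, _ = synth.simulate_recording(**kw)
        b, _ = synth.simulate_recording(**kw)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="unknown channel"):
            synth.simulate_recording(
                ["ch1"], {"u1": synth.UnitSpec("chX", base_rate=5.0)},
                synth.LfpSpec(), None, 1.0,
            )

    def test_mains_interference_present(self):
        lfp = synth.LfpSpec(theta_amp=0.0, pink_rms=0.0, mains_amp=50.0)
        rec, _ = synth.simulate_recording(["ch1"], {}, lfp, None, 2.0,
                                          noise_rms=0.0, rate=24414.0)
        x = rec.channel("ch1")
        t = rec.times
        power_60 = abs(np.sum(x * np.exp(-2j * math.pi * 60.0 * t))) / len(x)
        assert power_60 == pytest.approx(25.0, rel=0.05)  # amp/2 for a sine


class TestSessionSeries:
    def test_trajectory_and_sortable_schedule(self, tmp_path):
        chs = [f"ch{i}" for i in range(12)]
        units = {f"u{i}": synth.UnitSpec(f"ch{i}", base_rate=5.0)
                 for i in range(12)}
        week1 = chs[:5]
        manifest, truths = synth.simulate_session_series(
            tmp_path, chs, units, synth.LfpSpec(), None,
            weeks=[1, 15, 33], amplitude_trajectory=[24.0, 143.0, 125.0],
            sortable_channels=[week1, chs, chs], duration=2.0, seed=0,
        )
        assert manifest.weeks == [1.0, 15.0, 33.0]
        assert len(truths[0].unit_specs) == 5  # 5 of 12 channels in week 1
        for gt, amp in zip(truths, [24.0, 143.0, 125.0]):
            for spec in gt.unit_specs.values():
                assert spec.amplitude == amp
        # fixed template shape: only the amplitude scales between weeks
        back = read_recording(manifest.sessions[0][1])
        assert back.n_channels == 12

    def test_trajectory_length_mismatch(self, tmp_path):
        with pytest.raises(ValueError, match="trajectory"):
            synth.simulate_session_series(
                tmp_path, ["ch1"], {}, synth.LfpSpec(), None,
                weeks=[1, 2], amplitude_trajectory=[24.0],
                sortable_channels=None, duration=1.0,
            )

    def test_constant_trajectory_identical_templates(self, tmp_path):
        units = {"u1": synth.UnitSpec("ch1", base_rate=5.0)}
        _, truths = synth.simulate_session_series(
            tmp_path, ["ch1"], units, synth.LfpSpec(), None,
            weeks=[1, 2], amplitude_trajectory=[90.0, 90.0],
            sortable_channels=None, duration=1.0, seed=0,
        )
        assert truths[0].unit_specs["u1"] == truths[1].unit_specs["u1"]
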