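"""Simulator unit and property tests: delays, rendering, calibration, scenarios."""

import numpy as np
import pytest

from dircuff.construct import TETRAPOLAR_COEFFS
from dircuff.synth import (
    APTemplate,
    CuffGeometry,
    FiringSchedule,
    GroundTruthManifest,
    Protocol,
    ScenarioConfig,
    add_calibrated_noise,
    contact_delays,
    noise_vpp_estimate,
    render_contact_voltages,
    sample_schedule,
    simulate_physio,
    simulate_recording,
    tetra_spike_vpp,
)

GEO = CuffGeometry()


class TestContactDelays:
    def test_adjacent_contact_delay_is_four_samples(self):
        # 2.5 mm at 25 m/s and 40 kHz -> 0.1 ms = 4 samples
        d = contact_delays(GEO, 25.0, "afferent")
        assert np.allclose(d, [0, 4, 8, 12])

    def test_infinite_velocity_gives_zero_delays(self):
        assert np.allclose(contact_delays(GEO, np.inf, "afferent"), 0.0)

    def test_efferent_reverses_delay_vector(self):
        aff = contact_delays(GEO, 25.0, "afferent")
        eff = contact_delays(GEO, 25.0, "efferent")
        assert np.allclose(eff, aff[::-1])

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            contact_delays(GEO, 0.0, "afferent")
        with pytest.raises(ValueError):
            contact_delays(GEO, -5.0, "afferent")
        with pytest.raises(ValueError):
            contact_delays(GEO, 25.0, "sideways")


def _single_spike_schedule(direction="afferent", amp=10.0, t=0.005):
    return FiringSchedule(
        spike_times=np.array([t]),
        directions=np.array([direction], dtype=object),
        amplitudes_uv=np.array([amp]),
    )


class TestRendering:
    def test_empty_schedule_renders_zeros(self):
        sched = FiringSchedule(spike_times=np.empty(0), directions=np.empty(0, dtype=object))
        c = render_contact_voltages(sched, APTemplate.biphasic(), GEO, 25.0, n_samples=1000)
        assert np.all(c.stack() == 0.0)

    def test_infinite_velocity_is_common_mode(self):
        c = render_contact_voltages(
            _single_spike_schedule(), APTemplate.biphasic(), GEO, np.inf, n_samples=1000
        )
        v = c.stack()
        assert np.allclose(v[0], v[1]) and np.allclose(v[0], v[3])
        assert np.max(np.abs(TETRAPOLAR_COEFFS @ v)) < 1e-12

    def test_linearity_in_amplitude(self):
        t = APTemplate.biphasic()
        c1 = render_contact_voltages(_single_spike_schedule(amp=5.0), t, GEO, 25.0, 1000)
        c2 = render_contact_voltages(_single_spike_schedule(amp=10.0), t, GEO, 25.0, 1000)
        assert np.allclose(c2.stack(), 2.0 * c1.stack())

    def test_direction_polarity_is_opposite(self):
        """Efferent rendering through the tetrapolar combination is the exact
        negative of the afferent one (antisymmetric coefficients), so the
        dominant peaks have opposite signs."""
        t = APTemplate.biphasic()
        a = TETRAPOLAR_COEFFS @ render_contact_voltages(
            _single_spike_schedule("afferent"), t, GEO, 25.0, 1200
        ).stack()
        e = TETRAPOLAR_COEFFS @ render_contact_voltages(
            _single_spike_schedule("efferent"), t, GEO, 25.0, 1200
        ).stack()
        assert np.allclose(e, -a, atol=1e-12)
        assert np.sign(a[np.argmax(np.abs(a))]) != np.sign(e[np.argmax(np.abs(e))])


class TestNoiseCalibration:
    def _traces(self):
        sched = _single_spike_schedule()
        return render_contact_voltages(sched, APTemplate.biphasic(), GEO, 25.0, n_samples=200_000)

    def test_snr_calibration_within_half_db_over_20_seeds(self):
        traces = self._traces()
        vpp = tetra_spike_vpp(APTemplate.biphasic(), GEO, 25.0)
        for seed in range(20):
            _, achieved = add_calibrated_noise(traces, 6.05, vpp, seed)
            assert abs(achieved - 6.05) < 0.5

    def test_target_20db_means_vpp_ratio_10(self):
        traces = self._traces()
        noisy, _ = add_calibrated_noise(traces, 20.0, 10.0, seed=1)
        tetra_noise = TETRAPOLAR_COEFFS @ (noisy.stack() - traces.stack())
        assert noise_vpp_estimate(tetra_noise, GEO.sampling_rate) == pytest.approx(1.0, rel=1e-6)

    def test_same_seed_is_bit_identical(self):
        traces = self._traces()
        a, _ = add_calibrated_noise(traces, 6.0, 10.0, seed=7)
        b, _ = add_calibrated_noise(traces, 6.0, 10.0, seed=7)
        assert np.array_equal(a.stack(), b.stack())

    def test_infinite_target_returns_unchanged(self):
        traces = self._traces()
        out, achieved = add_calibrated_noise(traces, np.inf, 10.0, seed=0)
        assert np.array_equal(out.stack(), traces.stack())
        assert achieved == np.inf


TINY = Protocol(baseline_s=10.0, n_obstructions=1, obstruction_s=10.0, gap_s=1.0, post_s=5.0)


class TestScenarios:
    def test_complete_transection_has_no_spikes(self):
        rec = simulate_recording(ScenarioConfig(condition="complete_transection", protocol=TINY, seed=1))
        assert rec.manifest.n_spikes == 0

    def test_proximal_transection_is_afferent_only(self):
        rec = simulate_recording(ScenarioConfig(condition="proximal_transection", protocol=TINY, seed=2))
        assert rec.manifest.n_spikes > 0
        assert all(d == "afferent" for d in rec.manifest.directions)

    def test_distal_transection_is_efferent_only(self):
        rec = simulate_recording(ScenarioConfig(condition="distal_transection", protocol=TINY, seed=3))
        assert all(d == "efferent" for d in rec.manifest.directions)

    def test_no_suppression_keeps_obstruction_rate(self):
        cfg = ScenarioConfig(
            condition="proximal_transection", protocol=TINY, seed=4, obstruction_suppression=1.0
        )
        sched = sample_schedule(cfg, np.random.default_rng(4))
        t = sched.spike_times
        rate_base = np.sum(t < 10.0) / 10.0
        rate_obs = np.sum((t >= 10.0) & (t < 20.0)) / 10.0
        # equal expected rates; allow 3 combined Poisson standard errors
        se = np.sqrt(rate_base / 10.0 + rate_obs / 10.0)
        assert abs(rate_base - rate_obs) < 3 * se

    def test_epoch_rates_recover_base_rates(self):
        cfg = ScenarioConfig(condition="intact", protocol=TINY, seed=5)
        rec = simulate_recording(cfg)
        for direction, rate in (("afferent", cfg.afferent_rate), ("efferent", cfg.efferent_rate)):
            n = rec.manifest.count(direction, (0.0, 10.0))
            expected = rate * 10.0
            assert abs(n - expected) < 3 * np.sqrt(expected)

    def test_manifest_round_trips(self, tmp_path):
        rec = simulate_recording(ScenarioConfig(condition="intact", protocol=TINY, seed=6))
        path = tmp_path / "manifest.json"
        rec.manifest.to_json(path)
        back = GroundTruthManifest.from_json(path)
        assert np.array_equal(back.spike_times, rec.manifest.spike_times)
        assert list(back.directions) == list(rec.manifest.directions)
        assert back.obstruction_intervals == rec.manifest.obstruction_intervals

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            Protocol(baseline_s=0.0)
        with pytest.raises(ValueError):
            Protocol(obstruction_s=-1.0)
        with pytest.raises(ValueError):
            ScenarioConfig(condition="hemisection")


class TestPhysioChannels:
    def test_heart_rate_360_gives_6hz_rr(self):
        cfg = ScenarioConfig(condition="intact", protocol=TINY, seed=7, hr_effect=0.0)
        ecg, _, _ = simulate_physio(cfg)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(ecg.data, height=0.5 * ecg.data.max(), distance=100)
        rr = np.diff(peaks) / ecg.sampling_rate
        assert np.mean(rr) == pytest.approx(1.0 / 6.0, rel=0.01)

    def test_bp_step_is_exact_fraction(self):
        cfg = ScenarioConfig(condition="intact", protocol=TINY, seed=8)
        _, bp, _ = simulate_physio(cfg)
        fs = bp.sampling_rate
        base = bp.data[: int(9 * fs)].mean()
        obs = bp.data[int(11 * fs) : int(19 * fs)].mean()
        assert obs / base == pytest.approx(1.20, abs=0.01)

    def test_zero_ggemg_effect_keeps_burst_amplitude(self):
        cfg = ScenarioConfig(condition="intact", protocol=TINY, seed=9, ggemg_effect=0.0)
        _, _, gg = simulate_physio(cfg)
        fs = gg.sampling_rate
        base = np.abs(gg.data[: int(10 * fs)]).mean()
        obs = np.abs(gg.data[int(10 * fs) : int(20 * fs)]).mean()
        assert obs == pytest.approx(base, rel=0.15)
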