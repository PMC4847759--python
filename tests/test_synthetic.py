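"""Generators: rachis profiles, swept sines, display trajectories,
rattle audio and mode envelopes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trainrattle import kinematics, synthetic
from trainrattle.datatypes import SWEEP_PRESETS, SweepProtocol


class TestRachisProfile:
    def test_determinism(self):
        spec = synthetic.FeatherSpec("eyespot", L_R=0.9, seed=42)
        a = synthetic.gen_rachis_profile(spec)
        b = synthetic.gen_rachis_profile(spec)
        assert np.array_equal(a.D1, b.D1)
        assert np.array_equal(a.mu_F, b.mu_F)

    def test_monotone_taper_and_density_ordering(self):
        spec = synthetic.FeatherSpec("eyespot", L_R=0.66, seed=3)
        prof = synthetic.gen_rachis_profile(spec)
        assert np.all(np.diff(prof.D1) < 0)
        assert np.all(np.diff(prof.mu_R) < 0)
        assert np.all(prof.mu_F >= prof.mu_R)
        assert prof.mu_E is not None and prof.M_E > 0

    def test_slenderness_calibration_longest_class(self):
        spec = synthetic.FeatherSpec("eyespot", L_R=1.12, jitter=0.0, seed=0)
        prof = synthetic.gen_rachis_profile(spec)
        assert prof.L_R / prof.D_avg == pytest.approx(293, rel=1e-6)
        spec_s = synthetic.FeatherSpec("eyespot", L_R=0.14, jitter=0.0, seed=0)
        prof_s = synthetic.gen_rachis_profile(spec_s)
        assert prof_s.L_R / prof_s.D_avg == pytest.approx(95, rel=1e-6)

    def test_zero_taper_gives_uniform_beam(self):
        spec = synthetic.FeatherSpec(
            "rectrix", L_R=0.4, taper_exponent=0.0, jitter=0.0, seed=0
        )
        prof = synthetic.gen_rachis_profile(spec)
        assert np.allclose(prof.D1, prof.D1[0])
        assert np.allclose(prof.mu_R, prof.mu_R[0])

    def test_rectrix_has_no_tip_mass(self):
        prof = synthetic.gen_rachis_profile(
            synthetic.FeatherSpec("rectrix", L_R=0.45, seed=0)
        )
        assert prof.M_E == 0.0

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            synthetic.FeatherSpec("eyespot", L_R=-1.0)
        with pytest.raises(ValueError):
            synthetic.FeatherSpec("eyespot", L_R=1.0, n_segments=2)
        with pytest.raises(ValueError):
            synthetic.FeatherSpec("eyespot", L_R=1.0, M_E=-1e-4)
        with pytest.raises(ValueError):
            synthetic.FeatherSpec(
                "eyespot", L_R=1.0, cortex_density=100.0, pith_density=200.0
            )


class TestSweptSine:
    def test_resonant_amplification_at_fixed_frequency(self):
        # drive exactly at the resonance: response/drive = Q * gain
        f0, Q, gain = 12.0, 5.0, 0.7
        bank = synthetic.OscillatorBank(modes=((f0, Q, gain),))
        ratio = bank.response_ratio(np.array([f0]))[0]
        assert ratio == pytest.approx(Q * gain, rel=1e-12)

    def test_envelope_maximal_near_resonance(self):
        bank = synthetic.OscillatorBank(modes=((25.0, 5.0, 1.0),))
        drive, resp = synthetic.gen_swept_sine_pair(
            bank, SWEEP_PRESETS["high"], noise_sd=0.0, seed=0
        )
        t_peak = np.argmax(np.abs(resp.displacement)) / resp.fps
        f_peak = SWEEP_PRESETS["high"].instantaneous_frequency(t_peak)
        assert abs(f_peak - 25.0) < 1.5

    def test_amplitude_at_resonance_linear_in_q(self):
        amps = []
        for Q in (2.0, 4.0, 8.0):
            bank = synthetic.OscillatorBank(modes=((25.0, Q, 1.0),))
            _, resp = synthetic.gen_swept_sine_pair(
                bank, SWEEP_PRESETS["high"], noise_sd=0.0, seed=0
            )
            amps.append(np.max(np.abs(resp.displacement)))
        assert amps[1] / amps[0] == pytest.approx(2.0, rel=0.05)
        assert amps[2] / amps[1] == pytest.approx(2.0, rel=0.05)

    def test_presets_within_nyquist(self):
        for name, sweep in SWEEP_PRESETS.items():
            synthetic.gen_swept_sine_pair(
                synthetic.OscillatorBank(modes=((2.0, 3.0, 1.0),)),
                SweepProtocol(sweep.f_start, min(sweep.f_stop, 20.0), sweep.rate),
                seed=0,
            )
        assert SWEEP_PRESETS["low"].rate == 0.042
        assert SWEEP_PRESETS["mid"].rate == 0.25
        assert SWEEP_PRESETS["high"].rate == 1.8

    def test_bad_sweep_rejected(self):
        with pytest.raises(ValueError):
            SweepProtocol(10.0, 120.0, 0.0)
        bank = synthetic.OscillatorBank(modes=((25.0, 5.0, 1.0),))
        with pytest.raises(ValueError):
            synthetic.gen_swept_sine_pair(
                bank, SweepProtocol(10.0, 200.0, 1.8), seed=0
            )

    def test_bank_invariants(self):
        with pytest.raises(ValueError):
            synthetic.OscillatorBank(modes=((25.0, 5.0, 1.0), (6.0, 4.0, 1.0)))
        with pytest.raises(ValueError):
            synthetic.OscillatorBank(modes=((25.0, 0.4, 1.0),))

    def test_determinism(self):
        bank = synthetic.OscillatorBank(modes=((25.0, 5.0, 1.0),))
        a = synthetic.gen_swept_sine_pair(
            bank, SWEEP_PRESETS["high"], noise_sd=0.1, seed=9
        )
        b = synthetic.gen_swept_sine_pair(
            bank, SWEEP_PRESETS["high"], noise_sd=0.1, seed=9
        )
        assert np.array_equal(a[0].displacement, b[0].displacement)
        assert np.array_equal(a[1].displacement, b[1].displacement)


class TestDisplayTrajectory:
    def test_initial_frequency_slope(self):
        # d f/dt at t=0 equals f_ss / tau for the saturating exponential
        f_ss, tau = 26.0, 0.8
        assert f_ss / tau == pytest.approx(32.5)
        traj = synthetic.gen_display_trajectory(f_ss, tau, duration=6.0, seed=0)
        t, fi = kinematics.instantaneous_frequency(traj)
        early = fi[t < 0.15]
        model = f_ss * (1 - np.exp(-t[t < 0.15] / tau))
        assert np.allclose(early, model, rtol=0.08)

    def test_tau_zero_limit_constant_frequency_sinusoid(self):
        traj = synthetic.gen_display_trajectory(
            25.6, 0.0, amplitude=5.0, duration=5.0, seed=0
        )
        expected = 5.0 * np.sin(2 * np.pi * 25.6 * traj.t)
        assert np.allclose(traj.displacement, expected, atol=1e-9)

    def test_cycle_count_recovers_frequency_within_quantization(self):
        traj = synthetic.gen_display_trajectory(25.6, 0.0, duration=12.0, seed=0)
        from trainrattle.datatypes import TrajectoryTimeSeries

        sub = TrajectoryTimeSeries(traj.displacement[1200:], fps=240.0)
        f = kinematics.frequency_by_cycle_count(sub)
        assert 240 * 10 / 94 <= f <= 25.6 + 1e-9

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            synthetic.gen_display_trajectory(25.6, -0.5)


class TestRattleAudio:
    def test_inter_pulse_interval(self):
        clip = synthetic.gen_rattle_audio(25.6, seed=0)
        from trainrattle import acoustics

        idx = acoustics.detect_pulses(clip)
        intervals = np.diff(idx) / clip.fs
        assert np.median(intervals) == pytest.approx(1 / 25.6, rel=0.02)

    def test_overlapping_pulses_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            synthetic.gen_rattle_audio(25.6, pulse_dur=0.05)

    def test_zero_amplitude_silent(self):
        clip = synthetic.gen_rattle_audio(25.6, amplitude=0.0, seed=0)
        assert np.allclose(clip.samples, 0.0)
        from trainrattle import acoustics

        assert acoustics.detect_pulses(clip).size == 0

    def test_broadband_striations_in_spectrogram(self):
        # energy concentrated in the passband, repeating at the pulse rate
        from trainrattle import acoustics

        clip = synthetic.gen_rattle_audio(
            25.6, band=(500.0, 15000.0), pulse_dur=0.005, seed=1
        )
        f, t, mag = acoustics.spectrogram(clip)
        band_energy = mag[(f > 500) & (f < 15000)].sum()
        assert band_energy / mag.sum() > 0.9
        # column energy is periodic at the pulse rate: autocorrelate
        col = mag.sum(axis=0) - mag.sum(axis=0).mean()
        ac = np.correlate(col, col, mode="full")[col.size :]
        dt = t[1] - t[0]
        lag = np.argmax(ac[int(0.5 * (1 / 25.6) / dt) :]) + int(
            0.5 * (1 / 25.6) / dt
        )
        assert lag * dt == pytest.approx(1 / 25.6, rel=0.1)

    def test_rms_normalization(self):
        clip = synthetic.gen_rattle_audio(25.6, rms=0.04, seed=0)
        assert np.sqrt(np.mean(clip.samples**2)) == pytest.approx(0.04, rel=0.01)


class TestModeEnvelope:
    @pytest.mark.parametrize("boundary", ["clamped_free", "clamped_hinged"])
    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_interior_node_count(self, boundary, k):
        # brute-force zero-crossing count on a dense grid
        env = synthetic.gen_mode_envelope(boundary, k, n_points=4001)
        interior = env[1:-1]
        crossings = np.count_nonzero(np.diff(np.sign(interior)) != 0)
        assert crossings == k - 1

    def test_clamped_free_k1_no_interior_node(self):
        env = synthetic.gen_mode_envelope("clamped_free", 1, 501)
        assert np.all(env[1:] > 0)

    def test_hinged_tip_is_node(self):
        env = synthetic.gen_mode_envelope("clamped_hinged", 3, 501)
        assert abs(env[-1]) < 1e-9

    def test_unsupported_boundary(self):
        with pytest.raises(ValueError):
            synthetic.gen_mode_envelope("free_free", 1)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    f_ss=st.floats(20.0, 30.0),
    tau=st.floats(0.2, 1.5),
)
def test_onset_model_slope_identity(f_ss, tau):
    """The generator's frequency law satisfies initial_rate = f_ss/tau."""
    t = np.linspace(0, 5, 4001)
    f = f_ss * (1 - np.exp(-t / tau))
    slope0 = (f[1] - f[0]) / (t[1] - t[0])
    assert slope0 == pytest.approx(f_ss / tau, rel=0.01)
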