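"""Signal front end: decimation + filtering, complementary-filter
orientation, and world-frame channel derivation."""

import numpy as np
import pytest
from scipy import signal
from scipy.spatial.transform import Rotation

import moodscreen as ms
from moodscreen.kinematics import KinematicsError


def _sine_recording(freq, rate=300.0, duration=10.0, axis=2, offset=0.0):
    t = np.arange(int(duration * rate)) / rate
    accel = np.zeros((t.size, 3))
    accel[:, axis] = offset + np.sin(2 * np.pi * freq * t)
    return ms.ImuRecording(time=t, accel=accel, gyro=np.zeros((t.size, 3)),
                           sample_rate_hz=rate)


def _filtfilt_gain(freq, cutoff=20.0, order=4, fs=100.0):
    """Oracle: squared magnitude response of the designed digital filter,
    evaluated independently of the filtering code path."""
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    _, h = signal.sosfreqz(sos, worN=[freq], fs=fs)
    return float(np.abs(h[0]) ** 2)  # forward-backward doubles attenuation


class TestPreprocess:
    def test_constant_input_passes_with_unit_dc_gain(self, static_recording):
        out = ms.preprocess(static_recording)
        assert out.sample_rate_hz == 100.0
        assert out.n_samples == static_recording.n_samples // 3
        np.testing.assert_allclose(out.accel[:, 2], 1.0, atol=1e-10)
        np.testing.assert_allclose(out.accel[:, :2], 0.0, atol=1e-10)

    @pytest.mark.parametrize("freq, rtol", [(5.0, 0.01), (25.0, 0.02)])
    def test_sinusoid_amplitude_matches_filter_response(self, freq, rtol):
        """Passband tones survive within 1%; stopband tones attenuate to
        the zero-phase Butterworth gain computed by an independent
        frequency-response oracle."""
        rec = _sine_recording(freq)
        out = ms.preprocess(rec)
        mid = out.accel[200:-200, 2]  # avoid edge transients
        amplitude = np.sqrt(2.0) * np.sqrt(np.mean(mid**2))
        expected = _filtfilt_gain(freq)
        assert amplitude == pytest.approx(expected, rel=rtol)
        if freq <= 10.0:
            assert amplitude == pytest.approx(1.0, rel=0.01)

    def test_stopband_tone_strongly_attenuated(self):
        # 25 Hz gain of the digital zero-phase filter is ~0.072 (the
        # analog prototype would give 0.144; the bilinear design is
        # steeper near Nyquist)
        g = _filtfilt_gain(25.0)
        assert 0.05 < g < 0.09

    def test_rejects_bad_inputs(self, static_recording):
        short = ms.ImuRecording(time=np.arange(30) / 300.0,
                                accel=np.zeros((30, 3)),
                                gyro=np.zeros((30, 3)), sample_rate_hz=300.0)
        with pytest.raises(KinematicsError, match="too short"):
            ms.preprocess(short)
        slow = ms.ImuRecording(time=np.arange(300) / 50.0,
                               accel=np.zeros((300, 3)),
                               gyro=np.zeros((300, 3)), sample_rate_hz=50.0)
        with pytest.raises(KinematicsError, match="upsampling"):
            ms.preprocess(slow)
        with pytest.raises(KinematicsError, match="increasing"):
            ms.ImuRecording(time=np.zeros(10), accel=np.zeros((10, 3)),
                            gyro=np.zeros((10, 3)), sample_rate_hz=300.0)


class TestOrientation:
    def test_stationary_level_device_keeps_identity(self, static_recording):
        rec = ms.preprocess(static_recording)
        orient = ms.estimate_orientation(rec)
        np.testing.assert_allclose(orient.quat[:, 3], 1.0, atol=1e-9)

    def test_constant_vertical_rate_integrates_to_180_degrees(self):
        n = 201
        t = np.arange(n) / 100.0
        accel = np.tile([0.0, 0.0, 1.0], (n, 1))
        gyro = np.tile([0.0, 0.0, 90.0], (n, 1))
        rec = ms.ImuRecording(time=t, accel=accel, gyro=gyro,
                              sample_rate_hz=100.0)
        orient = ms.estimate_orientation(rec)
        yaw = Rotation.from_quat(orient.quat[-1]).as_euler("ZYX", degrees=True)[0]
        assert abs(abs(yaw) - 180.0) < 0.5

    def test_static_tilt_converges_to_accelerometer_tilt(self):
        n = 400
        t = np.arange(n) / 100.0
        a = np.array([np.sin(np.radians(30.0)), 0.0, np.cos(np.radians(30.0))])
        accel = np.tile(a, (n, 1))
        rec = ms.ImuRecording(time=t, accel=accel, gyro=np.zeros((n, 3)),
                              sample_rate_hz=100.0)
        # accelerometer init pins the tilt immediately
        orient = ms.estimate_orientation(rec)
        ch = ms.derive_channels(rec, orient)
        assert abs(ch.alpha[0] - 30.0) < 0.5
        # a deliberately wrong (level) start converges within 3 s
        rec2 = ms.ImuRecording(
            time=t,
            accel=np.vstack([[0.0, 0.0, 1.0], accel[1:]]),
            gyro=np.zeros((n, 3)), sample_rate_hz=100.0)
        orient2 = ms.estimate_orientation(rec2, init_window_s=1e-9)
        ch2 = ms.derive_channels(rec2, orient2)
        assert abs(ch2.alpha[0]) < 1e-6
        assert abs(ch2.alpha[-1] - 30.0) < 0.5  # converged within 3 s

    def test_freefall_samples_skip_correction(self):
        n = 200
        t = np.arange(n) / 100.0
        accel = np.zeros((n, 3))
        accel[:50] = [0.0, 0.0, 1.0]
        rec = ms.ImuRecording(time=t, accel=accel, gyro=np.zeros((n, 3)),
                              sample_rate_hz=100.0)
        orient = ms.estimate_orientation(rec)
        np.testing.assert_allclose(orient.quat[:, 3], 1.0, atol=1e-9)


class TestDeriveChannels:
    def test_rest_case_all_channels_near_zero(self, static_recording):
        rec = ms.preprocess(static_recording)
        ch = ms.derive_channels(rec, ms.estimate_orientation(rec))
        for name in ms.CHANNEL_ORDER:
            np.testing.assert_allclose(ch.channel(name), 0.0, atol=1e-6)

    def test_pure_vertical_rotation_decomposition(self):
        n = 400
        t = np.arange(n) / 100.0
        rate = 45.0
        accel = np.tile([0.0, 0.0, 1.0], (n, 1))
        gyro = np.tile([0.0, 0.0, rate], (n, 1))
        rec = ms.ImuRecording(time=t, accel=accel, gyro=gyro,
                              sample_rate_hz=100.0)
        ch = ms.derive_channels(rec, ms.estimate_orientation(rec))
        np.testing.assert_allclose(ch.omegav, rate, atol=1e-6)
        np.testing.assert_allclose(ch.omegah, 0.0, atol=1e-6)
        # gamma grows linearly at |rate|
        np.testing.assert_allclose(ch.gamma, rate * t, atol=0.5)

    def test_horizontal_acceleration_magnitude_is_yaw_invariant(self):
        n = 300
        t = np.arange(n) / 100.0
        m = 0.3  # g of device-frame horizontal acceleration
        for yaw_deg in (0.0, 37.0, 200.0):
            q = Rotation.from_euler("z", yaw_deg, degrees=True)
            quat = np.tile(q.as_quat(), (n, 1))
            accel = np.tile([m, 0.0, 1.0], (n, 1))
            rec = ms.ImuRecording(time=t, accel=accel, gyro=np.zeros((n, 3)),
                                  sample_rate_hz=100.0)
            ch = ms.derive_channels(rec, ms.OrientationSeries(quat))
            np.testing.assert_allclose(ch.ah, m * ms.G, rtol=1e-9)

    def test_heading_offset_leaves_ah_omegah_gamma_unchanged(self):
        rng = np.random.default_rng(3)
        n = 500
        t = np.arange(n) / 100.0
        accel = np.tile([0.0, 0.0, 1.0], (n, 1)) + 0.05 * rng.standard_normal((n, 3))
        gyro = 20.0 * rng.standard_normal((n, 3))
        rec = ms.ImuRecording(time=t, accel=accel, gyro=gyro,
                              sample_rate_hz=100.0)
        orient = ms.estimate_orientation(rec)
        ch = ms.derive_channels(rec, orient)
        offset = Rotation.from_euler("z", 73.0, degrees=True)
        quat2 = (offset * Rotation.from_quat(orient.quat)).as_quat()
        ch2 = ms.derive_channels(rec, ms.OrientationSeries(quat2))
        for name in ("ah", "omegah", "gamma"):
            np.testing.assert_allclose(ch2.channel(name), ch.channel(name),
                                       rtol=1e-6, atol=1e-6)

    def test_gravity_norm_conserved_at_rest(self):
        # tilted but static: world-frame specific-force norm stays 1 g
        n = 300
        t = np.arange(n) / 100.0
        a = np.array([np.sin(0.4), 0.0, np.cos(0.4)])
        rec = ms.ImuRecording(time=t, accel=np.tile(a, (n, 1)),
                              gyro=np.zeros((n, 3)), sample_rate_hz=100.0)
        orient = ms.estimate_orientation(rec)
        a_w = orient.as_rotation().apply(rec.accel_ms2())
        np.testing.assert_allclose(np.linalg.norm(a_w, axis=1), ms.G, rtol=0.02)

    def test_length_mismatch_rejected(self, static_recording):
        rec = ms.preprocess(static_recording)
        orient = ms.estimate_orientation(rec)
        bad = ms.OrientationSeries(orient.quat[:-5])
        with pytest.raises(KinematicsError, match="length"):
            ms.derive_channels(rec, bad)


def test_round_trip_world_signal_recovery():
    """Rotating a known world-frame motion into the device frame and back
    through the channel derivation recovers it."""
    n = 400
    t = np.arange(n) / 100.0
    yaw = 30.0 * np.sin(2 * np.pi * 0.2 * t)
    rot = Rotation.from_euler("z", yaw[:, None], degrees=True)
    a_world = np.column_stack([
        0.2 * np.sin(2 * np.pi * 1.0 * t),
        np.zeros(n),
        np.full(n, 1.0),
    ])
    accel_dev = rot.inv().apply(a_world)
    rel = rot[:-1].inv() * rot[1:]
    gyro = np.degrees(np.vstack([rel.as_rotvec() * 100.0, [[0, 0, 0]]]))
    gyro[-1] = gyro[-2]
    rec = ms.ImuRecording(time=t, accel=accel_dev, gyro=gyro,
                          sample_rate_hz=100.0)
    ch = ms.derive_channels(rec, ms.OrientationSeries(rot.as_quat()))
    np.testing.assert_allclose(ch.ah, np.abs(a_world[:, 0]) * ms.G, atol=1e-6)
    np.testing.assert_allclose(ch.gamma, np.abs(yaw), atol=1e-6)
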