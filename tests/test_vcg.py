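import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from aecg.beats import AveragedBeat, Fiducials
from aecg.exceptions import ConfigError, DomainError
from aecg.vcg import (DEFAULT_KORS, Vcg, angle_between, azimuth_elevation, derive_vcg,
                      kors_right_inverse, mean_vector, qrs_integrals_and_voltages,
                      qrs_loop_pl_ratio, sai_qrst, spatial_qrst_angles,
                      ventricular_gradient)

from conftest import make_vcg


class TestDeriveVcg:
    def test_zero_template_gives_zero_vcg(self):
        beat = AveragedBeat(np.zeros((100, 12)), 500.0, 1)
        fid = Fiducials(0, 1, 10, 40, 90)
        vcg = derive_vcg(beat, fiducials=fid)
        assert not np.any(vcg.xyz)

    def test_impulse_on_lead_ii_reads_kors_column(self):
        template = np.zeros((100, 12))
        template[50, 1] = 1.0  # lead II
        beat = AveragedBeat(template, 500.0, 1)
        vcg = derive_vcg(beat, fiducials=Fiducials(0, 1, 10, 40, 90))
        np.testing.assert_allclose(vcg.xyz[50], DEFAULT_KORS[:, 1])
        assert not np.any(np.delete(vcg.xyz, 50, axis=0))

    def test_right_inverse_roundtrip(self):
        rng = np.random.default_rng(0)
        xyz = rng.normal(size=(200, 3))
        right_inv = kors_right_inverse()
        np.testing.assert_allclose(DEFAULT_KORS @ right_inv, np.eye(3), atol=1e-12)
        from aecg.io import complete_limb_leads
        template = complete_limb_leads(xyz @ right_inv.T)
        beat = AveragedBeat(template, 500.0, 1)
        vcg = derive_vcg(beat, fiducials=Fiducials(0, 1, 10, 100, 190))
        np.testing.assert_allclose(vcg.xyz, xyz, atol=1e-10)

    def test_bad_matrix_shape_rejected(self):
        beat = AveragedBeat(np.zeros((100, 12)), 500.0, 1)
        with pytest.raises(ConfigError):
            derive_vcg(beat, kors_matrix=np.zeros((3, 7)),
                       fiducials=Fiducials(0, 1, 10, 40, 90))

    def test_z_polarity_flag(self):
        template = np.zeros((100, 12))
        template[50, 6] = 1.0  # V1, anterior: negative Z in the default convention
        beat = AveragedBeat(template, 500.0, 1)
        fid = Fiducials(0, 1, 10, 40, 90)
        default = derive_vcg(beat, fiducials=fid)
        flipped = derive_vcg(beat, fiducials=fid, z_anterior_positive=True)
        assert default.xyz[50, 2] < 0 < flipped.xyz[50, 2]


class TestAngles:
    def test_orthogonal_mean_vectors_90_degrees(self):
        n = 40
        xyz = np.zeros((n, 3))
        xyz[3:20, 0] = 1.0   # QRS along +X
        xyz[20:39, 1] = 1.0  # T along +Y
        vcg, _ = make_vcg(xyz, qrs=(3, 20), t_offset=39)
        result = spatial_qrst_angles(vcg)
        assert result.mean_angle == pytest.approx(90.0, abs=1e-9)
        assert result.peaks_angle == pytest.approx(90.0, abs=1e-9)

    def test_scaled_t_loop_gives_zero_angle(self):
        rng = np.random.default_rng(1)
        loop = rng.normal(size=(30, 3)) + 2.0
        xyz = np.vstack([loop, 0.2 * loop])
        vcg, _ = make_vcg(xyz, qrs=(0, 30), t_offset=60)
        result = spatial_qrst_angles(vcg)
        assert result.mean_angle == pytest.approx(0.0, abs=1e-6)
        assert result.peaks_angle == pytest.approx(0.0, abs=1e-6)

    def test_angle_symmetry_and_range(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            u, v = rng.normal(size=3), rng.normal(size=3)
            a = angle_between(u, v)
            assert a == pytest.approx(angle_between(v, u))
            assert 0.0 <= a <= 180.0

    def test_rotation_invariance(self):
        rng = np.random.default_rng(3)
        xyz = rng.normal(size=(60, 3))
        vcg, _ = make_vcg(xyz, qrs=(0, 30), t_offset=59)
        base = spatial_qrst_angles(vcg)
        for seed in range(5):
            rot = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
            vcg_rot, _ = make_vcg(xyz @ rot.T, qrs=(0, 30), t_offset=59)
            rotated = spatial_qrst_angles(vcg_rot)
            assert rotated.mean_angle == pytest.approx(base.mean_angle, abs=1e-8)
            assert rotated.peaks_angle == pytest.approx(base.peaks_angle, abs=1e-8)

    def test_scale_invariance_of_angles_and_ratio(self):
        rng = np.random.default_rng(4)
        xyz = rng.normal(size=(60, 3)) + np.array([1.0, 0.0, 0.5])
        vcg, _ = make_vcg(xyz, qrs=(0, 30), t_offset=59)
        scaled, _ = make_vcg(3.7 * xyz, qrs=(0, 30), t_offset=59)
        a, b = spatial_qrst_angles(vcg), spatial_qrst_angles(scaled)
        assert b.mean_angle == pytest.approx(a.mean_angle)
        assert qrs_loop_pl_ratio(scaled) == pytest.approx(qrs_loop_pl_ratio(vcg))
        assert sai_qrst(scaled) == pytest.approx(3.7 * sai_qrst(vcg))

    def test_zero_vector_angle_undefined(self):
        with pytest.raises(DomainError):
            angle_between([0, 0, 0], [1, 0, 0])

    def test_azimuth_elevation_conventions(self):
        az, el = azimuth_elevation([1.0, 0.0, 0.0])  # leftward
        assert (az, el) == (0.0, 0.0)
        az, el = azimuth_elevation([0.0, 0.0, 1.0])  # posterior
        assert az == pytest.approx(90.0)
        az, el = azimuth_elevation([0.0, 1.0, 0.0])  # inferior
        assert el == pytest.approx(90.0)


class TestVentricularGradient:
    def test_constant_integrand(self):
        # X = 1 mV over a 300 ms QRST window at 1 kHz -> 300 mV*ms leftward
        n = 301
        xyz = np.zeros((n, 3))
        xyz[:, 0] = 1.0
        vcg, _ = make_vcg(xyz, qrs=(0, 100), t_offset=n - 1)
        vcg.fiducials = Fiducials(0, 1, 3, 100, 303)  # window padded by make_vcg
        mag, az, el = ventricular_gradient(vcg)
        assert mag == pytest.approx(300.0, rel=0.02)
        assert az == pytest.approx(0.0)
        assert el == pytest.approx(0.0)

    def test_sign_flip_is_antipodal(self):
        rng = np.random.default_rng(5)
        xyz = rng.normal(size=(80, 3)) + 0.3
        vcg, _ = make_vcg(xyz, qrs=(0, 40), t_offset=79)
        flipped, _ = make_vcg(-xyz, qrs=(0, 40), t_offset=79)
        m1, az1, el1 = ventricular_gradient(vcg)
        m2, az2, el2 = ventricular_gradient(flipped)
        assert m2 == pytest.approx(m1)
        assert el2 == pytest.approx(-el1)
        assert abs(abs(az2 - az1) - 180.0) < 1e-6

    def test_trapezoid_close_to_riemann_at_500hz(self):
        from aecg.simulate import EcgSimConfig, _clean_beat_xyz
        config = EcgSimConfig()
        times = np.arange(0, 2.0, 1 / 500.0)
        xyz = _clean_beat_xyz(config, times, 1.0)
        vcg, _ = make_vcg(xyz, sampling_rate=500.0, qrs=(400, 550), t_offset=750)
        trap = ventricular_gradient(vcg)[0]
        fid = vcg.fiducials
        dt = 2.0  # ms per sample
        riemann = np.linalg.norm(
            vcg.xyz[fid.qrs_onset:fid.t_offset].sum(axis=0) * dt)
        assert abs(trap - riemann) / riemann < 0.005


class TestScalarParameters:
    def test_sai_constant_block(self):
        n = 301
        xyz = np.zeros((n, 3))
        xyz[:101, 0] = 1.0  # 1 mV for 100 ms at 1 kHz
        vcg, _ = make_vcg(xyz, qrs=(0, 150), t_offset=n - 1)
        vcg.fiducials = Fiducials(0, 1, 3, 150, 303)
        assert sai_qrst(vcg) == pytest.approx(100.0, rel=0.02)

    def test_sai_sign_invariant_and_additive(self):
        rng = np.random.default_rng(6)
        xyz = rng.normal(size=(100, 3))
        vcg, _ = make_vcg(xyz, qrs=(0, 50), t_offset=99)
        flipped, _ = make_vcg(-xyz, qrs=(0, 50), t_offset=99)
        assert sai_qrst(flipped) == pytest.approx(sai_qrst(vcg))
        # equals the sum of per-axis absolute integrals computed independently
        fid = vcg.fiducials
        t = np.arange(fid.qrs_onset, fid.t_offset) * 1000.0 / vcg.sampling_rate
        per_axis = sum(np.trapezoid(np.abs(vcg.xyz[fid.qrs_onset:fid.t_offset, k]), t)
                       for k in range(3))
        assert sai_qrst(vcg) == pytest.approx(per_axis)

    def test_pl_ratio_simple(self):
        xyz = np.zeros((20, 3))
        xyz[5, 0] = 1.0   # leftward max 1
        xyz[7, 2] = 2.0   # posterior max 2
        vcg, _ = make_vcg(xyz, qrs=(0, 10), t_offset=19)
        vcg.fiducials = Fiducials(0, 1, 3, 23, 26)
        assert qrs_loop_pl_ratio(vcg) == 2.0

    def test_pl_ratio_anterior_loop_is_zero(self):
        xyz = np.zeros((20, 3))
        xyz[:, 0] = 1.0
        xyz[:, 2] = -0.5
        vcg, _ = make_vcg(xyz, qrs=(0, 10), t_offset=19)
        assert qrs_loop_pl_ratio(vcg) == 0.0

    def test_pl_ratio_no_leftward_undefined(self):
        xyz = np.zeros((20, 3))
        xyz[:, 0] = -1.0
        vcg, _ = make_vcg(xyz, qrs=(0, 10), t_offset=19)
        with pytest.raises(DomainError):
            qrs_loop_pl_ratio(vcg)

    def test_pl_ratio_matches_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            xyz = rng.normal(size=(50, 3)) + np.array([0.5, 0.0, 0.0])
            vcg, _ = make_vcg(xyz, qrs=(0, 30), t_offset=49)
            fid = vcg.fiducials
            best_post, best_left = 0.0, -np.inf
            for i in range(fid.qrs_onset, fid.qrs_offset):
                best_post = max(best_post, vcg.xyz[i, 2])
                best_left = max(best_left, vcg.xyz[i, 0])
            if best_left <= 0:
                continue
            assert qrs_loop_pl_ratio(vcg) == pytest.approx(best_post / best_left)

    def test_z_integral_constant_negative(self):
        n = 201
        xyz = np.zeros((n, 3))
        xyz[:104, 2] = -1.0
        vcg, beat = make_vcg(xyz, qrs=(0, 101), t_offset=n - 1)
        z_int, _ = qrs_integrals_and_voltages(beat, vcg)
        assert z_int == pytest.approx(-100.0, rel=0.02)

    def test_total_voltage_biphasic_leads(self):
        template = np.zeros((100, 12))
        template[30, :] = 0.5
        template[40, :] = -0.5
        beat = AveragedBeat(template, 1000.0, 1)
        xyz = np.zeros((100, 3))
        vcg = Vcg(xyz, 1000.0, Fiducials(0, 1, 10, 60, 90))
        _, total = qrs_integrals_and_voltages(beat, vcg)
        assert total == pytest.approx(12.0)

    def test_total_voltage_matches_per_lead_oracle(self):
        rng = np.random.default_rng(8)
        template = rng.normal(size=(120, 12))
        beat = AveragedBeat(template, 500.0, 1)
        fid = Fiducials(0, 1, 20, 80, 110)
        vcg = derive_vcg(beat, fiducials=fid)
        _, total = qrs_integrals_and_voltages(beat, vcg)
        oracle = sum(template[20:80, k].max() - template[20:80, k].min()
                     for k in range(12))
        assert total == pytest.approx(oracle)


def test_mean_vector_of_constant_signal():
    xyz = np.ones((50, 3)) * np.array([2.0, -1.0, 0.5])
    vcg, _ = make_vcg(xyz, qrs=(0, 25), t_offset=49)
    np.testing.assert_allclose(mean_vector(vcg, 3, 28), [2.0, -1.0, 0.5])
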