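"""Volumetric primitives: rotations, poses, Fourier filters, resampling, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npcensus.errors import ParameterError
from npcensus.volumes import (FULL_WEDGE, Pose, Rotation, Volume, WedgeSpec,
                              apply_missing_wedge, bin_volume, lowpass,
                              make_inplane_grid, make_rotation_grid, read_mrc,
                              read_particle_table, transform, wedge_zero_fraction,
                              write_mrc, write_particle_table)


def smooth_noise(shape=(32, 32, 32), seed=0, sigma=2.0):
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    return Volume(gaussian_filter(rng.normal(size=shape), sigma).astype(np.float32), 2.0)


class TestVolume:
    def test_invariants(self):
        with pytest.raises(ParameterError):
            Volume(np.zeros((4, 16, 16)))          # dimension below 8
        with pytest.raises(ParameterError):
            Volume(np.full((16, 16, 16), np.nan))  # non-finite
        with pytest.raises(ParameterError):
            Volume(np.zeros((16, 16, 16)), voxel_size_nm=0.0)

    def test_center_convention(self):
        v = Volume(np.zeros((16, 12, 10)), 2.0)
        assert np.array_equal(v.center_xyz, [5, 6, 8])


class TestRotation:
    @pytest.mark.parametrize("inc,count", [(360.0, 1), (90.0, 48), (10.0, 24624)])
    def test_grid_counts(self, inc, count):
        grid = make_rotation_grid(inc)
        assert len(grid) == count
        if inc == 360.0:
            assert grid[0] == Rotation.identity()

    def test_grid_rejects_bad_increment(self):
        for bad in (0.0, -5.0, np.nan, 400.0):
            with pytest.raises(ParameterError):
                make_rotation_grid(bad)

    def test_roundtrip_1000_random(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            r = Rotation(rng.uniform(0, 360), rng.uniform(0, 180), rng.uniform(0, 360))
            m = r.as_matrix() @ r.inverse().as_matrix()
            assert np.abs(m - np.eye(3)).max() < 1e-9

    def test_normalisation(self):
        r = Rotation(-30.0, 200.0, 370.0)
        assert 0 <= r.phi < 360 and 0 <= r.theta <= 180 and 0 <= r.psi < 360

    def test_geodesic(self):
        assert Rotation.about_z(30).geodesic_deg(Rotation.about_z(40)) == pytest.approx(10, abs=1e-9)

    def test_inplane_grid(self):
        grid = make_inplane_grid(45.0)
        assert len(grid) == 8
        assert all(r.theta == 0 for r in grid)


class TestPose:
    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=3),
           st.floats(0, 360), st.floats(0, 180), st.floats(0, 360))
    @settings(max_examples=50, deadline=None)
    def test_point_roundtrip(self, shift, phi, theta, psi):
        p = Pose(shift=np.array(shift), rotation=Rotation(phi, theta, psi))
        x = np.array([1.3, -2.1, 0.7])
        back = p.inverse().apply_point(p.apply_point(x))
        assert np.abs(back - x).max() < 1e-6

    def test_compose(self):
        a = Pose(shift=np.array([1.0, 0, 0]), rotation=Rotation.about_z(90))
        b = Pose(shift=np.array([0, 2.0, 0]), rotation=Rotation.about_z(45))
        x = np.array([0.5, 0.5, 0.5])
        assert np.abs(a.compose(b).apply_point(x) - a.apply_point(b.apply_point(x))).max() < 1e-9


class TestWedge:
    def test_validation(self):
        with pytest.raises(ParameterError):
            WedgeSpec(40, -40)
        with pytest.raises(ParameterError):
            WedgeSpec(-100, 40)

    def test_full_coverage_identity(self, rng):
        v = Volume(rng.normal(size=(32, 32, 32)).astype(np.float32), 2.0)
        out = apply_missing_wedge(v, FULL_WEDGE)
        assert np.abs(out.data - v.data).max() < 1e-5 * np.abs(v.data).max()

    def test_study_wedge_zero_fraction(self):
        frac = wedge_zero_fraction((64, 64, 64), WedgeSpec(-52, 64))
        assert frac == pytest.approx((180 - 116) / 180, abs=0.01)

    def test_zero_fraction_random_wedges(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            lo = rng.uniform(-80, -20)
            hi = rng.uniform(20, 80)
            frac = wedge_zero_fraction((48, 48, 48), WedgeSpec(lo, hi))
            assert frac == pytest.approx((180 - (hi - lo)) / 180, abs=0.01)

    def test_idempotent(self, rng):
        v = Volume(rng.normal(size=(32, 32, 32)).astype(np.float32), 2.0)
        w = WedgeSpec(-52, 64)
        once = apply_missing_wedge(v, w)
        twice = apply_missing_wedge(once, w)
        assert np.abs(twice.data - once.data).max() < 1e-6 * np.abs(once.data).max()

    def test_constant_volume_unchanged(self):
        v = Volume(np.full((16, 16, 16), 3.5, dtype=np.float32), 2.0)
        out = apply_missing_wedge(v, WedgeSpec(-52, 64))
        assert np.abs(out.data - 3.5).max() < 1e-5


class TestLowpass:
    def test_projection_and_mean(self, rng):
        v = Volume(rng.normal(size=(32, 32, 32)), 2.0)
        lp = lowpass(v, 8.0)
        lp2 = lowpass(lp, 8.0)
        assert np.abs(lp2.data - lp.data).max() < 1e-6 * np.abs(lp.data).max()
        assert lp.data.mean() == pytest.approx(v.data.mean(), rel=1e-9)

    def test_variance_reduction_at_nyquist(self, rng):
        v = Volume(rng.normal(size=(32, 32, 32)), 2.0)
        assert lowpass(v, 4.0).data.var() < v.data.var()

    def test_constant_unchanged(self):
        v = Volume(np.full((16, 16, 16), 2.0), 1.0)
        assert np.abs(lowpass(v, 4.0).data - 2.0).max() < 1e-6

    def test_sub_nyquist_rejected(self):
        v = Volume(np.zeros((16, 16, 16)), 2.0)
        with pytest.raises(ParameterError):
            lowpass(v, 3.0)

    def test_sinusoid_attenuation(self):
        # 2.5 nm period at 1 nm voxels, cutoff 5 nm: amplitude drops > 90%
        n = 40
        z = np.arange(n)
        v = Volume(np.broadcast_to(np.sin(2 * np.pi * z / 2.5), (n, n, n)).copy(), 1.0)
        out = lowpass(v, 5.0)
        assert np.abs(out.data).max() < 0.1 * np.abs(v.data).max()


class TestTransform:
    def test_identity_bitwise(self, rng):
        v = Volume(rng.normal(size=(16, 16, 16)).astype(np.float32), 2.0)
        assert np.array_equal(transform(v, Pose()).data, v.data)

    def test_integer_shift_exact(self, rng):
        v = Volume(rng.normal(size=(32, 32, 32)).astype(np.float32), 2.0)
        out = transform(v, Pose(shift=np.array([3.0, -2.0, 1.0])))
        # output(x) = input(x - shift) in (x, y, z); arrays are (z, y, x)
        assert np.allclose(out.data[5:25, 5:25, 5:25], v.data[4:24, 7:27, 2:22])

    def test_axis_rotation_moves_blob(self):
        v = np.zeros((32, 32, 32), dtype=np.float32)
        v[16, 16, 24] = 1.0  # blob at x = +8 from center
        out = transform(Volume(v, 2.0), Pose(rotation=Rotation.about_z(90.0)))
        z, y, x = np.unravel_index(np.argmax(out.data), out.data.shape)
        assert abs(x - 16) <= 0.5 and abs(y - 24) <= 0.5 and z == 16

    def test_roundtrip_correlation(self):
        v = smooth_noise(seed=5)
        p = Pose(shift=np.array([1.5, -2.0, 0.5]), rotation=Rotation(20, 30, 40))
        back = transform(transform(v, p), p.inverse())
        # compare inside the central sphere: cube corners legitimately sample
        # out-of-grid fill under rotation
        zz, yy, xx = np.indices(v.shape)
        m = ((xx - 16) ** 2 + (yy - 16) ** 2 + (zz - 16) ** 2) <= 10**2
        cc = np.corrcoef(v.data[m], back.data[m])[0, 1]
        assert cc >= 0.99


class TestIO:
    def test_mrc_roundtrip(self, tmp_path, rng):
        v = Volume(rng.normal(size=(20, 16, 12)).astype(np.float32), 2.0)
        path = tmp_path / "vol.mrc"
        write_mrc(v, path)
        back = read_mrc(path)
        assert back.data.shape == v.data.shape
        assert np.allclose(back.data, v.data)
        assert back.voxel_size_nm == pytest.approx(2.0, rel=1e-5)

    def test_particle_table_roundtrip(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame({"id": [0, 1], "x": [1.0, 2.0], "y": [3.0, 4.0],
                           "z": [5.0, 6.0], "phi": [0.0, 90.0], "theta": [0.0, 45.0],
                           "psi": [10.0, 20.0], "score": [0.9, 0.8],
                           "class": ["kept", "kept"]})
        path = tmp_path / "particles.csv"
        write_particle_table(df, path)
        back = read_particle_table(path)
        assert len(back) == 2 and back.x.tolist() == [1.0, 2.0]

    def test_particle_table_missing_columns(self, tmp_path):
        import pandas as pd

        with pytest.raises(ParameterError):
            write_particle_table(pd.DataFrame({"x": [1.0]}), tmp_path / "bad.csv")

    def test_bin_volume(self, rng):
        v = Volume(rng.normal(size=(16, 16, 16)), 1.0)
        b = bin_volume(v, 2)
        assert b.shape == (8, 8, 8) and b.voxel_size_nm == 2.0
        assert b.data[0, 0, 0] == pytest.approx(v.data[:2, :2, :2].mean())
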