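"""Map algebra: summation, normalization, subtraction, carving,
filtering, interpolation and rigid transformation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from emdamage.model import Atom, AtomicModel, DensityMap, FrameStack
from emdamage.mapops import (
    carve_spheres,
    interpolate,
    lowpass_filter,
    normalize_rms,
    subtract_maps,
    sum_frames,
    transform_map,
)
from emdamage.synthetic import simulate_map


def random_map(rng, shape=(8, 9, 10), voxel=0.5, origin=(0, 0, 0)):
    return DensityMap(rng.normal(size=shape), voxel, origin)


def make_stack(rng, n_frames, fluence_per_frame=83.0 / 50):
    frames = [random_map(rng) for _ in range(n_frames)]
    return FrameStack(frames, fluence_per_frame)


class TestSumFrames:
    def test_full_stack_accumulates_total_fluence(self, rng):
        stack = make_stack(rng, 50, 83.0 / 50)
        out = sum_frames(stack, 1, 50)
        assert out.meta["fluence"] == pytest.approx(83.0)

    def test_single_frame_unchanged(self, rng):
        stack = make_stack(rng, 3)
        out = sum_frames(stack, 2, 2)
        assert np.array_equal(out.grid, stack.frames[1].grid)

    def test_two_frames_equal_voxelwise_addition(self, rng):
        stack = make_stack(rng, 2)
        out = sum_frames(stack, 1, 2)
        assert np.allclose(
            out.grid, stack.frames[0].grid + stack.frames[1].grid
        )

    def test_out_of_range_rejected(self, rng):
        stack = make_stack(rng, 3)
        with pytest.raises(ValueError):
            sum_frames(stack, 1, 4)
        with pytest.raises(ValueError):
            sum_frames(stack, 0, 2)


class TestNormalizeRMS:
    def test_self_normalization_is_identity(self, rng):
        m = random_map(rng)
        out = normalize_rms(m, m)
        assert np.allclose(out.grid, m.grid, rtol=1e-12)

    def test_double_of_reference_restored(self, rng):
        ref = random_map(rng)
        target = ref.copy()
        target.grid *= 2.0
        out = normalize_rms(target, ref)
        assert np.allclose(out.grid, ref.grid, rtol=1e-12)

    def test_rms_matches_reference(self, rng):
        a, b = random_map(rng), random_map(rng)
        out = normalize_rms(a, b)
        assert out.rms == pytest.approx(b.rms, rel=1e-10)

    def test_idempotent(self, rng):
        a, b = random_map(rng), random_map(rng)
        once = normalize_rms(a, b)
        twice = normalize_rms(once, b)
        assert np.allclose(twice.grid, once.grid, rtol=1e-12)

    def test_zero_map_rejected(self, rng):
        zero = DensityMap(np.zeros((3, 3, 3)), 1.0, (0, 0, 0))
        with pytest.raises(ValueError):
            normalize_rms(zero, random_map(rng))


class TestSubtract:
    def test_self_subtraction_zero(self, rng):
        m = random_map(rng)
        assert np.all(subtract_maps(m, m).grid == 0.0)

    def test_subtract_then_add_restores(self, rng):
        a, b = random_map(rng), random_map(rng)
        diff = subtract_maps(a, b)
        assert np.allclose(diff.grid + b.grid, a.grid, atol=0)

    @pytest.mark.parametrize(
        "field,mutate",
        [
            ("shape", lambda r: random_map(r, shape=(8, 9, 11))),
            ("voxel_size", lambda r: random_map(r, voxel=0.6)),
            ("origin", lambda r: random_map(r, origin=(1, 0, 0))),
        ],
    )
    def test_geometry_mismatch_names_field(self, rng, field, mutate):
        with pytest.raises(ValueError, match=field):
            subtract_maps(random_map(rng), mutate(rng))

    def test_difference_map_reveals_lost_disulfide_partner(self):
        """Low-dose minus high-dose density shows strong positive signal
        at the site of the atom lost in the high-dose arm."""
        intact = AtomicModel([
            Atom("S", "SG1", "SG", "CYS", "C", 1, (5.0, 6.0, 6.0), 1.0, 15.0),
            Atom("S", "SG2", "SG", "CYS", "C", 2, (5.0, 8.05, 6.0), 1.0, 15.0),
        ])
        broken = AtomicModel([a.copy() for a in intact])
        broken.atoms[1].occ = 0.0
        shape = (32, 32, 32)
        low = simulate_map(intact, shape, 0.45)
        high = simulate_map(broken, shape, 0.45)
        diff = subtract_maps(low, normalize_rms(high, low))
        val = interpolate(diff, (5.0, 8.05, 6.0))
        assert val >= 4.0 * diff.sigma


class TestCarve:
    def test_radius_zero_leaves_map(self, rng):
        m = random_map(rng)
        out = carve_spheres(m, [(1.13, 2.21, 0.77)], 0.0)
        assert np.array_equal(out.grid, m.grid)

    def test_gaussian_fully_removed_and_mass_matches_bruteforce(self):
        atom = Atom("O", "O1", "O1", "OEC", "A", 1, (7.2, 7.2, 7.2), 1.0, 12.8)
        m = simulate_map(AtomicModel([atom]), (40, 40, 40), 0.36)
        sigma_w = np.sqrt(12.8 / (8 * np.pi**2))
        radius = 3.0 * sigma_w
        out = carve_spheres(m, [atom.xyz], radius)
        # brute-force voxel loop oracle for the removed mass
        removed = 0.0
        inside_max = 0.0
        for i in range(40):
            for j in range(40):
                for k in range(40):
                    p = np.array([i, j, k]) * 0.36
                    if np.linalg.norm(p - atom.xyz) <= radius:
                        removed += m.grid[i, j, k]
                        inside_max = max(inside_max, out.grid[i, j, k])
        assert inside_max == 0.0
        assert m.grid.sum() - out.grid.sum() == pytest.approx(removed, rel=1e-12)

    def test_mass_removed_monotone_in_radius(self, toy_map, cluster_fragment):
        metals = cluster_fragment.positions(
            cluster_fragment.selection("metals")
        )
        masses = [
            carve_spheres(toy_map, metals, r).grid.sum()
            for r in (0.0, 0.5, 0.75, 1.5)
        ]
        assert all(b <= a for a, b in zip(masses, masses[1:]))


class TestLowpass:
    def test_bandlimited_map_unchanged(self, rng):
        # content band-limited at 8 Å lies fully below the cosine ramp of a
        # 3 Å filter on this grid (ramp width 5 Fourier voxels = 0.156 1/Å)
        m = random_map(rng, shape=(64, 64, 64))
        smooth = lowpass_filter(m, 8.0)
        again = lowpass_filter(smooth, 3.0)
        delta = np.abs(again.grid - smooth.grid).max()
        assert delta < 1e-8 * np.abs(smooth.grid).max()

    def test_out_of_band_power_suppressed(self, rng):
        m = random_map(rng, shape=(48, 48, 48), voxel=0.5)
        res = 2.0
        out = lowpass_filter(m, res)
        F = np.fft.fftn(out.grid)
        freqs = np.fft.fftfreq(48, d=0.5)
        fx, fy, fz = np.meshgrid(freqs, freqs, freqs, indexing="ij")
        fmag = np.sqrt(fx**2 + fy**2 + fz**2)
        p_out = np.sum(np.abs(F[fmag > 1.0 / res]) ** 2)
        p_in = np.sum(np.abs(F[fmag <= 1.0 / res]) ** 2)
        assert p_out < 0.01 * p_in

    def test_mean_preserved(self, rng):
        m = random_map(rng, shape=(24, 24, 24))
        m.grid += 3.7
        out = lowpass_filter(m, 3.0)
        assert out.mean == pytest.approx(m.mean, rel=1e-10)

    def test_sub_nyquist_rejected(self, rng):
        m = random_map(rng, voxel=1.0)
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_filter(m, 1.5)


class TestInterpolate:
    def test_voxel_center_exact(self, rng):
        m = random_map(rng)
        assert interpolate(m, m.index_to_xyz((3, 4, 5))) == pytest.approx(
            m.grid[3, 4, 5], rel=1e-14
        )

    def test_axis_midpoint_is_mean(self, rng):
        m = random_map(rng)
        p = m.index_to_xyz((3.5, 4, 5))
        assert interpolate(m, p) == pytest.approx(
            0.5 * (m.grid[3, 4, 5] + m.grid[4, 4, 5]), rel=1e-12
        )

    def test_random_points_match_bruteforce_reference(self, rng):
        m = random_map(rng, shape=(10, 10, 10), voxel=0.7, origin=(-1, 2, 0))
        pts = m.index_to_xyz(rng.uniform(0, 9, size=(100, 3)))
        got = interpolate(m, pts)
        for p, v in zip(pts, got):
            idx = m.xyz_to_index(p)
            i0 = np.floor(idx).astype(int)
            f = idx - i0
            ref = 0.0
            for di in (0, 1):
                for dj in (0, 1):
                    for dk in (0, 1):
                        w = (
                            (f[0] if di else 1 - f[0])
                            * (f[1] if dj else 1 - f[1])
                            * (f[2] if dk else 1 - f[2])
                        )
                        ref += w * m.grid[i0[0] + di, i0[1] + dj, i0[2] + dk]
            assert v == pytest.approx(ref, abs=1e-12)

    def test_out_of_bounds_rejected(self, rng):
        m = random_map(rng)
        with pytest.raises(ValueError, match="outside"):
            interpolate(m, (-1.0, 0.0, 0.0))


def rot_z_90():
    return np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])


class TestTransform:
    def test_identity_is_identity(self, rng):
        m = random_map(rng)
        out = transform_map(m, np.eye(3), (0, 0, 0))
        assert np.allclose(out.grid, m.grid, atol=1e-12)

    def test_rot90_is_exact_index_permutation(self, rng):
        n = 12
        m = DensityMap(rng.normal(size=(n, n, n)), 0.5, (0, 0, 0))
        c = (n - 1) / 2.0 * 0.5  # box center
        R = rot_z_90()
        t = np.array([c, c, c]) - R @ np.array([c, c, c])
        out = transform_map(m, R, t)
        # oracle: output voxel (i,j,k) samples the input at the
        # back-rotated index, which for +90 deg about z is (j, n-1-i, k)
        expected = np.transpose(m.grid, (1, 0, 2))[::-1, :, :]
        assert np.allclose(out.grid, expected, atol=1e-9)

    def test_round_trip_correlates_on_smooth_map(self, toy_map):
        # band-limit first: trilinear resampling is only faithful for
        # features broad relative to the voxel
        toy_map = lowpass_filter(toy_map, 2.0)
        theta = 0.3
        R = np.array([
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ])
        center = toy_map.index_to_xyz((np.array(toy_map.shape) - 1) / 2.0)
        t = center - R @ center
        fwd = transform_map(toy_map, R, t)
        back = transform_map(fwd, R.T, -R.T @ t)
        a, b = toy_map.grid.ravel(), back.grid.ravel()
        corr = np.corrcoef(a, b)[0, 1]
        assert corr > 0.999

    def test_non_orthonormal_rejected(self, rng):
        m = random_map(rng)
        with pytest.raises(ValueError, match="orthonormal"):
            transform_map(m, np.eye(3) * 1.1, (0, 0, 0))


@given(st.floats(0.1, 10.0), st.floats(0.1, 10.0))
def test_normalize_scale_invariance(s1, s2):
    """RMS normalization depends only on the shape of the maps, not their
    absolute scales."""
    rng = np.random.default_rng(0)
    a = random_map(rng)
    b = random_map(rng)
    out1 = normalize_rms(a, b)
    a2 = a.copy()
    a2.grid *= s1
    b2 = b.copy()
    b2.grid *= s2
    out2 = normalize_rms(a2, b2)
    assert np.allclose(out2.grid, s2 * out1.grid, rtol=1e-9)
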