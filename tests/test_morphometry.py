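"""3D morphometry: each index against analytic phantoms and brute-force oracles."""

import math

import numpy as np
import pytest

from conftest import euler_characteristic_bruteforce, local_thickness_bruteforce
from stromakit import morphometry as m
from stromakit import synthetic as syn
from stromakit.errors import (
    DegenerateInputError,
    EmptyStructureError,
    InsufficientScalesError,
    TooSmallError,
)
from stromakit.types import BoxCountConfig, VoxelVolume


def _cylinder(shape=(48, 24, 24), radius=3.0, value_in=1.0, value_out=0.0):
    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    mask = (yy - shape[1] / 2) ** 2 + (xx - shape[2] / 2) ** 2 <= radius**2
    return np.where(mask, value_in, value_out).astype(float), mask


class TestFrangi:
    def test_bright_cylinder_scores_above_background(self):
        gray, mask = _cylinder()
        score = m.frangi_tubularity(gray, scales=[2.0, 3.0])
        zz, yy, xx = np.mgrid[0:48, 0:24, 0:24]
        on_axis = (yy == 12) & (xx == 12) & (zz > 5) & (zz < 43)
        far_background = (yy - 12) ** 2 + (xx - 12) ** 2 > 8**2
        assert score[on_axis].mean() > 10 * max(score[far_background].mean(), 1e-12)

    def test_constant_volume_scores_zero(self):
        assert np.all(m.frangi_tubularity(np.full((8, 8, 8), 3.0)) == 0)

    def test_ball_less_tubular_than_cylinder(self):
        gray_c, _ = _cylinder((32, 32, 32), radius=4.0)
        ball, _ = syn.make_geometric_phantom("ball", (32, 32, 32), radius=4)
        score_c = m.frangi_tubularity(gray_c, scales=[4.0])
        score_b = m.frangi_tubularity(ball.occupancy.astype(float), scales=[4.0])
        assert score_c[16, 16, 16] > score_b[16, 16, 16]

    def test_too_small_grid_rejected(self):
        with pytest.raises(TooSmallError):
            m.frangi_tubularity(np.zeros((4, 8, 8)))


class TestBinarize:
    def test_otsu_splits_bimodal_volume(self):
        gray, mask = _cylinder(value_in=10.0, value_out=1.0)
        vol = m.binarize(gray)
        assert np.array_equal(vol.occupancy, mask)

    def test_fixed_threshold_identity_on_binary(self):
        occ = np.zeros((8, 8, 8))
        occ[2:5] = 1.0
        vol = m.binarize(occ, method=0.5)
        assert np.array_equal(vol.occupancy, occ.astype(bool))

    def test_otsu_constant_volume_rejected(self):
        with pytest.raises(DegenerateInputError):
            m.binarize(np.zeros((8, 8, 8)))

    def test_noisy_rods_recover_volume_fraction(self, rods_small):
        vol, truth = rods_small
        rng = np.random.default_rng(0)
        gray = vol.occupancy.astype(float) + rng.normal(0, 0.2, vol.shape)
        rebin = m.binarize(gray)
        assert m.volume_fraction(rebin) == pytest.approx(
            truth["realized_vol_fraction"], abs=0.03
        )


class TestVolumeFraction:
    def test_endpoints_and_half_slab(self):
        assert m.volume_fraction(VoxelVolume(np.ones((4, 4, 4), bool))) == 1.0
        occ = np.zeros((4, 4, 4), bool)
        occ[:2] = True
        assert m.volume_fraction(VoxelVolume(occ)) == 0.5

    def test_rods_match_analytic(self, rods_small):
        vol, truth = rods_small
        assert m.volume_fraction(vol) == pytest.approx(
            truth["analytic_vol_fraction"], rel=0.05
        )


class TestThicknessSpacing:
    def test_ball_thickness_matches_bruteforce(self):
        ball, _ = syn.make_geometric_phantom("ball", (48, 48, 48), radius=14)
        th = m.local_thickness(ball)
        oracle = local_thickness_bruteforce(ball.occupancy)
        fg = ball.occupancy
        assert th[fg].mean() == pytest.approx(oracle[fg].mean(), rel=0.10)
        assert th[fg].mean() == pytest.approx(28.0, rel=0.10)

    def test_slab_thickness_matches_bruteforce(self):
        occ = np.zeros((24, 24, 24), bool)
        occ[:, :, 9:14] = True
        vol = VoxelVolume(occ)
        oracle = local_thickness_bruteforce(occ)
        assert m.mean_thickness(vol) == pytest.approx(oracle[occ].mean(), rel=0.10)

    def test_one_voxel_plane_is_one_step_thick(self):
        plane, _ = syn.make_geometric_phantom("plane", (24, 24, 24))
        assert m.mean_thickness(plane) == pytest.approx(2.0, abs=1.0)

    def test_spacing_is_thickness_of_complement(self, rods_small):
        vol, _ = rods_small
        assert m.mean_spacing(vol) == m.mean_thickness(vol.complement())

    def test_spacing_monotone_in_pitch(self):
        spacings = []
        for pitch in (12.0, 16.0, 24.0):
            vol, _ = syn.make_parallel_rods((48, 48, 48), 4.0, pitch, "z")
            spacings.append(m.mean_spacing(vol))
        assert spacings == sorted(spacings)

    def test_empty_foreground_rejected(self):
        with pytest.raises(EmptyStructureError):
            m.mean_thickness(VoxelVolume(np.zeros((4, 4, 4), bool)))
        with pytest.raises(EmptyStructureError):
            m.mean_spacing(VoxelVolume(np.ones((4, 4, 4), bool)))

    def test_voxel_size_scales_thickness(self):
        ball, _ = syn.make_geometric_phantom("ball", (32, 32, 32), radius=10)
        scaled = VoxelVolume(ball.occupancy, voxel_size_um=0.89)
        assert m.mean_thickness(scaled) == pytest.approx(0.89 * m.mean_thickness(ball))


class TestMILAnisotropy:
    def test_parallel_rods_near_extreme(self):
        vol, _ = syn.make_parallel_rods((96, 96, 96), 4.0, 16.0, "z")
        res = m.mil_anisotropy(vol, n_directions=256, seed=7)
        assert res.da >= 0.9

    def test_random_spheres_near_isotropic(self):
        vol, _ = syn.make_random_spheres((96, 96, 96), 6.0, 0.3, seed=11)
        res = m.mil_anisotropy(vol, n_directions=256, seed=7)
        assert res.da <= 0.2

    def test_axis_permutation_invariance(self):
        vol, _ = syn.make_random_spheres((64, 64, 64), 6.0, 0.3, seed=2)
        base = m.mil_anisotropy(vol, n_directions=128, seed=1).da
        for perm in [(1, 0, 2), (2, 1, 0)]:
            permuted = VoxelVolume(np.transpose(vol.occupancy, perm))
            da = m.mil_anisotropy(permuted, n_directions=128, seed=1).da
            assert da == pytest.approx(base, abs=0.02)

    def test_da_monotone_in_fiber_concentration(self):
        das = []
        for conc in (0.0, 2.0, 1e6):
            spec = syn.FiberPhantomSpec(
                grid_shape=(64, 64, 64), orientation_concentration=conc, seed=4,
            )
            vol, _ = syn.make_fiber_phantom(spec)
            das.append(m.mil_anisotropy(vol, n_directions=128, seed=1).da)
        assert das == sorted(das)
        assert das[-1] >= 0.9

    def test_single_phase_rejected(self):
        with pytest.raises(EmptyStructureError):
            m.mil_anisotropy(VoxelVolume(np.ones((8, 8, 8), bool)))


class TestEulerConnectivity:
    @pytest.mark.parametrize(
        "kind,params,expected_chi,expected_conn",
        [
            ("ball", {"radius": 5}, 1, 0),
            ("torus", {"major_radius": 6, "minor_radius": 2.5}, 0, 1),
            ("two_balls", {"radius": 4}, 2, -1),
        ],
    )
    def test_interior_solids_match_bruteforce(self, kind, params, expected_chi, expected_conn):
        vol, _ = syn.make_geometric_phantom(kind, (20, 20, 20), **params)
        chi, conn, _ = m.euler_connectivity(vol)
        assert chi == euler_characteristic_bruteforce(vol.occupancy) == expected_chi
        assert conn == expected_conn

    def test_additivity_over_disjoint_union(self):
        rng = np.random.default_rng(0)
        a = rng.random((8, 8, 8)) > 0.7
        b = rng.random((8, 8, 8)) > 0.7
        combined = np.zeros((8, 20, 8), bool)
        combined[:, :8] = a
        combined[:, 12:] = b
        chi_a = euler_characteristic_bruteforce(a)
        chi_b = euler_characteristic_bruteforce(b)
        chi_c, _, _ = m.euler_connectivity(VoxelVolume(combined))
        assert chi_c == chi_a + chi_b

    def test_interior_structure_has_zero_edge_correction(self):
        vol, _ = syn.make_geometric_phantom("ball", (16, 16, 16), radius=4)
        chi, conn, _ = m.euler_connectivity(vol)
        assert conn == 1 - chi  # delta-chi vanishes away from the border

    def test_conn_density_uses_physical_volume(self):
        vol, _ = syn.make_geometric_phantom("torus", (20, 20, 20),
                                            major_radius=6, minor_radius=2.5)
        scaled = VoxelVolume(vol.occupancy, voxel_size_um=2.0)
        _, _, cd1 = m.euler_connectivity(vol)
        _, _, cd2 = m.euler_connectivity(scaled)
        assert cd2 == pytest.approx(cd1 / 8.0)


class TestFractalDimension:
    def test_filled_volume_dimension_three(self):
        vol, _ = syn.make_geometric_phantom("filled", (128, 128, 128))
        fr, table = m.fractal_dimension(vol)
        assert fr == pytest.approx(3.0, abs=0.05)
        assert len(table) >= 3

    def test_plane_dimension_two(self):
        vol, _ = syn.make_geometric_phantom("plane", (128, 128, 128))
        fr, _ = m.fractal_dimension(vol)
        assert fr == pytest.approx(2.0, abs=0.05)

    def test_ordering_plane_menger_filled(self):
        fr_plane, _ = m.fractal_dimension(syn.make_geometric_phantom("plane", (81,) * 3)[0])
        fr_menger, _ = m.fractal_dimension(
            syn.make_geometric_phantom("menger", (81,) * 3, level=4)[0]
        )
        fr_filled, _ = m.fractal_dimension(syn.make_geometric_phantom("filled", (81,) * 3)[0])
        assert fr_plane < fr_menger < fr_filled

    def test_permutation_invariance(self):
        vol, _ = syn.make_parallel_rods((64, 64, 64), 4.0, 16.0, "z")
        fr, _ = m.fractal_dimension(vol)
        fr_p, _ = m.fractal_dimension(VoxelVolume(np.transpose(vol.occupancy, (2, 0, 1))))
        assert fr_p == pytest.approx(fr, abs=1e-9)

    def test_initial_box_shrinks_to_small_grid(self):
        vol, _ = syn.make_geometric_phantom("filled", (32, 32, 32))
        fr, table = m.fractal_dimension(vol)
        assert fr == pytest.approx(3.0, abs=0.05)
        assert table[0]["nominal_box_px"] <= 32

    def test_too_few_scales_rejected(self):
        vol, _ = syn.make_geometric_phantom("filled", (8, 8, 8))
        with pytest.raises(InsufficientScalesError):
            m.fractal_dimension(vol, BoxCountConfig(initial_box_px=8, smallest_box_px=7))


class TestSkeleton:
    def test_straight_rod_single_branch_length(self):
        occ = np.zeros((64, 16, 16), bool)
        zz, yy, xx = np.mgrid[0:64, 0:16, 0:16]
        occ[(yy - 8) ** 2 + (xx - 8) ** 2 <= 9] = True
        lengths, mean_len = m.skeleton_fiber_lengths(VoxelVolume(occ))
        assert len(lengths) == 1
        assert mean_len == pytest.approx(63.0, rel=0.05)

    def test_t_tube_three_branches(self):
        occ = np.zeros((48, 48, 12), bool)
        occ[8:40, 22:27, 4:9] = True
        occ[20:25, 8:27, 4:9] = True
        lengths, _ = m.skeleton_fiber_lengths(VoxelVolume(occ), min_component_voxels=1)
        assert len(lengths) == 3

    def test_l_tube_single_branch(self):
        occ = np.zeros((48, 48, 12), bool)
        occ[8:40, 22:27, 4:9] = True
        occ[35:40, 22:45, 4:9] = True
        lengths, _ = m.skeleton_fiber_lengths(VoxelVolume(occ), min_component_voxels=1)
        assert len(lengths) == 1

    def test_noise_floor_removes_specks(self):
        occ = np.zeros((32, 32, 32), bool)
        occ[4:28, 13:18, 13:18] = True  # one real bundle (odd cross-section)
        occ[2, 2, 2] = True  # speck
        lengths, _ = m.skeleton_fiber_lengths(VoxelVolume(occ), min_component_voxels=27)
        assert len(lengths) == 1

    def test_empty_volume_rejected(self):
        with pytest.raises(EmptyStructureError):
            m.skeleton_fiber_lengths(VoxelVolume(np.zeros((8, 8, 8), bool)))


class TestSummary:
    def test_rods_composite(self, rods_small):
        vol, truth = rods_small
        s = m.morphometry_summary(vol, n_directions=128, seed=3)
        assert s.vol_fraction == pytest.approx(truth["analytic_vol_fraction"], rel=0.05)
        assert s.da >= 0.9
        assert 2.0 <= s.fr_dim <= 3.0
        assert s.thickness_um == pytest.approx(8.0, rel=0.15)

    def test_filled_volume_flagged_degenerate(self):
        vol, _ = syn.make_geometric_phantom("filled", (32, 32, 32))
        s = m.morphometry_summary(vol)
        assert s.vol_fraction == 1.0
        assert "full_foreground" in s.flags
        assert "spacing_degenerate_full_volume" in s.flags

    def test_same_seed_identical_summary(self, rods_small):
        vol, _ = rods_small
        a = m.morphometry_summary(vol, n_directions=64, seed=5)
        b = m.morphometry_summary(vol, n_directions=64, seed=5)
        assert a.as_dict() == b.as_dict()

    def test_fiber_phantom_estimator_recovery(self):
        spec = syn.FiberPhantomSpec(
            grid_shape=(64, 64, 64), fiber_radius_um=3.0,
            target_volume_fraction=0.25, orientation_concentration=0.0, seed=8,
        )
        vol, truth = syn.make_fiber_phantom(spec)
        s = m.morphometry_summary(vol, n_directions=128, seed=2)
        assert s.vol_fraction == pytest.approx(truth["realized_vol_fraction"], abs=1e-12)
        assert abs(s.vol_fraction - 0.25) < 0.02
        assert s.thickness_um == pytest.approx(6.0, rel=0.25)
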