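"""Per-algorithm behaviour on constructed fixtures and small phantoms."""

import numpy as np
import pytest

from lascar import (BinaryMask, ScarPrior, SigmoidEnhancementModel,
                    dice, segment_fwhm, segment_hb, segment_ic, segment_kcl,
                    segment_mv, segment_nsd, segment_sy, segment_uta,
                    segment_utb, segment_yl, signed_distance)
from lascar.phantom import generate_phantom, scar_prior_for
from lascar.segmenters import (declared_region, hb_wall, ic_probability_map,
                               nsd_threshold, remove_small_components)
from lascar.wall_model import band_mask, wall_shell

from .conftest import ball_mask, make_volume, small_phantom_spec


def slab_endo(shape=(24, 12, 12), depth=8):
    """Half-space endocardium: exact integer distances along +x."""
    data = np.zeros(shape, dtype=bool)
    data[:depth] = True
    return BinaryMask(data, (1.0, 1.0, 1.0), role="endocardium")


def shell_fixture(rng, wall_mean=40.0, wall_sd=10.0, scar_mean=100.0,
                  scar_sd=10.0, blood_mean=100.0, blood_sd=5.0):
    """Ball endocardium + 2.5 mm wall with one enhancing patch."""
    endo = ball_mask(shape=(32, 32, 32), radius=9.0)
    wall = wall_shell(endo, 2.5)
    patch_ball = ball_mask(shape=(32, 32, 32), radius=6.0,
                           center=(15.5 + 9.0, 15.5, 15.5))
    scar = wall.with_data(wall.data & patch_ball.data, role="scar")
    data = rng.normal(10.0, 3.0, size=(32, 32, 32))  # noisy background
    data[endo.data] = rng.normal(blood_mean, blood_sd, endo.count)
    healthy = wall.data & ~scar.data
    data[healthy] = rng.normal(wall_mean, wall_sd, int(healthy.sum()))
    data[scar.data] = rng.normal(scar_mean, scar_sd, scar.count)
    vol = make_volume(data)
    healthy_region = wall.with_data(healthy, role="region")
    return vol, endo, wall, scar, healthy_region


class TestIC:
    def test_joint_probability_at_sigmoid_midpoints(self):
        endo = slab_endo()
        # blood alternates 90/110 -> mu=100, sd=10; a voxel 3 mm outside
        # at I = 120 sits at both sigmoid centres (c_i=2 SD, c_d=3 mm)
        data = np.zeros((24, 12, 12))
        data[:8] = 90.0
        data[:8, ::2] = 110.0
        data[10, 6, 6] = 120.0
        vol = make_volume(data)
        p = ic_probability_map(vol, endo, SigmoidEnhancementModel())
        assert p.data[10, 6, 6] == pytest.approx(0.25, abs=1e-6)

    def test_hysteresis_collapses_to_plain_threshold(self):
        endo = slab_endo()
        data = np.zeros((24, 12, 12))
        data[:8] = 90.0
        data[:8, ::2] = 110.0
        data[9] = 140.0
        vol = make_volume(data)
        plain = segment_ic(vol, endo, t_high=0.4, t_low=0.4)
        p = ic_probability_map(vol, endo, SigmoidEnhancementModel())
        assert np.array_equal(plain.data, p.data >= 0.4)

    def test_faint_tissue_joins_only_through_a_bridge(self):
        endo = slab_endo(shape=(40, 16, 12))
        data = np.zeros((40, 16, 12))
        data[:8] = 90.0
        data[:8, ::2] = 110.0
        bright, faint = 160.0, 122.0     # p_i ~ 1 vs ~ 0.6
        data[9, 2:5, 6] = bright         # strong patch
        data[9, 5:9, 6] = faint          # faint bridge, 26-connected
        data[9, 9:12, 6] = bright        # second strong patch
        data[9, 14:16, 6] = faint        # isolated faint patch
        vol = make_volume(data)
        seg = segment_ic(vol, endo, t_high=0.5, t_low=0.25)
        assert seg.data[9, 3, 6] and seg.data[9, 10, 6]
        assert seg.data[9, 6, 6]          # bridge captured
        assert not seg.data[9, 14:16, 6].any()  # isolated faint excluded

    def test_invalid_thresholds_rejected(self):
        endo = slab_endo()
        vol = make_volume(np.zeros((24, 12, 12)))
        with pytest.raises(ValueError):
            segment_ic(vol, endo, t_high=0.2, t_low=0.4)


class TestMV:
    def test_no_seeds_gives_empty_mask(self, rng):
        # the brightest structure (the mixture's LGE component) lies deep
        # in the blood pool, so the seed threshold exceeds every band voxel
        vol, endo, scar, wall = _mv_fixture(rng, scar_mean=None)
        data = vol.data.copy()
        core = ball_mask(shape=(32, 32, 32), radius=3.0).data
        data[core] = rng.normal(220.0, 5.0, int(core.sum()))
        seg = segment_mv(make_volume(data), endo, seed=0)
        assert seg.count == 0

    def test_confined_to_band(self, rng):
        vol, endo, scar = _mv_fixture(rng, scar_mean=190.0)[:3]
        seg = segment_mv(vol, endo, seed=0)
        band = band_mask(signed_distance(endo), 1.0, 5.0)
        assert not (seg.data & ~band.data).any()

    def test_high_contrast_phantom_floor(self):
        case = generate_phantom(small_phantom_spec(scar_level_sd=6.0, seed=3))
        seg = segment_mv(case.volume, case.endo, seed=0)
        assert dice(case.scar_gt, seg) >= 70.0


def _mv_fixture(rng, scar_mean):
    """Ball endo with wall; optionally no enhancement at all."""
    endo = ball_mask(shape=(32, 32, 32), radius=9.0)
    wall = wall_shell(endo, 2.5)
    data = rng.normal(40.0, 8.0, size=(32, 32, 32))
    data[endo.data] = rng.normal(100.0, 10.0, endo.count)
    data[wall.data] = rng.normal(60.0, 8.0, wall.count)
    patch = ball_mask(shape=(32, 32, 32), radius=6.0,
                      center=(15.5 + 9.0, 15.5, 15.5))
    scar = wall.with_data(wall.data & patch.data, role="scar")
    if scar_mean is not None:
        data[scar.data] = rng.normal(scar_mean, 8.0, scar.count)
    return make_volume(data), endo, scar, wall


class TestSY:
    def test_uniform_wall_degenerates_to_all_healthy(self):
        endo = ball_mask(shape=(24, 24, 24), radius=7.0)
        vol = make_volume(np.full((24, 24, 24), 55.0))
        assert segment_sy(vol, endo, seed=0).count == 0

    def test_planted_bright_band_is_recovered(self, rng):
        vol, endo, scar, wall = _mv_fixture(rng, scar_mean=150.0)
        seg = segment_sy(vol, endo, dilation_mm=2.5, seed=0)
        assert dice(scar, seg) >= 80.0
        region = wall_shell(endo, 2.5)
        assert not (seg.data & ~region.data).any()

    def test_small_cluster_removal(self):
        data = np.zeros((10, 10, 10), dtype=bool)
        data[0, 0, 0] = True                # 1-voxel speck
        data[5, 5, 3:8] = True              # 5-voxel cluster
        mask = BinaryMask(data, (1, 1, 1))
        cleaned = remove_small_components(mask, min_voxels=3)
        assert not cleaned.data[0, 0, 0]
        assert cleaned.data[5, 5, 5]


class TestHB:
    def test_zero_gradient_wall_is_target_thickness_shell(self):
        endo = ball_mask(shape=(40, 40, 40), radius=10.0)
        vol = make_volume(np.zeros((40, 40, 40)))
        wall = hb_wall(vol, endo, lam=0.5, max_wall_mm=3.0)
        d = signed_distance(endo).data
        inner = (d > 0) & (d <= 2.0)
        assert wall.data[inner].all()          # shell interior retained
        assert d[wall.data].max() <= 3.0 + np.sqrt(3.0)  # stays near 3 mm

    def test_strong_gradient_ridge_stops_the_surface(self):
        endo = ball_mask(shape=(40, 40, 40), radius=10.0)
        d = signed_distance(endo).data
        vol = make_volume(np.where(d <= 2.0, 100.0, 0.0))
        wall = hb_wall(vol, endo, lam=0.3, max_wall_mm=3.0)
        # the surface locks onto the intensity step at 2 mm, not 3 mm
        assert d[wall.data].max() <= 2.0 + np.sqrt(3.0)
        assert wall.data[(d > 0) & (d <= 1.0)].all()

    def test_two_population_wall_classification(self, rng):
        vol, endo, wall, scar, _ = shell_fixture(rng, wall_mean=40.0,
                                                 scar_mean=120.0)
        seg = segment_hb(vol, endo, seed=0)
        missed = (seg.data ^ scar.data)[wall.data].mean()
        assert missed <= 0.02   # recovers the planted split within 2%


class TestYL:
    def test_threshold_extremes(self, rng):
        vol, endo, wall, scar, _ = shell_fixture(rng)
        assert segment_yl(vol, wall, 1e9).count == 0
        low = segment_yl(vol, wall, -1e9)
        assert low.count == wall.count

    def test_counting_against_patch_mean(self, rng):
        vol, endo, wall, scar, _ = shell_fixture(rng)
        thr = float(vol.data[scar.data].mean())
        seg = segment_yl(vol, wall, thr)
        expected = wall.data & (vol.data > thr)
        assert np.array_equal(seg.data, expected)

    def test_missing_wall_rejected(self, rng):
        vol = make_volume(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            segment_yl(vol, None, 10.0)


class TestKCL:
    def test_unreachable_prior_gives_empty_mask(self, rng):
        vol, endo, wall, scar, _ = shell_fixture(rng)
        seg = segment_kcl(vol, endo, ScarPrior(50.0, 0.5), seed=0)
        assert seg.count == 0

    def test_confined_to_band_and_recovers_phantom_scar(self):
        spec = small_phantom_spec(seed=5)
        case = generate_phantom(spec)
        prior = ScarPrior(*scar_prior_for(spec))
        seg = segment_kcl(case.volume, case.endo, prior, seed=0)
        band = band_mask(signed_distance(case.endo), 3.0, 3.0)
        assert not (seg.data & ~band.data).any()
        assert dice(case.scar_gt, seg) >= 70.0


class TestUTA:
    def test_no_offsets_equals_global_threshold(self, rng):
        vol, endo, wall, scar, _ = shell_fixture(rng)
        a = segment_uta(vol, wall, n_sd=3.0, seed=0)
        b = segment_uta(vol, wall, n_sd=3.0, slice_offsets={}, seed=0)
        assert np.array_equal(a.data, b.data)

    def test_infinite_offset_empties_a_slice(self, rng):
        vol, endo, wall, scar, _ = shell_fixture(rng)
        k = 16
        seg = segment_uta(vol, wall, n_sd=2.0,
                          slice_offsets={k: np.inf}, seed=0)
        assert not seg.data[:, :, k].any()
        base = segment_uta(vol, wall, n_sd=2.0, seed=0)
        other = [i for i in range(32) if i != k]
        assert np.array_equal(seg.data[:, :, other], base.data[:, :, other])

    def test_threshold_recovery_against_generator(self, rng):
        vol, endo, wall, scar, _ = shell_fixture(rng, wall_mean=40.0,
                                                 wall_sd=10.0,
                                                 scar_mean=120.0)
        seg = segment_uta(vol, wall, n_sd=2.0, seed=0)
        thr = nsd_threshold(vol, wall.with_data(wall.data & ~scar.data), 0.0)
        # recovered lower mode ~ N(40, 10): threshold ~ 60
        expected_thr = 60.0
        got = vol.data[seg.data].min() if seg.count else np.inf
        assert got == pytest.approx(expected_thr, abs=3.0)
        assert np.array_equal(seg.data, wall.data & (vol.data > got - 1e-9)) \
            or seg.count == 0


class TestUTB:
    def test_single_cluster_labels_whole_wall(self, rng):
        vol, endo, wall, scar, _ = shell_fixture(rng)
        seg = segment_utb(vol, wall, k=1, seed=0)
        assert seg.count == wall.count

    def test_four_planted_tiers_top_is_scar(self):
        endo = ball_mask(shape=(24, 24, 24), radius=7.0)
        wall = wall_shell(endo, 2.5)
        coords = np.argwhere(wall.data)
        data = np.zeros((24, 24, 24))
        tiers = np.array([10.0, 40.0, 70.0, 100.0])
        assignment = np.arange(len(coords)) % 4
        data[tuple(coords.T)] = tiers[assignment]
        vol = make_volume(data)
        seg = segment_utb(vol, wall, k=4, seed=0)
        expected = np.zeros_like(wall.data)
        expected[tuple(coords[assignment == 3].T)] = True
        assert np.array_equal(seg.data, expected)

    def test_deterministic_under_seed(self, rng):
        vol, endo, wall, scar, _ = shell_fixture(rng)
        a = segment_utb(vol, wall, seed=11, blood=endo)
        b = segment_utb(vol, wall, seed=11, blood=endo)
        assert np.array_equal(a.data, b.data)


class TestNSD:
    def test_threshold_arithmetic(self):
        vals = np.zeros((4, 4, 4))
        vals.ravel()[:8] = [30, 50] * 4    # mean 40, population SD 10
        region = np.zeros((4, 4, 4), dtype=bool)
        region.ravel()[:8] = True
        thr = nsd_threshold(make_volume(vals),
                            BinaryMask(region, (1, 1, 1)), 2.0)
        assert thr == 60.0

    def test_nsd_nesting(self, rng):
        vol, endo, wall, scar, healthy = shell_fixture(rng)
        segs = {n: segment_nsd(vol, endo, healthy, n=n) for n in (2, 4, 6)}
        assert np.all(segs[4].data <= segs[2].data)
        assert np.all(segs[6].data <= segs[4].data)

    def test_well_separated_phantom_floor(self, rng):
        vol, endo, wall, scar, healthy = shell_fixture(
            rng, wall_mean=40.0, wall_sd=10.0, scar_mean=100.0, scar_sd=10.0)
        seg = segment_nsd(vol, endo, healthy, n=4)
        assert dice(scar, seg) >= 90.0

    def test_zero_variance_healthy_rejected(self):
        vol = make_volume(np.zeros((8, 8, 8)))
        endo = ball_mask(shape=(8, 8, 8), radius=2.0)
        region = ball_mask(shape=(8, 8, 8), radius=2.0, role="region")
        from lascar import DegenerateFitError
        with pytest.raises(DegenerateFitError):
            segment_nsd(vol, endo, region, n=2)


class TestFWHM:
    def test_threshold_is_fraction_of_region_max(self, rng):
        vol, endo, wall, scar, _ = shell_fixture(rng)
        from lascar.segmenters import fwhm_threshold
        thr = fwhm_threshold(vol, scar, 0.5)
        assert thr == pytest.approx(0.5 * vol.data[scar.data].max())

    def test_fraction_one_keeps_only_the_maximum(self, rng):
        vol, endo, wall, scar, _ = shell_fixture(rng)
        seg = segment_fwhm(vol, endo, scar, fraction=1.0)
        mx = vol.data[scar.data].max()
        assert seg.count >= 1
        assert np.all(vol.data[seg.data] >= mx)

    def test_disconnected_bright_artefact_excluded(self, rng):
        endo = ball_mask(shape=(40, 24, 24), radius=8.0,
                         center=(11.0, 11.5, 11.5))
        wall = wall_shell(endo, 2.5)
        data = np.zeros((40, 24, 24))
        data[endo.data] = 100.0
        data[wall.data] = 40.0
        patch = ball_mask(shape=(40, 24, 24), radius=5.0,
                          center=(3.0, 11.5, 11.5))
        scar = wall.with_data(wall.data & patch.data, role="region")
        data[scar.data] = 160.0
        # bright spot inside the 3 mm search shell but far from the patch
        far = ball_mask(shape=(40, 24, 24), radius=8.0 + 2.6,
                        center=(11.0, 11.5, 11.5))
        spot = np.zeros_like(data, dtype=bool)
        spot[21, 11, 11] = True
        spot &= far.data & ~endo.data
        data[spot] = 200.0
        vol = make_volume(data)
        seg = segment_fwhm(vol, endo, scar, fraction=0.5)
        assert seg.data[scar.data].mean() > 0.9
        assert not (seg.data & spot).any()


class TestDeclaredRegions:
    def test_every_method_has_a_region(self, rng):
        vol, endo, wall, scar, _ = shell_fixture(rng)
        from lascar.segmenters import METHODS
        for name in METHODS:
            region = declared_region(name, vol, endo=endo, wall_manual=wall)
            assert region.count > 0
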