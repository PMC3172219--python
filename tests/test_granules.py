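import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from actinmesh.errors import (
    DetectionError,
    NoRingError,
    UndefinedStatisticError,
)
from actinmesh.geometry import RingGeometry, central_region
from actinmesh.granules import (
    detect_granules,
    estimate_diameter,
    height_strata,
    lateral_distance_to_penetrable,
    mtoc_position,
    odds_ratio,
    ring_relative_stats,
)
from actinmesh.holes import segment_actin
from actinmesh.images import CalibratedImage, CalibratedStack
from actinmesh.penetrability import PenetrableMask, distance_map, penetrable_mask
from actinmesh.synth import (
    FWHM_TO_SIGMA,
    MeshFixtureSpec,
    SimulationSpec,
    make_mesh_fixture,
    sample_lateral_positions,
    simulate_granule_stack,
)


def _region(shape, px_nm):
    return central_region(
        RingGeometry(False), None, px_nm, override_mask=np.ones(shape, bool)
    )


def _render_patch(diameter_nm, px_nm=40.0, psf_nm=100.0, amp=500.0, half=12):
    fwhm = np.sqrt(diameter_nm**2 + psf_nm**2)
    sig = fwhm * FWHM_TO_SIGMA / px_nm
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    return 10.0 + amp * np.exp(-(x**2 + y**2) / (2 * sig**2))


class TestDetectGranules:
    def test_well_separated_granules_all_found_subpixel(self):
        spec = SimulationSpec(seed=3, n_granules=36)
        stack, truth = simulate_granule_stack(spec)
        det = detect_granules(stack)
        assert len(det) == 36
        d, _ = cKDTree(truth[["x_um", "y_um"]].to_numpy()).query(
            det[["x_um", "y_um"]].to_numpy()
        )
        rms_px = np.sqrt((d**2).mean()) / stack.pixel_size_nm * 1000
        assert rms_px < 1.0

    def test_noise_only_stack_finds_nothing(self):
        spec = SimulationSpec(seed=4, n_granules=0)
        stack, _ = simulate_granule_stack(spec)
        assert len(detect_granules(stack)) == 0

    def test_unresolvable_pair_not_double_counted(self):
        # two 400 nm granules 150 nm apart: below the separation limit
        spec = SimulationSpec(seed=5, n_granules=2, granule_diameter_mean_nm=400.0,
                              granule_diameter_sd_nm=1e-9)
        stack, _ = simulate_granule_stack(
            spec, positions=np.array([[6.0, 6.0], [6.15, 6.0]])
        )
        assert len(detect_granules(stack)) <= 1

    def test_saturated_stack_raises(self):
        sat = CalibratedStack(
            [CalibratedImage(np.full((32, 32), 65535.0), 40.0)] * 3, 125.0
        )
        with pytest.raises(DetectionError):
            detect_granules(sat)


class TestEstimateDiameter:
    def test_point_source_reports_resolution_floor(self):
        patch = _render_patch(0.0)
        assert estimate_diameter(patch, 40.0) == pytest.approx(100.0)

    def test_noise_free_400nm_recovery(self):
        patch = _render_patch(400.0)
        assert estimate_diameter(patch, 40.0) == pytest.approx(400.0, abs=10.0)

    def test_parameter_recovery_within_two_sem(self):
        """Detection + sizing recovers the true cohort mean for n >= 500."""
        rng = np.random.default_rng(0)
        true = np.clip(rng.normal(251, 40, 500), 120, None)
        est = np.array(
            [
                estimate_diameter(
                    rng.poisson(_render_patch(d, amp=200.0)).astype(float), 40.0
                )
                for d in true
            ]
        )
        sem = true.std() / np.sqrt(len(true))
        assert abs(est.mean() - true.mean()) < 2 * sem


class TestHeightStrata:
    def test_simple_fractions(self):
        g = pd.DataFrame({"z_nm": [100.0, 200.0, 300.0]})
        out = height_strata(g)
        np.testing.assert_allclose(
            out["fraction_pct"], [200 / 3, 100 / 3, 0.0, 0.0], atol=1e-9
        )

    def test_uniform_placement_quarters(self):
        rng = np.random.default_rng(1)
        g = pd.DataFrame({"z_nm": rng.uniform(0, 1000, 4000)})
        out = height_strata(g)
        np.testing.assert_allclose(out["fraction_pct"], 25.0, atol=2.5)
        assert out["fraction_pct"].sum() == pytest.approx(100.0)

    def test_docked_preset_two_thirds_near_surface(self):
        spec = SimulationSpec(seed=6, n_granules=36, granule_height_mode="docked")
        _, truth = simulate_granule_stack(spec)
        frac = (truth["z_nm"] < 250).mean()
        assert frac == pytest.approx(2 / 3, abs=0.17)

    def test_empty_raises(self):
        with pytest.raises(UndefinedStatisticError):
            height_strata(pd.DataFrame({"z_nm": []}))


@pytest.fixture(scope="module")
def fixture_pen():
    img, _ = make_mesh_fixture(MeshFixtureSpec())
    region = _region(img.shape, img.pixel_size_nm)
    dist = distance_map(segment_actin(img))
    return img, region, penetrable_mask(dist, 200.0, region)


class TestLateralDistance:
    def test_granule_on_penetrable_pixel_scores_zero(self, fixture_pen):
        img, region, pm = fixture_pen
        r, c = np.argwhere(pm.mask)[0]
        px_um = img.pixel_size_um
        g = pd.DataFrame({"x_um": [c * px_um], "y_um": [r * px_um], "z_nm": [500.0]})
        out, _ = lateral_distance_to_penetrable(g, pm, img.pixel_size_nm)
        assert out["lateral_distance_um"].iloc[0] == 0.0

    def test_axial_coordinate_ignored(self, fixture_pen):
        img, region, pm = fixture_pen
        px_um = img.pixel_size_um
        # a single penetrable pixel, granule 1 µm away in-plane at two heights
        single = np.zeros_like(pm.mask)
        single[500, 500] = True
        pm1 = PenetrableMask(single, 200.0, 100.0 / region.n_pixels, region)
        g = pd.DataFrame(
            {"x_um": [500 * px_um + 1.0] * 2, "y_um": [500 * px_um] * 2,
             "z_nm": [0.0, 900.0]}
        )
        out, _ = lateral_distance_to_penetrable(g, pm1, img.pixel_size_nm)
        d = out["lateral_distance_um"].to_numpy()
        assert d[0] == pytest.approx(d[1])
        assert d[0] == pytest.approx(1.0, abs=0.05)

    def test_empty_mask_flags_undefined(self, fixture_pen):
        img, region, pm = fixture_pen
        empty = PenetrableMask(np.zeros_like(pm.mask), 200.0, 0.0, region)
        g = pd.DataFrame({"x_um": [5.0], "y_um": [5.0], "z_nm": [100.0]})
        out, _ = lateral_distance_to_penetrable(g, empty, img.pixel_size_nm)
        assert not out["distance_defined"].iloc[0]
        assert np.isnan(out["lateral_distance_um"].iloc[0])

    def test_docked_closer_than_uniform_near_surface(self, fixture_pen):
        img, region, pm = fixture_pen
        rng = np.random.default_rng(2)
        docked_xy = sample_lateral_positions(
            region.mask, img.pixel_size_nm, 200, rng, on_mask=pm.mask, on_fraction=0.8
        )
        uniform_xy = sample_lateral_positions(region.mask, img.pixel_size_nm, 200, rng)
        z = rng.uniform(0, 250, 200)
        mk = lambda xy: pd.DataFrame({"x_um": xy[:, 0], "y_um": xy[:, 1], "z_nm": z})
        d_docked, _ = lateral_distance_to_penetrable(mk(docked_xy), pm, img.pixel_size_nm)
        d_unif, _ = lateral_distance_to_penetrable(mk(uniform_xy), pm, img.pixel_size_nm)
        assert (
            d_docked["lateral_distance_um"].mean() < d_unif["lateral_distance_um"].mean()
        )


class TestOddsRatio:
    def test_direct_arithmetic(self, fixture_pen):
        """p = 0.2 against a baseline f = 0.0625 gives OR = 3.75."""
        img, region, _ = fixture_pen
        # synthetic mask with exactly f = 1/16 of the region penetrable
        mask = np.zeros_like(region.mask)
        mask[:250, :250] = True  # 62500 px of 1e6
        pm = PenetrableMask(mask, 200.0, 6.25, region)
        px_um = img.pixel_size_um
        on = np.argwhere(mask)[:1]
        off = np.argwhere(~mask & region.mask)[:4]
        pts = np.vstack([on, off])
        g = pd.DataFrame(
            {"x_um": pts[:, 1] * px_um, "y_um": pts[:, 0] * px_um,
             "z_nm": [50.0] * 5}
        )
        out = odds_ratio(g, pm, region, axial_edges_nm=(0.0, 100.0))
        assert out["p_on_penetrable"].iloc[0] == pytest.approx(0.2)
        assert out["odds_ratio"].iloc[0] == pytest.approx(3.75)

    def test_uniform_placement_median_near_one(self, fixture_pen):
        img, region, pm = fixture_pen
        rng = np.random.default_rng(3)
        ors = []
        for _ in range(100):
            xy = sample_lateral_positions(region.mask, img.pixel_size_nm, 400, rng)
            g = pd.DataFrame(
                {"x_um": xy[:, 0], "y_um": xy[:, 1],
                 "z_nm": rng.uniform(0, 900, 400)}
            )
            out = odds_ratio(g, pm, region, axial_edges_nm=(0.0, 900.0))
            ors.append(out["odds_ratio"].iloc[0])
        assert 0.8 <= np.median(ors) <= 1.25

    def test_docked_enrichment_elevates_near_surface_bins(self, fixture_pen):
        img, region, pm = fixture_pen
        rng = np.random.default_rng(4)
        f = (pm.mask & region.mask).sum() / region.n_pixels
        xy = sample_lateral_positions(
            region.mask, img.pixel_size_nm, 600, rng, on_mask=pm.mask, on_fraction=0.12
        )
        g = pd.DataFrame(
            {"x_um": xy[:, 0], "y_um": xy[:, 1], "z_nm": rng.uniform(0, 250, 600)}
        )
        out = odds_ratio(g, pm, region, axial_edges_nm=(0.0, 250.0))
        assert out["odds_ratio"].iloc[0] > 2.0

    def test_empty_bin_reports_nan_not_zero(self, fixture_pen):
        img, region, pm = fixture_pen
        g = pd.DataFrame({"x_um": [5.0], "y_um": [5.0], "z_nm": [50.0]})
        out = odds_ratio(g, pm, region, axial_edges_nm=(0.0, 100.0, 200.0))
        assert np.isnan(out["odds_ratio"].iloc[1])

    def test_degenerate_fraction_raises(self, fixture_pen):
        img, region, pm = fixture_pen
        full = PenetrableMask(np.ones_like(pm.mask), 200.0, 100.0, region)
        g = pd.DataFrame({"x_um": [5.0], "y_um": [5.0], "z_nm": [50.0]})
        with pytest.raises(UndefinedStatisticError):
            odds_ratio(g, full, region)


class TestRingRelativeStats:
    RING = RingGeometry(True, (6.0, 6.0), 5.0, 8.0)

    def test_all_inside(self):
        g = pd.DataFrame({"x_um": [6.0, 6.5], "y_um": [6.0, 5.8]})
        st = ring_relative_stats(g, self.RING)
        assert (st.inside_pct, st.on_ring_pct, st.outside_pct) == (100.0, 0.0, 0.0)

    def test_fractions_conserve_signal(self):
        rng = np.random.default_rng(5)
        g = pd.DataFrame(
            {"x_um": rng.uniform(0, 12, 500), "y_um": rng.uniform(0, 12, 500)}
        )
        st = ring_relative_stats(g, self.RING)
        assert st.inside_pct + st.on_ring_pct + st.outside_pct == pytest.approx(100.0)

    def test_uniform_density_gives_flat_area_normalised_profile(self):
        rng = np.random.default_rng(6)
        # uniform density in a disc of radius 5 around the ring centre
        n = 40000
        r = 5.0 * np.sqrt(rng.uniform(size=n))
        th = rng.uniform(0, 2 * np.pi, n)
        g = pd.DataFrame({"x_um": 6.0 + r * np.cos(th), "y_um": 6.0 + r * np.sin(th)})
        st = ring_relative_stats(g, self.RING, bin_width_um=1.0)
        dens = st.profile["frequency_per_um2"].to_numpy()[:5]
        assert dens.std() / dens.mean() < 0.1

    def test_polarised_signal_mostly_inside(self):
        rng = np.random.default_rng(7)
        n = 400
        inside = rng.uniform(size=n) < 0.85
        r = np.where(inside, 2.0 * np.sqrt(rng.uniform(size=n)),
                     4.5 + rng.uniform(0, 1.0, n))
        th = rng.uniform(0, 2 * np.pi, n)
        g = pd.DataFrame({"x_um": 6.0 + r * np.cos(th), "y_um": 6.0 + r * np.sin(th)})
        st = ring_relative_stats(g, self.RING)
        assert st.inside_pct > 80.0

    def test_image_mode_and_missing_ring(self):
        img = CalibratedImage(np.ones((100, 100)), 100.0)
        with pytest.raises(NoRingError):
            ring_relative_stats(img, RingGeometry(False))


class TestMtocPosition:
    @pytest.mark.parametrize("z_nm,height_range", [(240.0, (0.0, 1000.0)),
                                                   (1200.0, (0.0, 2000.0))])
    def test_height_recovery_within_one_z_step(self, z_nm, height_range):
        spec = SimulationSpec(seed=8, n_granules=1, granule_diameter_mean_nm=800.0,
                              granule_diameter_sd_nm=1e-9,
                              height_range_nm=height_range, photons=800.0)
        stack, truth = simulate_granule_stack(spec, positions=np.array([[6.0, 6.0]]))
        # place deterministically by overriding the sampled height
        arr = stack.as_array()
        h, _ = mtoc_position(stack)
        assert abs(h * 1000 - truth["z_nm"].iloc[0]) <= stack.z_step_nm

    def test_lateral_distance_zero_on_domain(self, fixture_pen):
        img, region, pm = fixture_pen
        r, c = np.argwhere(pm.mask)[len(np.argwhere(pm.mask)) // 2]
        px_um = img.pixel_size_um
        spec = SimulationSpec(seed=9, n_granules=1, field_size_um=10.0,
                              pixel_size_nm=10.0, photons=800.0)
        stack, _ = simulate_granule_stack(
            spec, positions=np.array([[c * px_um, r * px_um]])
        )
        _, lat = mtoc_position(stack, pm)
        assert lat == pytest.approx(0.0, abs=0.05)

    def test_blank_stack_raises(self):
        blank = CalibratedStack(
            [CalibratedImage(np.full((32, 32), 5.0), 40.0)] * 3, 125.0
        )
        with pytest.raises(DetectionError):
            mtoc_position(blank)
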