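"""Digital phantom construction, motion traces, rendering and the plan."""

import math

import numpy as np
import pytest
from scipy import ndimage

from kvtrack.geometry import ImagingGeometry, project
from kvtrack.phantom import (
    MU_120KV,
    CohortSpec,
    MotionTrace,
    PhantomConfig,
    build_phantom,
    generate_cohort,
    render_drr,
    render_treatment_image,
    sample_positions,
    simulate_observation_cohort,
    synthetic_plan,
)


class TestBuildPhantom:
    def test_plain_config_yields_configured_densities_only(self):
        cfg = PhantomConfig(
            shape=(48, 48, 48), spacing=6.0, n_gas_pockets=0, n_fiducials=0,
            texture_amplitude=0.0,
        )
        vol = build_phantom(cfg).density()
        expected = {0.0, cfg.body_density, cfg.lung_density,
                    cfg.spine_density, cfg.target_density}
        assert set(np.unique(vol).tolist()) <= expected

    def test_same_seed_bit_identical(self):
        cfg = PhantomConfig(shape=(48, 48, 48), spacing=6.0, seed=11)
        v1 = build_phantom(cfg).density((3.0, -2.0, 5.0))
        v2 = build_phantom(cfg).density((3.0, -2.0, 5.0))
        np.testing.assert_array_equal(v1, v2)

    def test_ptv_is_ctv_dilated_by_margin(self, small_phantom):
        """Brute-force distance-transform oracle for the 5 mm PTV margin."""
        cfg = small_phantom.config
        masks = small_phantom.masks()
        ctv, ptv = masks["ctv"], masks["ptv"]
        assert np.all(ptv[ctv])
        dist = ndimage.distance_transform_edt(~ctv, sampling=cfg.spacing)
        diag = cfg.spacing * math.sqrt(3.0)
        assert dist[ptv].max() <= cfg.ptv_margin + diag
        assert not ptv[dist > cfg.ptv_margin + diag].any()

    def test_target_outside_volume_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(shape=(32, 32, 32), spacing=2.0, target_center=(0, 0, 100))

    def test_fiducial_density_must_exceed_clip(self):
        with pytest.raises(ValueError):
            PhantomConfig(fiducial_density=1.5)


class TestMotionTrace:
    def test_zero_amplitude_zero_baseline(self):
        trace = MotionTrace(sample_times=tuple(range(10)))
        pos, mean = sample_positions(trace, 10)
        assert not pos.any() and not mean.any()

    def test_cosine_peak_to_peak(self):
        """Phases 0 and pi differ by twice the (half) amplitude."""
        trace = MotionTrace(
            amplitude=(0, 0, 10.0), period_s=2 * math.pi, waveform="cos",
            sample_times=(0.0, math.pi),
        )
        pos, _ = sample_positions(trace, 2)
        assert pos[0, 2] - pos[1, 2] == pytest.approx(20.0)

    def test_cos4_range_and_dwell(self):
        t = np.linspace(0, 4.0, 400)
        trace = MotionTrace(amplitude=(0, 0, 5.0), period_s=4.0, sample_times=tuple(t))
        pos, _ = sample_positions(trace, 400)
        z = pos[:, 2]
        assert z.max() == pytest.approx(5.0, abs=1e-6)
        assert z.min() == pytest.approx(-5.0, abs=1e-3)
        # end-exhale dwell: more than half the cycle sits in the lower half
        assert (z < 0).mean() > 0.5

    def test_deterministic_for_same_inputs(self):
        trace = MotionTrace(
            baseline=(1, 2, 3), amplitude=(2, 3, 4), phase=0.7,
            sample_times=tuple(np.linspace(0, 30, 12)),
        )
        p1, _ = sample_positions(trace, 12)
        p2, _ = sample_positions(trace, 12)
        np.testing.assert_array_equal(p1, p2)


class TestRenderDRR:
    def test_empty_volume_gives_zero_image(self, small_geometry):
        img = render_drr(np.zeros((32, 32, 32)), 5.0, small_geometry, "A")
        assert not img.any()

    def test_uniform_cube_line_integral(self, small_geometry):
        """The 45-degree diagonal through a 100 mm unit-density cube has
        path length 100 sqrt(2), giving mu * 141.4 ~ 2.418."""
        vol = np.zeros((100, 100, 100), dtype=np.float32)
        vol[25:75, 25:75, 25:75] = 1.0  # 100 mm cube at 2 mm voxels
        img = render_drr(vol, 2.0, small_geometry, "A")
        analytic = MU_120KV * 100.0 * math.sqrt(2.0)
        assert img.max() == pytest.approx(analytic, rel=0.05)

    def test_density_clipping_hides_dense_voxels(self, small_geometry):
        vol = np.ones((32, 32, 32), dtype=np.float32)
        dense = vol.copy()
        dense[16, 16, 16] = 3.0
        img_clipped = render_drr(dense, 5.0, small_geometry, "A")
        img_plain = render_drr(vol, 5.0, small_geometry, "A")
        np.testing.assert_array_equal(img_clipped, img_plain)

    def test_unknown_view_rejected(self, small_geometry):
        with pytest.raises(ValueError):
            render_drr(np.zeros((8, 8, 8)), 5.0, small_geometry, "C")


class TestTreatmentImages:
    def test_identity_case_equals_drr(self, small_geometry):
        cfg = PhantomConfig(shape=(64, 64, 64), spacing=5.0, n_fiducials=0)
        ph = build_phantom(cfg)
        imgs = render_treatment_image(ph, small_geometry, (0, 0, 0), 0.0, 0.0, 0)
        for view in ("A", "B"):
            drr = render_drr(ph.density(), cfg.spacing, small_geometry, view)
            np.testing.assert_allclose(imgs[view], drr, atol=1e-6)

    def test_si_displacement_moves_diaphragm_edge(self, small_phantom, small_geometry):
        """A +10 mm superior shift moves the diaphragm edge 2 rows up (5 mm/px)."""
        base = render_treatment_image(small_phantom, small_geometry, (0, 0, 0), 0, 0, 0)
        moved = render_treatment_image(small_phantom, small_geometry, (0, 0, 10.0), 0, 0, 0)
        for view in ("A", "B"):
            col = small_geometry.image_size // 2
            prof0 = base[view][:, col]
            prof1 = moved[view][:, col]
            e0 = np.argmax(np.abs(np.diff(prof0[:40])))
            e1 = np.argmax(np.abs(np.diff(prof1[:40])))
            assert e0 - e1 == 2

    def test_fixed_seed_reproducible(self, small_phantom, small_geometry):
        kw = dict(true_position=(1, 2, 3), noise_level=0.1,
                  intensity_perturbation=0.1)
        a = render_treatment_image(small_phantom, small_geometry, seed=5, **kw)
        b = render_treatment_image(small_phantom, small_geometry, seed=5, **kw)
        for view in ("A", "B"):
            np.testing.assert_array_equal(a[view], b[view])


class TestCohort:
    SPEC = dict(n_patients=1, n_fractions=1, n_images=3, master_seed=2)

    def test_counts(self, small_phantom_config, small_geometry):
        cohort = generate_cohort(
            CohortSpec(**self.SPEC), small_phantom_config, small_geometry
        )
        p = cohort.patients[0]
        assert len(p.images) == 3
        assert set(p.drr) == {"A", "B"}
        assert len(p.truth) == 3
        assert list(cohort.truth.columns) == [
            "patient", "fraction", "image", "x_mm", "y_mm", "z_mm",
        ]

    def test_same_seed_identical(self, small_phantom_config, small_geometry):
        c1 = generate_cohort(CohortSpec(**self.SPEC), small_phantom_config, small_geometry)
        c2 = generate_cohort(CohortSpec(**self.SPEC), small_phantom_config, small_geometry)
        np.testing.assert_array_equal(
            c1.patients[0].images[(0, 0)]["A"], c2.patients[0].images[(0, 0)]["A"]
        )
        assert c1.truth.equals(c2.truth)

    def test_zero_motion_cohort_truth_all_zero(self, small_phantom_config, small_geometry):
        spec = CohortSpec(
            n_patients=1, n_fractions=2, n_images=2, baseline_sigma=0.0,
            amplitude_ranges=((0, 0), (0, 0), (0, 0)), master_seed=3,
        )
        cohort = generate_cohort(spec, small_phantom_config, small_geometry)
        assert not cohort.truth[["x_mm", "y_mm", "z_mm"]].to_numpy().any()

    def test_patient_seeds_independent(self, small_phantom_config, small_geometry):
        spec = CohortSpec(n_patients=2, n_fractions=1, n_images=1, master_seed=4)
        cohort = generate_cohort(spec, small_phantom_config, small_geometry)
        t = cohort.truth
        assert not np.array_equal(
            t[t.patient == 0][["x_mm", "y_mm", "z_mm"]].to_numpy(),
            t[t.patient == 1][["x_mm", "y_mm", "z_mm"]].to_numpy(),
        )


@pytest.fixture(scope="module")
def ptv():
    n = 41
    ax = (np.arange(n) - n // 2) * 2.0
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
    return X**2 + Y**2 + Z**2 <= 20.0**2


class TestSyntheticPlan:

    def test_single_beam_is_the_total(self, ptv):
        beams, total = synthetic_plan(ptv, 2.0, n_beams=1, prescription=35.0)
        np.testing.assert_array_equal(beams[0], total)

    def test_components_sum_to_total(self, ptv):
        beams, total = synthetic_plan(ptv, 2.0, n_beams=12, prescription=35.0)
        np.testing.assert_allclose(np.sum(beams, axis=0), total, rtol=1e-12)

    def test_d95_normalised_to_prescription(self, ptv):
        _, total = synthetic_plan(ptv, 2.0, n_beams=12, prescription=35.0)
        d95 = np.percentile(total[ptv], 5)
        assert d95 == pytest.approx(35.0, abs=0.01)

    def test_empty_ptv_rejected(self):
        with pytest.raises(ValueError):
            synthetic_plan(np.zeros((8, 8, 8), bool), 2.0)


class TestObservationSimulators:
    def test_deterministic(self):
        a = simulate_observation_cohort(n_patients=2, n_images=5, seed=9)
        b = simulate_observation_cohort(n_patients=2, n_images=5, seed=9)
        np.testing.assert_array_equal(a.v, b.v)
        np.testing.assert_array_equal(a.r, b.r)

    def test_shapes_and_grouping(self):
        obs = simulate_observation_cohort(
            n_patients=3, n_fractions=2, n_images=4, seed=10
        )
        assert obs.v.shape == (24, 104) and obs.r.shape == (24, 3)
        assert set(obs.patients().tolist()) == {0, 1, 2}
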