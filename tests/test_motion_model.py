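"""Inter/intra decomposition, the truncated-SVD solver and the scenarios."""

import numpy as np
import pytest

from kvtrack.motion_model import (
    ObservationSet,
    build_design,
    decompose,
    error_stats,
    fit_models,
    fit_svd,
    fitting_set_table,
    loocv,
    track_with_dvi,
    track_without_dvi,
    true_fraction_means,
)
from kvtrack.phantom import linear_map_cohort, simulate_observation_cohort


def _obs(v, r, patient=None, fraction=None):
    n = v.shape[0]
    return ObservationSet(
        v=v,
        r=r,
        patient=np.zeros(n, int) if patient is None else patient,
        fraction=np.zeros(n, int) if fraction is None else fraction,
        image=np.arange(n),
    )


class TestDecompose:
    def test_single_image_fraction_has_zero_residual(self, rng):
        obs = _obs(rng.normal(size=(1, 104)), rng.normal(size=(1, 3)))
        dec = decompose(obs)
        assert not dec.v_resid.any() and not dec.r_resid.any()

    def test_fraction_mean_and_residuals(self):
        r = np.array([[0, 0, 2.0], [0, 0, 4.0]])
        obs = _obs(np.zeros((2, 104)), r)
        dec = decompose(obs)
        np.testing.assert_array_equal(dec.r_mean, [[0, 0, 3.0]])
        np.testing.assert_array_equal(dec.r_resid[:, 2], [-1.0, 1.0])

    def test_residuals_sum_to_zero_per_fraction(self, rng):
        obs = _obs(
            rng.normal(size=(30, 104)),
            rng.normal(size=(30, 3)),
            fraction=np.repeat([0, 1, 2], 10),
        )
        dec = decompose(obs)
        for g in range(3):
            np.testing.assert_allclose(
                dec.v_resid[dec.group_index == g].sum(axis=0), 0.0, atol=1e-12
            )

    def test_recomposition_is_exact(self, rng):
        obs = _obs(
            rng.normal(size=(20, 104)),
            rng.normal(size=(20, 3)),
            fraction=np.repeat([0, 1], 10),
        )
        dec = decompose(obs)
        np.testing.assert_allclose(
            dec.r_mean[dec.group_index] + dec.r_resid, obs.r, atol=1e-14
        )


class TestFitSVD:
    def test_matches_least_squares_oracle(self, rng):
        """Noise-free linear data, R -> inf: exact recovery of the map."""
        V, Rpos, C = linear_map_cohort(300, noise_sigma=0.0, seed=3)
        model = fit_svd(V, Rpos, cutoff_ratio=1e6)
        np.testing.assert_allclose(model.coef, C, atol=1e-8)
        oracle, *_ = np.linalg.lstsq(build_design(V), Rpos, rcond=None)
        np.testing.assert_allclose(model.coef, oracle, atol=1e-8)

    def test_zero_components_fit_intercept_only(self):
        V = np.zeros((50, 104))
        b = np.tile([1.0, -2.0, 3.0], (50, 1))
        with pytest.raises(ValueError):
            fit_svd(V, b, cutoff_ratio=10.0)

    def test_intercept_recovered_with_tiny_component(self, rng):
        V = np.zeros((50, 104))
        V[:, 0] = rng.normal(size=50)
        b = np.tile([1.0, -2.0, 3.0], (50, 1))
        model = fit_svd(V, b, cutoff_ratio=1e6)
        np.testing.assert_allclose(model.coef[-1], [1.0, -2.0, 3.0], atol=1e-8)
        np.testing.assert_allclose(model.coef[:-1], 0.0, atol=1e-8)

    def test_rank_one_truncation_matches_oracle(self, rng):
        V, Rpos, _ = linear_map_cohort(200, noise_sigma=0.5, seed=4)
        A = build_design(V)
        U, w, Vt = np.linalg.svd(A, full_matrices=False)
        # cutoff between the first two singular values keeps only the largest
        ratio = float(w[0] / np.sqrt(w[0] * w[1]))
        model = fit_svd(V, Rpos, cutoff_ratio=ratio)
        assert model.n_retained == 1
        oracle = np.outer(Vt[0] / w[0], U[:, 0] @ Rpos)
        np.testing.assert_allclose(model.coef, oracle, atol=1e-10)

    def test_retained_count_monotone_in_cutoff(self, rng):
        V, Rpos, _ = linear_map_cohort(120, noise_sigma=1.0, seed=5)
        counts = [
            fit_svd(V, Rpos, cutoff_ratio=r).n_retained
            for r in (1.2, 2.0, 7.0, 100.0, 1e6)
        ]
        assert counts == sorted(counts)

    def test_prediction_affine_identity(self, rng):
        V, Rpos, _ = linear_map_cohort(150, noise_sigma=1.0, seed=6)
        model = fit_svd(V, Rpos, cutoff_ratio=7.0)
        v1, v2 = rng.normal(size=(2, 104))
        lhs = model.predict(v1 + v2) + model.predict(np.zeros(104))
        rhs = model.predict(v1) + model.predict(v2)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_training_point_reproduced_full_rank(self, rng):
        V, Rpos, _ = linear_map_cohort(300, noise_sigma=0.0, seed=7)
        model = fit_svd(V, Rpos, cutoff_ratio=1e9)
        np.testing.assert_allclose(model.predict(V[17]), Rpos[17], atol=1e-7)

    def test_predict_length_mismatch(self, rng):
        V, Rpos, _ = linear_map_cohort(50, seed=8)
        model = fit_svd(V, Rpos, cutoff_ratio=7.0)
        with pytest.raises(ValueError):
            model.predict(np.zeros(10))


class TestHeldOutRecovery:
    def test_rmse_approaches_noise_floor(self):
        """Held-out RMSE tends to the observation noise sigma as n grows."""
        sigma = 1.0
        rmses = {}
        for n in (300, 3000):
            V, Rpos, _ = linear_map_cohort(n + 200, noise_sigma=sigma, seed=9)
            model = fit_svd(V[:n], Rpos[:n], cutoff_ratio=1e6)
            resid = model.predict(V[n:]) - Rpos[n:]
            rmses[n] = np.sqrt(np.mean(resid**2))
        assert rmses[3000] <= rmses[300]
        assert rmses[3000] <= 1.1 * sigma


class TestScenarios:
    def test_exact_models_reproduce_truth(self):
        obs = simulate_observation_cohort(
            n_patients=3, n_fractions=3, n_images=15, observation_noise=0.0, seed=2
        )
        inter, intra = fit_models(obs, r_inter=1e6, r_intra=1e6)
        pred = track_without_dvi(inter, intra, obs)
        np.testing.assert_allclose(pred, obs.r, atol=1e-6)
        pred_dvi = track_with_dvi(intra, obs, true_fraction_means(obs))
        np.testing.assert_allclose(pred_dvi, obs.r, atol=1e-6)

    def test_zero_intra_model_predicts_fraction_constant(self):
        obs = simulate_observation_cohort(n_patients=2, n_images=10, seed=3)
        _, intra = fit_models(obs)
        zero_intra = type(intra)(
            coef=np.zeros_like(intra.coef), cutoff_ratio=7.0, kind="intra"
        )
        means = true_fraction_means(obs)
        pred = track_with_dvi(zero_intra, obs, means)
        dec = decompose(obs)
        np.testing.assert_allclose(pred, dec.r_mean[dec.group_index], atol=1e-12)

    def test_missing_fraction_mean_raises(self):
        obs = simulate_observation_cohort(n_patients=2, n_images=5, seed=4)
        _, intra = fit_models(obs)
        with pytest.raises(KeyError):
            track_with_dvi(intra, obs, {})

    def test_dvi_beats_no_dvi_with_baseline_noise(self):
        """Knowing each fraction's mean position can only help: paired
        comparison over 10 seeded cohorts with 5 mm baseline scatter."""
        for seed in range(10):
            obs = simulate_observation_cohort(
                n_patients=4, n_fractions=3, n_images=20,
                baseline_sigma=5.0, seed=seed,
            )
            result = loocv(obs)
            for s in ("no_dvi", "dvi"):
                assert (result.tables[s].patient == "all").sum() == 1
            for pid in obs.patients():
                med = {
                    s: float(
                        result.tables[s].set_index("patient").loc[pid, "median_mm"]
                    )
                    for s in ("no_dvi", "dvi")
                }
                assert med["dvi"] <= med["no_dvi"]


class TestLoocv:
    def test_two_identical_patients_transfer_exactly(self):
        base = simulate_observation_cohort(
            n_patients=1, n_fractions=3, n_images=20, observation_noise=0.0, seed=5
        )
        twin = ObservationSet(
            v=np.vstack([base.v, base.v]),
            r=np.vstack([base.r, base.r]),
            patient=np.r_[base.patient, base.patient + 1],
            fraction=np.r_[base.fraction, base.fraction],
            image=np.r_[base.image, base.image],
        )
        result = loocv(twin, r_inter=1e6, r_intra=1e6)
        pooled = result.tables["no_dvi"]
        assert float(pooled[pooled.patient == "all"].median_mm.iloc[0]) < 1e-6

    def test_table_shape(self):
        obs = simulate_observation_cohort(n_patients=3, n_images=8, seed=6)
        result = loocv(obs)
        assert len(result.tables["dvi"]) == 4  # 3 patients + pooled row

    def test_requires_two_patients(self):
        obs = simulate_observation_cohort(n_patients=1, n_images=5, seed=7)
        with pytest.raises(ValueError):
            loocv(obs)

    def test_fitting_set_table_shares_structure(self):
        obs = simulate_observation_cohort(n_patients=3, n_images=8, seed=8)
        table = fitting_set_table(obs)
        assert len(table) == 3
        assert {"median_mm", "lq_mm", "uq_mm"} <= set(table.columns)


class TestErrorStats:
    def test_three_four_five(self):
        stats = error_stats(np.array([[3.0, 4.0, 0.0]]), np.zeros((1, 3)))
        assert float(stats.set_index("direction").loc["3d", "median_mm"]) == 5.0

    def test_median_of_three(self):
        pred = np.array([[1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        stats = error_stats(pred, np.zeros((3, 3)))
        row = stats.set_index("direction").loc["left-right"]
        assert row.median_mm == 2.0 and row.min_mm == 1.0 and row.max_mm == 3.0

    def test_axis_medians_bounded_by_3d_median(self, rng):
        pred = rng.normal(size=(200, 3))
        truth = rng.normal(size=(200, 3))
        stats = error_stats(pred, truth).set_index("direction")
        for axis in ("left-right", "antero-posterior", "supero-inferior"):
            assert stats.loc[axis, "median_mm"] <= stats.loc["3d", "median_mm"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            error_stats(np.zeros((0, 3)), np.zeros((0, 3)))
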