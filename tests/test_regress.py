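"""NIPALS PLS, PCR, prediction, cross-validation, and fit metrics."""

import numpy as np
import pytest

import specfuse as sf
from specfuse.exceptions import (
    AlignmentError,
    InvalidInputError,
    RankDeficiencyError,
    UndefinedMetricError,
)
from specfuse.regress import pls_regression_vectors
from conftest import fit_variant


def ols_fitted(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return X @ beta


class TestFitPls:
    def test_exact_univariate_fit(self):
        X = np.array([[-1.0], [0.0], [1.0]])
        y = np.array([-2.0, 0.0, 2.0])
        model = sf.fit_pls(X, y, 1)
        assert model.regression_vector[0] == pytest.approx(2.0)
        assert sf.rmse(y, X @ model.regression_vector) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_full_rank_matches_ols(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(10, 6))
        X -= X.mean(axis=0)
        y = rng.normal(size=10)
        y -= y.mean()
        model = sf.fit_pls(X, y, 6)
        assert np.max(np.abs(X @ model.regression_vector - ols_fitted(X, y))) < 1e-8

    def test_orthogonal_response_gives_zero_vector(self, rng):
        X = rng.normal(size=(8, 3))
        X -= X.mean(axis=0)
        # project a random y onto the orthogonal complement of col(X)
        y = rng.normal(size=8)
        y -= X @ np.linalg.lstsq(X, y, rcond=None)[0]
        model = sf.fit_pls(X, y, 2)
        assert np.allclose(model.regression_vector, 0.0, atol=1e-10)

    def test_scores_orthogonal(self, rng):
        X = rng.normal(size=(30, 12))
        X -= X.mean(axis=0)
        y = X @ rng.normal(size=12) + 0.1 * rng.normal(size=30)
        model = sf.fit_pls(X, y - y.mean(), 6)
        G = model.x_scores.T @ model.x_scores
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(G))

    def test_rank_deficiency_raises(self, rng):
        t = rng.normal(size=10)
        X = np.outer(t, rng.normal(size=4))  # rank 1
        y = t.copy()
        with pytest.raises(RankDeficiencyError):
            sf.fit_pls(X - X.mean(axis=0), y - y.mean(), 2)

    def test_rmsec_non_increasing_in_components(self, rng):
        X = rng.normal(size=(40, 15))
        X -= X.mean(axis=0)
        y = X @ rng.normal(size=15) + rng.normal(size=40)
        y -= y.mean()
        prev = np.inf
        for k in range(1, 9):
            model = sf.fit_pls(X, y, k)
            err = sf.rmse(y, X @ model.regression_vector)
            assert err <= prev + 1e-12
            prev = err

    def test_incremental_regression_vectors_match_refits(self, rng):
        X = rng.normal(size=(25, 10))
        X -= X.mean(axis=0)
        y = X @ rng.normal(size=10) + rng.normal(size=25)
        y -= y.mean()
        betas = pls_regression_vectors(X, y, 5)
        for k in range(1, 6):
            assert np.allclose(
                betas[:, k - 1], sf.fit_pls(X, y, k).regression_vector, atol=1e-10
            )


class TestFitPcr:
    @pytest.mark.parametrize("seed", range(5))
    def test_full_rank_matches_ols(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(10, 6))
        X -= X.mean(axis=0)
        y = rng.normal(size=10)
        y -= y.mean()
        model = sf.fit_pcr(X, y, 6)
        assert np.max(np.abs(X @ model.regression_vector - ols_fitted(X, y))) < 1e-8

    def test_dominant_direction_aligned_with_response(self, rng):
        p1 = np.array([1.0, 0.0, 0.0])
        t1 = rng.normal(scale=10.0, size=40)
        X = np.outer(t1, p1) + rng.normal(scale=1e-6, size=(40, 3))
        X -= X.mean(axis=0)
        y = X[:, 0].copy()
        model = sf.fit_pcr(X, y, 1)
        assert sf.rmse(y, X @ model.regression_vector) < 1e-4

    def test_response_on_minor_component_needs_pls(self, rng):
        # variance direction and response direction decoupled: PCR with one
        # component misses the response; PLS with one component nails it.
        n = 60
        t1 = rng.normal(scale=10.0, size=n)  # dominant, response-irrelevant
        t2 = rng.normal(scale=0.3, size=n)  # minor, carries the response
        t1 -= t1.mean()
        t2 -= t2.mean()
        t2 -= t1 * (t1 @ t2) / (t1 @ t1)  # exact orthogonality
        X = np.column_stack([t1, t2])
        y = t2.copy()
        pcr = sf.fit_pcr(X, y, 1)
        pls = sf.fit_pls(X, y, 1)
        r2_pcr = sf.r_squared(y, X @ pcr.regression_vector)
        r2_pls = sf.r_squared(y, X @ pls.regression_vector)
        assert r2_pcr < 0.1
        assert r2_pls > 0.99

    def test_rank_deficiency_raises(self, rng):
        t = rng.normal(size=10)
        X = np.outer(t, rng.normal(size=4))
        with pytest.raises(RankDeficiencyError):
            sf.fit_pcr(X - X.mean(axis=0), t - t.mean(), 3)


class TestPredict:
    def test_training_identity_for_exact_fit(self):
        X = np.array([[-1.0], [0.0], [1.0]])
        y = np.array([-2.0, 0.0, 2.0])
        model = sf.fit_pls(X, y, 1)
        model.x_mean = np.zeros(1)
        model.y_mean = 0.0
        assert np.allclose(sf.predict(model, X), y, atol=1e-12)

    def test_mean_spectrum_predicts_mean_concentration(self, fused_default, default_plan):
        model = fit_variant(fused_default, default_plan, "PLS", 5)
        pred = sf.predict(model, model.x_mean[None, :])
        assert pred[0] == pytest.approx(model.y_mean, abs=1e-10)

    def test_feature_count_mismatch_rejected(self, rng):
        X = rng.normal(size=(6, 4))
        model = sf.fit_pls(X - X.mean(0), rng.normal(size=6), 2)
        with pytest.raises(AlignmentError):
            sf.predict(model, rng.normal(size=(3, 5)))

    def test_consistent_column_permutation_invariance(self, rng):
        X = rng.normal(size=(30, 8))
        X -= X.mean(axis=0)
        y = X @ rng.normal(size=8) + 0.05 * rng.normal(size=30)
        y -= y.mean()
        Xnew = rng.normal(size=(10, 8))
        perm = rng.permutation(8)
        m1 = sf.fit_pls(X, y, 4)
        m2 = sf.fit_pls(X[:, perm], y, 4)
        assert np.allclose(
            Xnew @ m1.regression_vector,
            Xnew[:, perm] @ m2.regression_vector,
            atol=1e-8,
        )

    def test_raw_block_prediction_round_trip(self, default_blocks, fused_default, default_plan):
        model = fit_variant(fused_default, default_plan, "PLS", 10)
        model.preprocess = sf.PreprocessSpec()
        model.masks = dict(sf.DEFAULT_MASKS)
        model.provenance = fused_default.provenance
        # predicting from raw blocks must replay the stored chain exactly
        mir, nir = default_blocks
        via_blocks = sf.predict(model, [mir, nir])
        via_matrix = sf.predict(model, fused_default.X)
        assert np.allclose(via_blocks, via_matrix, atol=1e-10)


class TestNoiselessRecovery:
    def make_fused(self, apply_snv=False):
        cfg = sf.SimulationConfig(
            noise_sd=0.0,
            baseline_amplitude=0.0,
            replicate_effect_sd=0.0,
            matrix_heterogeneity_sd=0.0,
            scatter_sd=0.01,  # keeps the per-block designs full rank
            n_spectra_per_sample=3,
        )
        mir, nir = sf.simulate_dataset(cfg)
        pipeline = sf.PreprocessPipeline(sf.PreprocessSpec(apply_snv=apply_snv))
        return (
            pipeline.transform_block(mir),
            pipeline.transform_block(nir),
        )

    def test_single_block_exact_with_two_lv(self):
        _, nir = self.make_fused()
        fused = sf.fuse_blocks([nir], {"NIR": None})
        plan = sf.split_dataset(fused)
        model = fit_variant(fused, plan, "PLS", 2)
        err = np.max(np.abs(sf.predict(model, fused.X) - fused.concentration))
        assert err < 1e-6

    def test_fused_exact_with_three_lv(self):
        mir, nir = self.make_fused()
        fused = sf.fuse_blocks([mir, nir])
        plan = sf.split_dataset(fused)
        for method, k in (("PLS", 3), ("PCR", 3)):
            model = fit_variant(fused, plan, method, k)
            err = np.max(np.abs(sf.predict(model, fused.X) - fused.concentration))
            assert err < 1e-6, method


class TestCrossValidate:
    def test_matches_manual_two_fold_oracle(self):
        # 4 samples x 2 spectra; venetian blinds with 2 splits holds out
        # samples {0, 2} then {1, 3}
        X = np.array(
            [[0.0], [0.1], [1.0], [1.1], [2.0], [2.1], [3.0], [3.1]]
        )
        y = np.array([0.0, 0.1, 1.0, 1.1, 2.0, 2.1, 3.0, 3.1])
        groups = np.array(["a", "a", "b", "b", "c", "c", "d", "d"])
        got = sf.cross_validate(X, y, groups, "PLS", 1, n_splits=2)

        sq = 0.0
        for held in ({"a", "c"}, {"b", "d"}):
            test = np.asarray([g in held for g in groups])
            Xt, yt = X[~test], y[~test]
            xm, ym = Xt.mean(axis=0), yt.mean()
            beta = np.linalg.lstsq(Xt - xm, yt - ym, rcond=None)[0]
            pred = (X[test] - xm) @ beta + ym  # 1 LV on 1 column == OLS
            sq += float(np.sum((pred - y[test]) ** 2))
        expected = np.sqrt(sq / len(y))
        assert got[0] == pytest.approx(expected, abs=1e-12)

    def test_noiseless_linear_data_gives_zero_rmsecv(self):
        t = np.repeat(np.linspace(-1, 1, 8), 2)
        X = t[:, None]
        y = 3.0 * t
        groups = np.repeat(np.arange(8), 2)
        out = sf.cross_validate(X, y, groups, "PLS", 1, n_splits=4)
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_rmsecv_curve_has_interior_minimum_on_noisy_data(self):
        argmins, edge_excess = [], []
        for seed in range(3):
            mir, nir = sf.simulate_dataset(sf.SimulationConfig(seed=seed))
            pipeline = sf.PreprocessPipeline()
            fused = sf.fuse_blocks(
                [pipeline.transform_block(mir), pipeline.transform_block(nir)]
            )
            plan = sf.split_dataset(fused)
            cal = plan.calibration_mask(fused.sample_id)
            curve = sf.cross_validate(
                fused.X[cal],
                fused.concentration[cal],
                fused.sample_id[cal],
                "PLS",
                20,
                n_splits=10,
            )
            argmins.append(int(np.argmin(curve)) + 1)
            edge_excess.append(min(curve[0], curve[-1]) - curve.min())
        k_star = int(np.median(argmins))
        assert 1 < k_star < 20  # under- then over-fitting: U-shaped curve
        assert np.median(edge_excess) > 0

    def test_degenerate_fold_warns(self):
        X = np.arange(8.0)[:, None]
        # training part of the first fold (odd groups) has constant response
        y = np.array([0.0, 1.0, 2.0, 1.0, 4.0, 1.0, 6.0, 1.0])
        groups = np.arange(8)
        with pytest.warns(UserWarning, match="degenerate"):
            sf.cross_validate(X, y, groups, "PLS", 1, n_splits=2)


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([0.0, 1.0, 2.0])
        assert sf.rmse(y, y) == 0.0
        assert sf.r_squared(y, y) == 1.0

    def test_arithmetic_example(self):
        y = np.array([0.0, 2.0])
        yhat = np.array([1.0, 1.0])
        assert sf.rmse(y, yhat) == pytest.approx(1.0)
        assert sf.r_squared(y, yhat) == pytest.approx(0.0)

    def test_matches_direct_formula(self, rng):
        y = rng.normal(size=50)
        yhat = y + rng.normal(scale=0.3, size=50)
        assert sf.rmse(y, yhat) == pytest.approx(
            np.sqrt(np.mean((yhat - y) ** 2)), abs=1e-14
        )
        expected_r2 = 1 - np.sum((yhat - y) ** 2) / np.sum((y - y.mean()) ** 2)
        assert sf.r_squared(y, yhat) == pytest.approx(expected_r2, abs=1e-14)

    def test_zero_variance_response_rejected(self):
        with pytest.raises(UndefinedMetricError):
            sf.r_squared(np.ones(5), np.zeros(5))

    def test_compute_metrics_contexts(self, rng):
        y = rng.normal(size=10)
        yhat = y + 0.1
        assert "r2" in sf.compute_metrics(y, yhat, "prediction")
        assert "r2" not in sf.compute_metrics(y, yhat, "calibration")
        with pytest.raises(InvalidInputError):
            sf.compute_metrics(y, yhat, "bogus")


def test_regression_vector_peaks_at_analyte_bands():
    """On near-noiseless MIR data the regression vector is structured around
    the analyte's band positions (the bands that drive the correlation)."""
    cfg = sf.SimulationConfig(
        noise_sd=0.0,
        baseline_amplitude=0.0,
        replicate_effect_sd=0.0,
        matrix_heterogeneity_sd=0.0,
        scatter_sd=0.01,
        n_spectra_per_sample=3,
    )
    mir, _ = sf.simulate_dataset(cfg)
    pipeline = sf.PreprocessPipeline(sf.PreprocessSpec(apply_snv=False))
    fused = sf.fuse_blocks([pipeline.transform_block(mir)], {"MIR": (800.0, 1800.0)})
    Xc = fused.X - fused.X.mean(axis=0)
    yc = fused.concentration - fused.concentration.mean()
    model = sf.fit_pls(Xc, yc, 2)
    b = np.abs(model.regression_vector)
    axis = fused.provenance["value"].to_numpy()
    is_peak = np.zeros_like(b, dtype=bool)
    is_peak[1:-1] = (b[1:-1] >= b[:-2]) & (b[1:-1] >= b[2:])
    peak_positions = axis[is_peak]
    step = float(axis[1] - axis[0])
    for center in (906.0, 1036.0, 1111.0, 1330.0, 1414.0):
        assert np.min(np.abs(peak_positions - center)) <= step, center
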