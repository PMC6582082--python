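"""MaxEnt core: features, the L1 objective, its optimizer and contributions."""

import numpy as np
import pytest
from scipy.special import logsumexp

from breedsuit import (
    MaxentConfig,
    MaxentModel,
    build_features,
    default_classes_for,
    fit_maxent,
    fit_occurrence_model,
    predict,
    sample_presences,
    variable_contributions,
    TrueSuitability,
)
from breedsuit.maxent import default_class_beta, regularized_objective


def grid_search_1d(F, pbar, betas, lo=-50.0, hi=50.0, step=1e-4):
    """Dense 1-D scan of the regularized objective (independent oracle)."""
    lam = np.arange(lo, hi + step, step)
    smooth = -lam * pbar[0] + logsumexp(F[:, :1] * lam[None, :], axis=0)
    J = smooth + betas[0] * np.abs(lam)
    k = int(np.argmin(J))
    return lam[k], J[k]


class TestFeatures:
    def test_linear_is_minmax_scaled(self):
        v = np.array([[2.0], [4.0], [10.0]])
        exp = build_features(v, {"linear"})
        F = exp.transform(v)
        np.testing.assert_allclose(F[:, 0], [0.0, 0.25, 1.0])

    def test_class_combinatorics(self):
        v = np.random.default_rng(0).uniform(size=(20, 2))
        exp = build_features(v, {"linear", "quadratic", "product"})
        assert exp.n_features == 2 + 2 + 1

    def test_hinge_count_and_range(self):
        v = np.random.default_rng(1).uniform(size=(30, 1))
        exp = build_features(v, {"hinge"}, n_hinge_knots=4)
        # forward at 4 knots + reverse at the 3 interior knots
        assert exp.n_features == 7
        F = exp.transform(v)
        assert F.min() >= 0.0 and F.max() <= 1.0 + 1e-12

    def test_constant_variable_dropped(self):
        v = np.column_stack([np.ones(10), np.arange(10.0)])
        exp = build_features(v, {"linear"}, variable_names=["flat", "ramp"])
        assert exp.dropped == ["flat"]
        assert exp.variable_names == ["ramp"]

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            build_features(np.ones((5, 2)), {"linear"})

    def test_features_unit_interval_on_background(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(50, 3))
        exp = build_features(v, {"linear", "quadratic", "product", "hinge"},
                             n_hinge_knots=5)
        F = exp.transform(v)
        assert F.min() >= -1e-12 and F.max() <= 1.0 + 1e-12


class TestDefaultsTables:
    def test_class_schedule_by_presence_count(self):
        assert default_classes_for(5) == {"linear"}
        assert default_classes_for(12) == {"linear", "quadratic"}
        assert "hinge" in default_classes_for(40)
        assert default_classes_for(150) == {"linear", "quadratic",
                                            "product", "hinge"}

    def test_beta_interpolation_monotone(self):
        ms = [1, 10, 30, 60, 100, 500]
        for cls in ("linear", "quadratic", "product"):
            betas = [default_class_beta(cls, m) for m in ms]
            assert all(a >= b for a, b in zip(betas, betas[1:]))


class TestFitOracle:
    def test_one_feature_grid_search(self):
        """The spec's core oracle: CD solution vs a dense 1-D objective scan."""
        rng = np.random.default_rng(0)
        B = np.sort(rng.uniform(0, 1, 10))[:, None]
        P = B[-5:]  # presences at the 5 highest-value cells
        model = fit_maxent(P, B, MaxentConfig(classes={"linear"},
                                              reg_multiplier=1.0,
                                              tol=1e-14, max_iter=10_000))
        F = model.expansion.transform(B)
        pbar = model.expansion.transform(P).mean(axis=0)
        lam_star, J_star = grid_search_1d(F, pbar, model.reg_betas)
        assert abs(model.lambdas[0] - lam_star) <= 1e-4
        assert model.objective_value <= J_star + 1e-8

    def test_presences_equal_background_gives_zero(self):
        rng = np.random.default_rng(1)
        B = rng.uniform(size=(20, 2))
        model = fit_maxent(B, B, MaxentConfig(classes={"linear"},
                                              tol=1e-14, max_iter=5000))
        np.testing.assert_allclose(model.lambdas, 0.0, atol=1e-8)
        # raw distribution over background is uniform
        s = model.expansion.transform(B) @ model.lambdas
        raw = np.exp(s - model.log_Z)
        np.testing.assert_allclose(raw, 1.0 / 20, atol=1e-10)

    def test_huge_regularization_kills_all_weights(self):
        rng = np.random.default_rng(2)
        B = rng.uniform(size=(15, 2))
        P = B[:4]
        model = fit_maxent(P, B, MaxentConfig(classes={"linear"},
                                              reg_multiplier=1e6))
        assert np.all(np.abs(model.lambdas) <= 1e-6)
        assert abs(model.entropy_H - np.log(15)) < 1e-9

    def test_regularization_monotonicity(self):
        rng = np.random.default_rng(3)
        B = rng.normal(size=(40, 2))
        P = B[np.argsort(B[:, 0])[-10:]]
        norms = []
        for mult in (0.5, 1.0, 2.0, 5.0):
            m = fit_maxent(P, B, MaxentConfig(classes={"linear"},
                                              reg_multiplier=mult,
                                              tol=1e-12, max_iter=5000))
            norms.append(np.abs(m.lambdas).sum())
        assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))

    def test_objective_convexity_along_segments(self):
        rng = np.random.default_rng(4)
        B = rng.normal(size=(30, 3))
        P = B[:8]
        model = fit_maxent(P, B, MaxentConfig(classes={"linear"}))
        F = model.expansion.transform(B)
        pbar = model.expansion.transform(P).mean(axis=0)
        for _ in range(3):
            a, b = rng.normal(size=(2, F.shape[1]))
            Ja = regularized_objective(a, F, pbar, model.reg_betas)
            Jb = regularized_objective(b, F, pbar, model.reg_betas)
            for t in (1 / 6, 2 / 6, 3 / 6, 4 / 6, 5 / 6):
                Jt = regularized_objective((1 - t) * a + t * b, F, pbar,
                                           model.reg_betas)
                assert Jt <= (1 - t) * Ja + t * Jb + 1e-9

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_maxent(np.empty((0, 1)), np.ones((5, 1)))
        with pytest.raises(ValueError):
            fit_maxent(np.ones((2, 1)), np.ones((1, 1)))
        with pytest.raises(ValueError):
            fit_maxent(np.array([[np.nan]]), np.ones((5, 1)))


class TestPrediction:
    def test_raw_normalized_over_background(self, small_world, quick_cfg):
        model = fit_occurrence_model(small_world.stack,
                                     small_world.occurrences, quick_cfg)
        raw = predict(model, small_world.stack, scale="raw")
        assert abs(np.nansum(raw.values) - 1.0) <= 1e-8

    def test_uniform_model_logistic_half(self):
        rng = np.random.default_rng(5)
        B = rng.uniform(size=(25, 1))
        model = fit_maxent(B[:5], B, MaxentConfig(classes={"linear"},
                                                  reg_multiplier=1e6))
        vals = model.predict_values(B, scale="logistic")
        np.testing.assert_allclose(vals, 0.5, atol=1e-6)
        raw = model.predict_values(B, scale="raw")
        np.testing.assert_allclose(raw, 1 / 25, atol=1e-9)

    def test_logistic_monotone_in_raw(self, small_world, quick_cfg):
        model = fit_occurrence_model(small_world.stack,
                                     small_world.occurrences, quick_cfg)
        raw = predict(model, small_world.stack, scale="raw").valid_values()
        lg = predict(model, small_world.stack, scale="logistic").valid_values()
        order = np.argsort(raw)
        assert np.all(np.diff(lg[order]) >= -1e-15)

    def test_clamping_above_training_max(self):
        rng = np.random.default_rng(6)
        B = rng.uniform(size=(30, 1))
        model = fit_maxent(B[-8:], B, MaxentConfig(classes={"linear"}))
        at_max = model.predict_values(np.array([[B.max()]]), scale="raw")
        beyond = model.predict_values(np.array([[B.max() + 10]]), scale="raw")
        np.testing.assert_allclose(beyond, at_max)

    def test_missing_layer_named_in_error(self, small_world, quick_cfg):
        model = fit_occurrence_model(small_world.stack,
                                     small_world.occurrences, quick_cfg)
        partial = type(small_world.stack)(
            layers={"var1": small_world.stack.layers["var1"]},
            transform=small_world.stack.transform,
            missing=small_world.stack.missing,
        )
        with pytest.raises(KeyError, match="var2"):
            predict(model, partial)

    def test_serialization_round_trip(self, small_world, quick_cfg, tmp_path):
        model = fit_occurrence_model(small_world.stack,
                                     small_world.occurrences, quick_cfg)
        model.save(tmp_path / "m.json")
        back = MaxentModel.load(tmp_path / "m.json")
        a = predict(model, small_world.stack, scale="logistic").values
        b = predict(back, small_world.stack, scale="logistic").values
        np.testing.assert_array_equal(a, b)


class TestContributions:
    def _single_var_model(self):
        rng = np.random.default_rng(7)
        B = np.column_stack([np.linspace(0, 1, 40), rng.uniform(size=40)])
        P = B[np.argsort(B[:, 0])[-10:]]
        model = fit_maxent(P, B, MaxentConfig(classes={"linear"},
                                              tol=1e-12, max_iter=5000))
        # var2 may pick up a small weight by chance; zero it explicitly to
        # construct the single-active-variable case the contract describes
        model.lambdas[1] = 0.0
        return model, P, B

    def test_inactive_variable_gets_zero(self):
        model, P, B = self._single_var_model()
        table = variable_contributions(model, P, B, method="permutation",
                                       n_repeats=3, seed=0)
        pct = table.as_dict()
        assert pct["var1"] == pytest.approx(100.0, abs=1e-9)
        assert pct["var2"] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("method", ["permutation", "path"])
    def test_percent_sum_and_bounds(self, small_world, quick_cfg, method):
        from breedsuit import extract_covariates
        model = fit_occurrence_model(small_world.stack,
                                     small_world.occurrences, quick_cfg)
        P, _ = extract_covariates(small_world.stack, small_world.occurrences)
        B = small_world.stack.covariate_matrix()
        table = variable_contributions(model, P, B, method=method,
                                       n_repeats=2, seed=1)
        pct = np.array([p for _, p in table.rows])
        assert np.all(pct >= 0)
        assert pct.sum() == pytest.approx(100.0, abs=1e-6)

    def test_informative_variables_rank_top(self, quick_cfg):
        """Truth loads on var1/var2 only: they must take the top-2 shares."""
        from breedsuit import extract_covariates, generate_world
        hits = 0
        for seed in range(5):
            w = generate_world(n_rows=50, n_cols=50, n_vars=5, n_points=200,
                               seed=100 + seed)
            model = fit_occurrence_model(w.stack, w.occurrences, quick_cfg)
            P, _ = extract_covariates(w.stack, w.occurrences)
            B = w.stack.covariate_matrix()
            table = variable_contributions(model, P, B, method="permutation",
                                           n_repeats=3, seed=seed)
            hits += set(table.top(2)) == {"var1", "var2"}
        assert hits >= 4

    def test_unknown_method_rejected(self, small_world, quick_cfg):
        model = fit_occurrence_model(small_world.stack,
                                     small_world.occurrences, quick_cfg)
        with pytest.raises(ValueError):
            variable_contributions(model, np.ones((2, 3)), np.ones((4, 3)),
                                   method="shapley")


def test_degenerate_single_cell_warns(small_world, quick_cfg):
    from breedsuit import OccurrenceSet
    pt = small_world.occurrences.points[:1]
    occ = OccurrenceSet("one", np.repeat(pt, 5, axis=0))
    with pytest.warns(UserWarning, match="single raster cell"):
        model = fit_occurrence_model(small_world.stack, occ, quick_cfg)
    assert model.presence_count == 1
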