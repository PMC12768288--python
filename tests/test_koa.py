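import numpy as np
import pytest

from seedstack.koa import (
    KOAConfig,
    Parameter,
    SearchSpace,
    decode_hyperparameters,
    distance_adaptive_update,
    initialize_population,
    optimize,
    orbital_position_update,
)
from seedstack.tuning import (
    FAMILIES,
    TuningConfig,
    build_model,
    default_search_space,
    tune_model,
    tuning_objective,
)

BOX2D = SearchSpace((Parameter("x", -5, 5), Parameter("y", -5, 5)))


def sphere(p):
    return float(p @ p)


class TestSearchSpace:
    def test_validation(self):
        with pytest.raises(ValueError):
            Parameter("a", 2, 1)
        with pytest.raises(ValueError):
            SearchSpace((Parameter("a", 0, 1), Parameter("a", 0, 2)))
        with pytest.raises(ValueError):
            SearchSpace(())

    def test_decode_dt_row(self):
        params = decode_hyperparameters(np.array([13.4, 0.45]), default_search_space("DT"))
        assert params == {"max_depth": 13, "max_features": 0.45}

    def test_decode_mlp_hidden_sizes(self):
        params = decode_hyperparameters(np.array([96.2, 74.4]), default_search_space("MLP"))
        assert (params["k1"], params["k2"]) == (96, 74)

    def test_integer_endpoints_decode_to_themselves(self):
        space = default_search_space("KNN")
        assert decode_hyperparameters(np.array([1.0, 5.0]), space) == {"n_neighbors": 1, "p": 5}

    def test_out_of_bounds_position_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            decode_hyperparameters(np.array([200.0, 0.5]), default_search_space("DT"))


class TestPositionUpdates:
    def test_orbital_identity_case(self):
        x = np.array([1.0, -2.0, 3.0])
        out = orbital_position_update(x, np.zeros(3), np.ones(3), 1.0, 0.5, 0.5, np.zeros(3))
        assert np.array_equal(out, x)

    def test_orbital_hand_value(self):
        out = orbital_position_update(
            np.array([0.0]), np.array([0.5]), np.array([1.0]),
            F=1.0, Fg=0.2, r=0.3, U=np.array([1.0]),
        )
        assert out[0] == pytest.approx(1.0)

    def test_orbital_matches_direct_formula_on_random_instances(self, rng):
        for _ in range(50):
            x, v, s = rng.normal(size=(3, 5))
            F = rng.choice([-1.0, 1.0])
            Fg, r = rng.random(), rng.normal()
            U = rng.integers(0, 2, 5).astype(float)
            out = orbital_position_update(x, v, s, F, Fg, r, U)
            assert np.allclose(out, x + F * v + (Fg + abs(r)) * U * (s - x))

    def test_orbital_moves_toward_sun_iff_pull_in_unit_band(self, rng):
        """With U = 1 and F·V = 0: closer to the Sun ⇔ Fg + |r| ∈ (0, 2)."""
        for _ in range(50):
            x, s = rng.normal(size=(2, 5))
            pull = rng.uniform(0, 3)
            out = orbital_position_update(x, np.zeros(5), s, 1.0, pull, 0.0, np.ones(5))
            closer = np.linalg.norm(out - s) < np.linalg.norm(x - s)
            assert closer == (0 < pull < 2)

    def test_distance_update_keeps_position_when_mask_is_ones(self):
        x = np.array([1.0, 2.0])
        out = distance_adaptive_update(x, np.zeros(2), np.ones(2), np.ones(2), np.ones(2), 0.7)
        assert np.array_equal(out, x)

    def test_distance_update_hand_value(self):
        out = distance_adaptive_update(
            np.array([0.0]), np.array([3.0]), np.array([3.0]), np.array([0.0]),
            U1=np.array([0.0]), h=0.0,
        )
        assert out[0] == pytest.approx(2.0)

    def test_distance_update_h_term_cancels_at_mean(self):
        x, s, a = np.array([1.0]), np.array([2.0]), np.array([3.0])
        mean = (x + s + a) / 3
        out = distance_adaptive_update(x, s, a, mean, U1=np.array([0.0]), h=1.0)
        assert out[0] == pytest.approx(mean[0])

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError):
            orbital_position_update(np.zeros(2), np.zeros(3), np.zeros(2), 1, 0, 0, np.zeros(2))
        with pytest.raises(ValueError):
            distance_adaptive_update(np.zeros(2), np.zeros(2), np.zeros(3), np.zeros(2),
                                     np.zeros(2), 0.5)


class TestInitialization:
    def test_bounds_seed_and_sun(self):
        cfg = KOAConfig(population_size=8, max_iterations=5)
        state = initialize_population(BOX2D, cfg, np.random.default_rng(4), sphere)
        pos = np.array([p.position for p in state.planets])
        assert np.all(pos >= -5) and np.all(pos <= 5)
        assert state.sun_fitness == min(p.fitness for p in state.planets)
        state2 = initialize_population(BOX2D, cfg, np.random.default_rng(4), sphere)
        assert np.array_equal(pos, np.array([p.position for p in state2.planets]))


class TestOptimize:
    def test_constant_objective(self):
        _, best, history = optimize(lambda p: 7.0, BOX2D, KOAConfig(seed=0, max_iterations=5))
        assert best == 7.0 and history[0] == 7.0

    def test_history_non_increasing_any_objective(self):
        rastrigin = lambda p: float(10 * len(p) + np.sum(p**2 - 10 * np.cos(2 * np.pi * p)))
        for seed in range(5):
            for obj in (sphere, rastrigin):
                _, _, history = optimize(obj, BOX2D, KOAConfig(seed=seed, max_iterations=30))
                assert np.all(np.diff(history) <= 0)

    def test_non_finite_objective_treated_as_inf(self):
        def nasty(p):
            return np.nan if p[0] > 0 else sphere(p)

        with pytest.warns(UserWarning, match="non-finite"):
            _, best, _ = optimize(nasty, BOX2D, KOAConfig(seed=1, max_iterations=10))
        assert np.isfinite(best)

    def test_deterministic_under_seed(self):
        a = optimize(sphere, BOX2D, KOAConfig(seed=5))
        b = optimize(sphere, BOX2D, KOAConfig(seed=5))
        assert np.array_equal(a[0], b[0]) and a[1] == b[1]

    def test_beats_random_search_on_rosenbrock(self):
        rosen = lambda p: float((1 - p[0]) ** 2 + 100 * (p[1] - p[0] ** 2) ** 2)
        cfg = KOAConfig(population_size=10, max_iterations=50)
        budget = 10 + 10 * 50
        koa_best, rs_best = [], []
        for seed in range(20):
            koa_best.append(optimize(rosen, BOX2D, KOAConfig(**{**cfg.__dict__, "seed": seed}))[1])
            pts = np.random.default_rng(10_000 + seed).uniform(-5, 5, size=(budget, 2))
            rs_best.append(min(rosen(p) for p in pts))
        assert np.median(koa_best) < np.median(rs_best)


@pytest.fixture(scope="module")
def blobs():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(90, 6))
    y = np.repeat(["A", "B", "C"], 30)
    X[y == "B", 0] += 2.5
    X[y == "C", 1] += 2.5
    return X, y


class TestTuning:
    def test_unknown_family_error_lists_supported(self, blobs):
        with pytest.raises(ValueError, match="DT.*GBDT"):
            tune_model("XGB", *blobs)

    def test_fitness_matches_independent_holdout_computation(self, blobs):
        """Oracle probe: the objective equals a manually coded holdout error."""
        from sklearn.model_selection import train_test_split

        X, y = blobs
        cfg = TuningConfig()
        obj = tuning_objective("DT", X, y, cfg, seed=3)
        position = np.array([10.0, 0.5])
        Xf, Xv, yf, yv = train_test_split(X, y, test_size=0.25, stratify=y, random_state=3)
        model = build_model("DT", {"max_depth": 10, "max_features": 0.5}, seed=3).fit(Xf, yf)
        manual = float(np.mean(model.predict(Xv) != yv))
        assert obj(position) == pytest.approx(manual, abs=1e-12)

    def test_cv_fitness_matches_manual_fold_average(self, blobs):
        from sklearn.model_selection import StratifiedKFold

        X, y = blobs
        obj = tuning_objective("KNN", X, y, TuningConfig(fitness="cv", cv_folds=3), seed=2)
        params = {"n_neighbors": 5, "p": 2}
        errs = []
        for tr, va in StratifiedKFold(3, shuffle=True, random_state=2).split(X, y):
            m = build_model("KNN", params, seed=2).fit(X[tr], y[tr])
            errs.append(np.mean(m.predict(X[va]) != y[va]))
        assert obj(np.array([5.0, 2.0])) == pytest.approx(float(np.mean(errs)), abs=1e-12)

    def test_tuning_deterministic(self, blobs):
        X, y = blobs
        cfg = TuningConfig(koa=KOAConfig(population_size=4, max_iterations=4))
        t1 = tune_model("DT", X, y, config=cfg, seed=7)
        t2 = tune_model("DT", X, y, config=cfg, seed=7)
        assert t1.best_params == t2.best_params
        assert np.array_equal(t1.history, t2.history)

    def test_tuned_no_worse_than_midpoint_params(self, blobs):
        """Optimizer-vs-baseline: majority over 5 seeds."""
        X, y = blobs
        space = default_search_space("DT")
        mid = (space.lower() + space.upper()) / 2
        wins = 0
        for seed in range(5):
            cfg = TuningConfig(koa=KOAConfig(population_size=5, max_iterations=8))
            obj = tuning_objective("DT", X, y, cfg, seed=seed)
            tuned = tune_model("DT", X, y, config=cfg, seed=seed)
            wins += int(tuned.best_fitness <= obj(mid))
        assert wins >= 3

    def test_all_families_build(self):
        space_params = {
            "DT": {"max_depth": 5, "max_features": 0.5},
            "SVM": {"C": 10.0, "gamma": 0.3},
            "KNN": {"n_neighbors": 3, "p": 2},
            "MLP": {"k1": 12, "k2": 10},
            "RF": {"n_estimators": 10, "max_depth": 5, "max_features": 0.5},
            "GBDT": {"n_estimators": 10, "max_depth": 5, "max_features": 0.5},
        }
        for fam in FAMILIES:
            model = build_model(fam, space_params[fam], seed=0)
            assert hasattr(model, "fit")
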