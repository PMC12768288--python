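import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from seedstack.cars import (
    PLSConfig,
    ars_sample,
    best_iteration_index,
    edf_schedule,
    encode_labels,
    pls_feature_weights,
    rmsecv,
    run_cars,
)


class TestEDFSchedule:
    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(3, 2000), st.integers(2, 100))
    def test_boundary_identities(self, m, N):
        s = edf_schedule(m, N)
        assert s.ratios[0] == pytest.approx(1.0, abs=1e-12)
        assert m * s.ratios[-1] == pytest.approx(2.0, abs=1e-12)
        assert np.all(np.diff(s.ratios) < 0)

    def test_retention_at_run_9_matches_direct_evaluation(self):
        # independent closed-form evaluation for m = 700, N = 20
        a = (700 / 2) ** (1 / 19)
        k = np.log(700 / 2) / 19
        expected = round(700 * a * np.exp(-9 * k))
        assert expected == 59  # 700 · 350^(−8/19), frozen from the closed form
        assert edf_schedule(700, 20).n_retained(9) == expected

    def test_final_run_targets_two_features(self):
        assert edf_schedule(700, 20).n_retained(20) == 2

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            edf_schedule(2, 10)
        with pytest.raises(ValueError):
            edf_schedule(700, 1)


class TestPLSWeights:
    def test_weights_nonnegative_and_finite_under_collinearity(self, rng):
        X = rng.normal(size=(40, 5))
        X[:, 4] = X[:, 3]  # duplicate column
        y = encode_labels(np.repeat(["A", "B"], 20))
        w = pls_feature_weights(X, y, PLSConfig(n_components=3), rng)
        assert w.shape == (5,)
        assert np.all(w >= 0) and np.all(np.isfinite(w))

    def test_informative_feature_wins_majority_of_seeds(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(120, 6))
            y = 3.0 * X[:, 0]  # linear in feature 0 only
            w = pls_feature_weights(X, y, PLSConfig(n_components=3), rng)
            wins += int(np.argmax(w) == 0)
        assert wins >= 15

    def test_one_hot_encoding_shape(self):
        Y = encode_labels(np.array(["b", "a", "c", "a"]), "one-hot")
        assert Y.shape == (4, 3)
        assert np.array_equal(Y.sum(axis=1), np.ones(4))
        assert np.array_equal(
            encode_labels(np.array(["b", "a", "c", "a"])).ravel(), [2, 1, 3, 1]
        )


class TestARS:
    def test_degenerate_weight_selects_only_that_feature(self, rng):
        w = np.array([0.0, 1.0, 0.0])
        assert ars_sample(w, 3, rng).tolist() == [1]

    def test_zero_weights_fall_back_to_uniform_with_warning(self, rng):
        with pytest.warns(UserWarning, match="zero"):
            out = ars_sample(np.zeros(5), 5, rng)
        assert set(out) <= set(range(5))

    def test_seed_contract(self):
        w = np.arange(1.0, 11.0)
        a = ars_sample(w, 6, np.random.default_rng(7))
        b = ars_sample(w, 6, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_expected_unique_count_matches_closed_form(self):
        # m equal-weight features, m draws with replacement:
        # E[#unique] = m(1 − (1 − 1/m)^m)
        m, trials = 20, 1000
        rng = np.random.default_rng(0)
        counts = [len(ars_sample(np.ones(m), m, rng)) for _ in range(trials)]
        expected = m * (1 - (1 - 1 / m) ** m)
        se = np.std(counts, ddof=1) / np.sqrt(trials)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_negative_weights_rejected(self, rng):
        with pytest.raises(ValueError):
            ars_sample(np.array([-1.0, 2.0]), 1, rng)


class TestRMSECV:
    def test_noiseless_linear_limit(self, rng):
        X = rng.normal(size=(60, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0])
        err = rmsecv(X, y, PLSConfig(n_components=4, cv_folds=5), rng=0)
        assert err < 1e-8

    def test_matches_brute_force_fold_loop(self, rng):
        """Independent oracle: explicit fold loop with pooled squared error."""
        X = rng.normal(size=(30, 5))
        y = (X @ rng.normal(size=5) + rng.normal(size=30) * 0.3).reshape(-1, 1)
        folds = list(KFold(4, shuffle=True, random_state=9).split(X))
        sq, n = 0.0, 0
        for tr, te in folds:
            pls = PLSRegression(n_components=3, scale=False).fit(X[tr], y[tr])
            resid = y[te] - pls.predict(X[te])
            sq += float((resid**2).sum())
            n += resid.size
        oracle = np.sqrt(sq / n)
        ours = rmsecv(X, y, PLSConfig(n_components=3, cv_folds=4), folds=folds)
        assert ours == pytest.approx(oracle, abs=1e-12)

    def test_pooling_invariant_to_sample_order(self, rng):
        X = rng.normal(size=(24, 3))
        y = rng.normal(size=(24, 1))
        folds = list(KFold(3, shuffle=True, random_state=1).split(X))
        base = rmsecv(X, y, PLSConfig(n_components=2, cv_folds=3), folds=folds)
        perm = rng.permutation(24)
        permuted_folds = [(np.where(np.isin(perm, tr))[0], np.where(np.isin(perm, te))[0])
                          for tr, te in folds]
        same = rmsecv(X[perm], y[perm], PLSConfig(n_components=2, cv_folds=3),
                      folds=permuted_folds)
        assert same == pytest.approx(base, abs=1e-10)


class TestRunCARS:
    def test_tie_break_earliest_minimum(self):
        assert best_iteration_index(np.array([3.0, 2.0, 2.0, 4.0])) == 2

    def test_sizes_non_increasing_and_subset_invariants(self, rng):
        X = rng.normal(size=(60, 40))
        labels = np.repeat(["A", "B", "C"], 20)
        res = run_cars(X, labels, N=10, config=PLSConfig(n_components=4, cv_folds=3), seed=3)
        sizes = [len(it.ars_feature_ids) for it in res.iterations]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
        for it in res.iterations:
            assert set(it.ars_feature_ids) <= set(it.edf_feature_ids)
        assert set(res.selected_features) <= set(range(40))
        assert res.best_iteration == int(np.argmin(res.rmsecv_curve)) + 1

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(45, 25))
        labels = np.repeat(["A", "B", "C"], 15)
        cfg = PLSConfig(n_components=3, cv_folds=3)
        r1 = run_cars(X, labels, N=6, config=cfg, seed=11)
        r2 = run_cars(X, labels, N=6, config=cfg, seed=11)
        assert np.array_equal(r1.selected_features, r2.selected_features)
        assert np.array_equal(r1.rmsecv_curve, r2.rmsecv_curve)

    def test_full_grid_scale_completes(self, small_tables):
        """A 700-channel table runs to completion with a strict subset."""
        spectra, _ = small_tables
        res = run_cars(
            spectra.intensities, spectra.labels, N=20,
            config=PLSConfig(n_components=8), seed=0,
            feature_names=spectra.grid.column_names(),
        )
        assert 0 < len(res.selected_features) < 700
        assert res.selected_names[0].startswith("wn_")

    def test_report_frame_layout(self, rng, tmp_path):
        X = rng.normal(size=(40, 15))
        labels = np.repeat(["A", "B"], 20)
        res = run_cars(X, labels, N=5, config=PLSConfig(n_components=3, cv_folds=3), seed=1)
        df = res.report_frame()
        assert list(df.columns) == ["iteration", "n_after_edf", "n_after_ars", "rmsecv"]
        res.write_report(tmp_path / "r.csv", tmp_path / "sel.json")
        assert (tmp_path / "r.csv").exists() and (tmp_path / "sel.json").exists()


class TestSelectionExportFormat:
    """The selected-feature export dialect matches published selections."""

    def test_spectral_selection_fixture_on_grid(self):
        import json
        from pathlib import Path

        from seedstack.synthetic import WavenumberGrid

        data = json.loads(
            (Path(__file__).parent / "data" / "reference_spectral_selection.json").read_text()
        )
        wns = data["wavenumbers_cm1"]
        assert len(wns) == 44
        grid_wns = set(WavenumberGrid().wavenumbers())
        assert all(w in grid_wns for w in wns)

    def test_image_selection_fixture_names_valid(self):
        import json
        from pathlib import Path

        from seedstack.synthetic import IMAGE_FEATURE_NAMES

        data = json.loads(
            (Path(__file__).parent / "data" / "reference_image_selection.json").read_text()
        )
        names = data["feature_names"]
        assert len(names) == 15
        assert set(names) <= set(IMAGE_FEATURE_NAMES)
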