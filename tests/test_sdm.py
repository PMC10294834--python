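"""Random-forest SDM: splitting, tuning, metrics, importance, surfaces."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

from habrisk.geodata import Grid, GridSpec, PredictorStack
from habrisk.sdm import (
    RandomForestSDM,
    SDMReport,
    _mtry_candidates,
    _vote_fraction,
    binarize,
    cross_validate,
    gini_importance,
    median_importance,
    predict_surface,
    response_curve,
    roc_auc,
    select_threshold,
    split_train_test,
    tss,
    tune_mtry,
)


def logistic_data(n, beta, seed, p=None):
    rng = np.random.default_rng(seed)
    p = p if p is not None else len(beta)
    X = rng.standard_normal((n, p))
    eta = X[:, : len(beta)] @ np.asarray(beta)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return X, y


class TestSplit:
    def test_divisible_counts_split_exactly(self):
        y = np.r_[np.ones(100, int), np.zeros(100, int)]
        split = split_train_test(y, 0.7, seed=0)
        for cls in (0, 1):
            assert (split[y == cls] == "train").sum() == 70

    def test_rounding_rule_on_odd_counts(self):
        y = np.ones(703, int)
        y[:10] = 0  # token absences so both classes exist
        split = split_train_test(y, 0.7, seed=1)
        n_train_pres = (split[y == 1] == "train").sum()
        assert n_train_pres in (485, 486)  # round(0.7 * 693) = 485.1
        y2 = np.r_[np.ones(703, int), np.zeros(300, int)]
        split2 = split_train_test(y2, 0.7, seed=1)
        assert (split2[y2 == 1] == "train").sum() in (492, 493)

    def test_determinism_and_seed_sensitivity(self):
        y = np.r_[np.ones(50, int), np.zeros(50, int)]
        a = split_train_test(y, seed=5)
        b = split_train_test(y, seed=5)
        c = split_train_test(y, seed=6)
        assert (a == b).all()
        assert (a != c).any()

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(np.array([1, 0, 0, 0]), 0.7, seed=0)


class TestTuneMtry:
    def test_single_variable_forced(self):
        X, y = logistic_data(100, [2.0], seed=1, p=1)
        assert tune_mtry(X, y, seed=0) == 1

    def test_candidate_ladder_shape(self):
        assert _mtry_candidates(7) == [1, 2, 4, 7]
        assert _mtry_candidates(9) == [1, 3, 6, 9]
        assert _mtry_candidates(2) == [1, 2]

    def test_returned_candidate_minimizes_oob_error(self):
        X, y = logistic_data(800, [1.0, 1.0, 1.0, 1.0], seed=2)
        chosen = tune_mtry(X, y, n_trees=50, seed=3)
        errors = {}
        for m in _mtry_candidates(4):
            rf = RandomForestClassifier(
                n_estimators=50, max_features=m, oob_score=True,
                bootstrap=True, random_state=3, n_jobs=1,
            ).fit(X, y)
            errors[m] = 1 - rf.oob_score_
        assert errors[chosen] <= min(errors.values()) + 1e-12

    def test_noise_labels_still_return_valid_candidate(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((200, 5))
        y = rng.integers(0, 2, 200)
        assert tune_mtry(X, y, seed=5) in _mtry_candidates(5)


class TestROCAUC:
    def test_perfect_separation_scores_one(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_score_half(self):
        assert roc_auc([0.5] * 10, [1, 0] * 5) == 0.5

    def test_matches_pairwise_concordance_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            s = rng.random(30)
            y = rng.integers(0, 2, 30)
            if y.min() == y.max():
                continue
            pos = s[y == 1]
            neg = s[y == 0]
            conc = sum(
                1.0 if a > b else 0.5 if a == b else 0.0
                for a, b in itertools.product(pos, neg)
            )
            assert roc_auc(s, y) == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-12)

    def test_invariant_under_increasing_transform(self):
        rng = np.random.default_rng(32)
        s = rng.random(50)
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        assert roc_auc(np.exp(3 * s), y) == pytest.approx(roc_auc(s, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestSelectThreshold:
    def test_separated_blocks_pick_smallest_maximal_midpoint(self):
        thr, sens, spec = select_threshold([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert thr == pytest.approx(0.5)
        assert sens == 1.0 and spec == 1.0

    def test_two_point_case(self):
        thr, sens, spec = select_threshold([0.7, 0.3], [1, 0])
        assert thr == pytest.approx(0.5)
        assert sens == spec == 1.0

    def test_anti_informative_scores_max_at_extremes(self):
        thr, sens, spec = select_threshold([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        assert sens + spec == pytest.approx(1.0)

    def test_optimality_against_exhaustive_enumeration(self):
        rng = np.random.default_rng(33)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            s = np.round(rng.random(n), 2)  # duplicates exercise tie handling
            y = rng.integers(0, 2, n)
            y[0], y[1] = 0, 1
            thr, sens, spec = select_threshold(s, y)
            best = max(
                ((s >= t)[y == 1].mean() + (~(s >= t))[y == 0].mean())
                for t in np.r_[0.0, 1.0, np.unique(s), np.unique(s) - 1e-9]
            )
            assert sens + spec == pytest.approx(best, abs=1e-12)


class TestTSS:
    @pytest.mark.parametrize(
        "sens,spec,expected", [(1.0, 1.0, 1.0), (0.5, 0.5, 0.0), (0.2, 0.3, -0.5)]
    )
    def test_identity(self, sens, spec, expected):
        assert tss(sens, spec) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tss(1.2, 0.5)

    def test_report_recomputes_tss_from_sens_spec(self):
        rep = SDMReport(
            species="t", n_trees=10, mtry=1, seed=0, auc_train=0.9, auc_test=0.9,
            threshold=0.5, sens_train=0.8, spec_train=0.7,
            sens_test=0.6, spec_test=0.9,
        )
        assert rep.tss_train == rep.sens_train + rep.spec_train - 1
        assert rep.tss_test == rep.sens_test + rep.spec_test - 1


class TestForest:
    def test_separable_data_gives_high_train_auc(self):
        rng = np.random.default_rng(41)
        X = np.r_[rng.normal(-3, 0.3, (150, 2)), rng.normal(3, 0.3, (150, 2))]
        y = np.r_[np.zeros(150, int), np.ones(150, int)]
        m = RandomForestSDM(n_trees=100, cv_folds=0, random_state=0).fit(X, y)
        assert m.auc_train_ >= 0.99
        assert m.auc_test_ >= 0.99

    def test_noise_labels_hover_at_chance(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            X = rng.standard_normal((500, 3))
            y = rng.integers(0, 2, 500)
            m = RandomForestSDM(n_trees=60, cv_folds=0, random_state=seed).fit(X, y)
            aucs.append(m.auc_test_)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_duplicating_rows_barely_changes_predictions(self):
        X, y = logistic_data(400, [2.0, -1.0], seed=42)
        probe = np.random.default_rng(43).standard_normal((200, 2))
        rf1 = RandomForestClassifier(n_estimators=300, max_features=1,
                                     random_state=0, n_jobs=1).fit(X, y)
        rf2 = RandomForestClassifier(n_estimators=300, max_features=1,
                                     random_state=0, n_jobs=1).fit(
            np.repeat(X, 2, axis=0), np.repeat(y, 2)
        )
        diff = np.abs(_vote_fraction(rf1, probe) - _vote_fraction(rf2, probe))
        assert diff.mean() < 0.1

    def test_single_class_training_rejected(self):
        X = np.random.default_rng(0).standard_normal((20, 2))
        with pytest.raises(ValueError):
            RandomForestSDM(n_trees=10).fit(X, np.ones(20, int))

    def test_report_fields_consistent(self):
        X, y = logistic_data(300, [2.0, 0.0], seed=44)
        m = RandomForestSDM(n_trees=80, cv_folds=3, species="G_test",
                            random_state=7).fit(X, y)
        r = m.report_
        assert r.tss_train == pytest.approx(r.sens_train + r.spec_train - 1)
        assert r.tss_test == pytest.approx(r.sens_test + r.spec_test - 1)
        assert 0 <= r.threshold <= 1
        assert len(r.cv_aucs) == 3
        assert r.cv_auc_mean == pytest.approx(np.mean(r.cv_aucs))
        assert set(r.importance) == {"x0", "x1"}

    def test_sklearn_estimator_api(self):
        from sklearn.base import clone

        X, y = logistic_data(200, [2.0], seed=45, p=2)
        m = RandomForestSDM(n_trees=50, cv_folds=0, random_state=1)
        assert clone(m).get_params() == m.get_params()
        m.fit(pd.DataFrame(X, columns=["a", "b"]), y)
        proba = m.predict_proba(pd.DataFrame(X, columns=["a", "b"]))
        assert proba.shape == (200, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert set(np.unique(m.predict(pd.DataFrame(X, columns=["a", "b"])))) <= {0, 1}


class TestCrossValidate:
    def test_separable_data_high_cv_auc(self):
        rng = np.random.default_rng(51)
        X = np.r_[rng.normal(-2, 0.5, (100, 2)), rng.normal(2, 0.5, (100, 2))]
        y = np.r_[np.zeros(100, int), np.ones(100, int)]
        aucs, mean, sd = cross_validate(X, y, k=5, seed=0, n_trees=50, tune=False)
        assert mean >= 0.95
        assert len(aucs) == 5

    def test_fold_count_exceeding_class_size_rejected(self):
        X = np.random.default_rng(0).standard_normal((12, 2))
        y = np.r_[np.ones(4, int), np.zeros(8, int)]
        with pytest.raises(ValueError):
            cross_validate(X, y, k=5, seed=0)

    def test_noise_labels_cv_auc_near_chance(self):
        means = []
        for seed in range(10):
            rng = np.random.default_rng(2000 + seed)
            X = rng.standard_normal((300, 3))
            y = rng.integers(0, 2, 300)
            _, mean, _ = cross_validate(X, y, k=5, seed=seed, n_trees=40, tune=False)
            means.append(mean)
        assert 0.4 <= np.mean(means) <= 0.6


class TestGiniImportance:
    def test_stump_matches_hand_computed_gini_decrease(self):
        # perfectly separable single split: decrease = n * gini(root) = 8 * 0.5
        X = np.array([[-2.0], [-1.5], [-1.0], [-0.5], [0.5], [1.0], [1.5], [2.0]])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        rf = RandomForestClassifier(n_estimators=1, bootstrap=False,
                                    random_state=0, n_jobs=1).fit(X, y)
        mdg = gini_importance(rf, ["x"])
        assert mdg["x"] == pytest.approx(8 * 0.5)

    def test_signal_variable_outranks_noise(self):
        wins = 0
        for seed in range(100):
            X, y = logistic_data(200, [2.5, 0.0], seed=3000 + seed)
            rf = RandomForestClassifier(n_estimators=50, max_features=1,
                                        random_state=seed, n_jobs=1).fit(X, y)
            mdg = gini_importance(rf, ["signal", "noise"])
            wins += mdg["signal"] > mdg["noise"]
        assert wins >= 95

    def test_all_noise_importances_stay_comparable(self):
        ok = 0
        for seed in range(100):
            rng = np.random.default_rng(4000 + seed)
            X = rng.standard_normal((150, 5))
            y = rng.integers(0, 2, 150)
            rf = RandomForestClassifier(n_estimators=50, random_state=seed,
                                        n_jobs=1).fit(X, y)
            mdg = gini_importance(rf, list("abcde"))
            ok += (mdg <= 3 * mdg.median()).all()
        assert ok >= 90

    def test_single_variable_holds_all_importance(self):
        X, y = logistic_data(150, [2.0], seed=6, p=1)
        rf = RandomForestClassifier(n_estimators=20, random_state=0,
                                    n_jobs=1).fit(X, y)
        mdg = gini_importance(rf, ["only"])
        assert mdg["only"] > 0
        assert mdg.sum() == mdg["only"]


class TestMedianImportance:
    def test_published_triplets_reproduce_their_medians(self):
        tables = {
            "sp1": pd.Series({"tpi": 76.25, "slope": 53.17}),
            "sp2": pd.Series({"tpi": 184.75, "slope": 115.58}),
            "sp3": pd.Series({"tpi": 10.90, "slope": 7.30}),
        }
        out = median_importance(tables)
        assert out.loc["tpi", "median"] == pytest.approx(76.25)
        assert out.loc["slope", "median"] == pytest.approx(53.17)
        assert out.loc["tpi", "rank"] == 1

    def test_single_table_median_is_itself(self):
        out = median_importance({"only": pd.Series({"a": 3.0, "b": 1.0})})
        assert out.loc["a", "median"] == 3.0

    def test_mismatched_variable_sets_rejected(self):
        with pytest.raises(ValueError):
            median_importance({
                "s1": pd.Series({"a": 1.0}),
                "s2": pd.Series({"b": 1.0}),
            })


class TestResponseCurve:
    def test_monotone_truth_gives_monotone_curve(self):
        cols = ["x"] + [f"n{i}" for i in range(6)]
        X, y = logistic_data(3000, [3.0], seed=61, p=7)
        df = pd.DataFrame(X, columns=cols)
        m = RandomForestSDM(n_trees=200, mtry=2, cv_folds=0, random_state=0).fit(df, y)
        rc = response_curve(m, df, "x", n_grid=20)
        assert rc.probability[-1] > rc.probability[0] + 0.5
        assert (np.diff(rc.probability) >= -0.01).all()

    def test_null_variable_curve_is_flat_on_average(self):
        # deep forests give the null curve a small local wiggle (each grid
        # value is effectively a nearest-training-neighbor average), so the
        # flatness band is assessed over replicate simulated forests
        cols = ["x"] + [f"n{i}" for i in range(6)]
        devs = []
        for seed in range(1, 7):
            X, y = logistic_data(5000, [3.0], seed=seed, p=7)
            df = pd.DataFrame(X, columns=cols)
            m = RandomForestSDM(n_trees=250, mtry=2, cv_folds=0,
                                random_state=0).fit(df, y)
            rc = response_curve(m, df, "n0")
            devs.append(np.abs(rc.probability - rc.probability.mean()).max())
        assert np.mean(devs) <= 0.05
        assert max(devs) <= 0.09

    def test_constant_variable_gives_single_point(self):
        X, y = logistic_data(100, [2.0], seed=63, p=2)
        X[:, 1] = 5.0
        m = RandomForestSDM(n_trees=30, cv_folds=0, random_state=0).fit(X, y)
        rc = response_curve(m, X, "x1")
        assert len(rc.grid) == 1

    def test_unknown_variable_rejected(self):
        X, y = logistic_data(100, [2.0], seed=64, p=2)
        m = RandomForestSDM(n_trees=20, cv_folds=0, random_state=0).fit(X, y)
        with pytest.raises(KeyError):
            response_curve(m, X, "absent")


class TestPredictSurface:
    @pytest.fixture
    def fitted_with_stack(self):
        spec = GridSpec(12, 12, origin_y=120.0, cell_size=10.0)
        rng = np.random.default_rng(71)
        layers = {
            "a": Grid(spec, rng.standard_normal(spec.shape)),
            "b": Grid(spec, rng.standard_normal(spec.shape)),
        }
        stack = PredictorStack(["a", "b"], layers)
        X, y = logistic_data(300, [2.5, 0.0], seed=72)
        m = RandomForestSDM(n_trees=60, cv_folds=0, random_state=0).fit(
            pd.DataFrame(X, columns=["a", "b"]), y
        )
        return m, stack

    def test_surface_binarize_degenerate_thresholds(self, fitted_with_stack):
        m, stack = fitted_with_stack
        surf = predict_surface(m, stack)
        assert (binarize(surf, 0.0).values == 1).all()
        assert (binarize(surf, 1.0 + 1e-9).values == 0).all()

    def test_binary_area_matches_counting_oracle(self, fitted_with_stack):
        m, stack = fitted_with_stack
        surf = predict_surface(m, stack)
        t = 0.4
        binary = binarize(surf, t)
        assert binary.values.sum() * surf.spec.cell_area() == pytest.approx(
            (surf.values >= t).sum() * surf.spec.cell_area()
        )

    def test_missing_variable_error_names_it(self, fitted_with_stack):
        m, stack = fitted_with_stack
        with pytest.raises(KeyError, match="b"):
            predict_surface(m, stack.subset(["a"]))

    def test_nodata_propagates_through_surface(self, fitted_with_stack):
        m, stack = fitted_with_stack
        vals = stack["a"].values.copy()
        vals[0, 0] = stack.spec.nodata
        stack.layers["a"] = Grid(stack.spec, vals)
        surf = predict_surface(m, stack)
        assert surf.mask_nodata()[0, 0]
        assert binarize(surf, 0.5).mask_nodata()[0, 0]
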