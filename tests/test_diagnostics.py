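"""VIP, selectivity ratio, jackknife and permutation-test behavior."""

import numpy as np
import pytest

import cellfp
from cellfp.plsda import ClassEncoding, PLSDAModel
from conftest import make_blobs


def manual_model(W, ssy):
    """Minimal PLSDAModel carrying only what VIP reads."""
    W = np.asarray(W, float)
    p, A = W.shape
    enc = ClassEncoding(["a", "b"], np.eye(2), np.full(2, 0.5))
    z = np.zeros
    return PLSDAModel(A, W, z((p, A)), z((2, A)), z((2, A)), z((p, 2)),
                      np.asarray(ssy, float), z(p), enc)


class TestVIP:
    def test_symmetric_weights_give_unit_vips(self):
        m = manual_model(np.array([[1 / np.sqrt(2)], [1 / np.sqrt(2)]]), [3.0])
        np.testing.assert_allclose(cellfp.vip(m), [1.0, 1.0], atol=1e-12)

    def test_concentrated_weight_closed_form(self):
        m = manual_model(np.array([[1.0], [0.0]]), [5.0])
        np.testing.assert_allclose(cellfp.vip(m), [np.sqrt(2.0), 0.0], atol=1e-12)

    def test_matches_brute_force_on_random_fit(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(15, 8))
        y = np.array(["a", "b", "c"] * 5)
        m = cellfp.fit_plsda(X, y, 3)
        v = cellfp.vip(m)
        assert np.mean(v ** 2) == pytest.approx(1.0, abs=1e-8)
        # independent elementwise evaluation of the formula
        p = 8
        brute = np.empty(p)
        for j in range(p):
            num = sum(m.ssy[a] * (m.weights[j, a] / np.linalg.norm(m.weights[:, a])) ** 2
                      for a in range(3))
            brute[j] = np.sqrt(p * num / m.ssy.sum())
        np.testing.assert_allclose(v, brute, atol=1e-8)

    def test_vip_squares_sum_to_feature_count(self, four_class_split):
        m = cellfp.PLSDAPipeline(3).fit(four_class_split["X_train"],
                                        four_class_split["y_train"]).model
        assert np.sum(cellfp.vip(m) ** 2) == pytest.approx(217, abs=1e-8)


class TestSelectivityRatio:
    def fit_random(self, seed=1, n=12, p=6):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        y = np.array(["a", "b"] * (n // 2))
        return X, y, cellfp.fit_plsda(X, y, 2)

    def test_matches_per_column_regression_oracle(self):
        X, y, m = self.fit_random()
        sr = cellfp.selectivity_ratio(m, X, 0)
        Xc = X - X.mean(0)
        b = m.coef[:, 0]
        t = Xc @ (b / np.linalg.norm(b))
        for j in range(X.shape[1]):
            beta = (t @ Xc[:, j]) / (t @ t)   # least squares of column on t
            expl = beta * t
            res = Xc[:, j] - expl
            expected = (expl @ expl) / (res @ res)
            assert sr[j] == pytest.approx(expected, rel=1e-8)

    def test_column_equal_to_target_projection_hits_inf_sentinel(self):
        X, y, m = self.fit_random(seed=2)
        # force the target direction onto the first coordinate axis: the
        # target projection then reproduces column 0 perfectly
        m.coef[:, 0] = np.eye(X.shape[1])[0]
        sr = cellfp.selectivity_ratio(m, X, 0)
        assert np.isinf(sr[0])
        table = cellfp.sr_table(m, X)
        assert np.all(np.isfinite(table[m.encoding.classes[0]]))  # capped

    def test_orthogonal_column_scores_zero(self):
        rng = np.random.default_rng(3)
        n = 40
        t = rng.normal(size=n)
        t -= t.mean()          # keep columns centered so centering is a no-op
        orth = rng.normal(size=n)
        orth -= orth.mean()
        orth -= (orth @ t) / (t @ t) * t
        X = np.column_stack([t, orth, rng.normal(size=n)])
        y = np.array(["a", "b"] * (n // 2))
        m = cellfp.fit_plsda(X, y, 1)
        # replace coefficients so the target projection is exactly t
        m.coef[:, 0] = np.array([1.0, 0.0, 0.0])
        Xc = X - X.mean(0)
        sr = cellfp.selectivity_ratio(m, X, 0)
        assert sr[1] == pytest.approx(0.0, abs=1e-10)

    def test_invariant_to_coefficient_rescaling(self):
        X, y, m = self.fit_random(seed=4)
        sr1 = cellfp.selectivity_ratio(m, X, 1)
        m.coef[:, 1] *= 37.5
        sr2 = cellfp.selectivity_ratio(m, X, 1)
        np.testing.assert_allclose(sr1, sr2, rtol=1e-10)


class TestJackknife:
    def test_duplicated_data_gives_zero_se(self):
        rng = np.random.default_rng(5)
        base_X, base_y = make_blobs(rng, {"a": (0, 0), "b": (3, 0)}, 5)
        X = np.tile(base_X, (5, 1))
        y = np.tile(base_y, 5)
        res = cellfp.jackknife_ci(X, y, n_components=1, n_folds=5, seed=0)
        assert np.max(res.se) < 0.05
        big = np.abs(res.estimate) > 0.05
        assert np.all(res.stable[big])

    def test_pure_noise_rarely_flags_stability(self):
        rng = np.random.default_rng(6)
        fracs = []
        for rep in range(10):
            X = rng.normal(size=(100, 50))
            y = np.array(["a", "b"] * 50)
            res = cellfp.jackknife_ci(X, y, n_components=2, n_folds=5, seed=rep)
            fracs.append(res.stable.mean())
        assert np.mean(fracs) <= 0.10

    def test_informative_bucket_is_stable(self):
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            y = np.array(["a", "b"] * 30)
            signal = np.where(y == "a", 2.0, -2.0) + 0.3 * rng.normal(size=60)
            X = np.column_stack([signal, rng.normal(size=(60, 9))])
            res = cellfp.jackknife_ci(X, y, n_components=1, n_folds=5, seed=rep)
            hits += bool(res.stable[0].all())
        assert hits >= 9

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="fold"):
            cellfp.jackknife_ci(np.random.default_rng(0).normal(size=(8, 4)),
                                ["a"] * 4 + ["b"] * 4, 1, n_folds=5)


class TestPermutationTest:
    def test_add_one_formula_and_strong_signal(self):
        rng = np.random.default_rng(7)
        X, y = make_blobs(rng, {"a": (0, 0, 0), "b": (5, 0, 0)}, 15)
        res = cellfp.permutation_test(lambda: cellfp.PLSDAPipeline(1), X, y,
                                      n_perm=49, cv_folds=5, seed=0)
        assert res.p_value == pytest.approx(
            (1 + np.sum(res.null_scores >= res.observed)) / 50)
        assert res.p_value == pytest.approx(1 / 50)  # separable: beats all nulls

    def test_observed_below_nulls_gives_p_one(self):
        class WorstCase(cellfp.PLSDAPipeline):
            """Predicts the wrong class whenever labels are unshuffled."""
            def fit(self, X, y):
                self._classes = sorted(set(y))
                self._lookup = {tuple(row): lab for row, lab in zip(map(tuple, X), y)}
                return self
            def predict(self, X):
                out = []
                for row in map(tuple, X):
                    lab = self._lookup.get(row)
                    others = [c for c in self._classes if c != lab]
                    out.append(others[0] if lab is not None else self._classes[0])
                return out
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 3))
        y = np.array(["a", "b", "c"] * 10)
        res = cellfp.permutation_test(WorstCase, X, y, n_perm=19, cv_folds=5, seed=1)
        assert res.p_value == 1.0

    def test_minimum_permutation_count_enforced(self):
        with pytest.raises(ValueError):
            cellfp.permutation_test(lambda: cellfp.PLSDAPipeline(1),
                                    np.zeros((10, 2)), ["a", "b"] * 5, n_perm=5)


class TestVIPRemoval:
    def test_zero_removals_reproduce_baseline(self):
        rng = np.random.default_rng(9)
        X, y = make_blobs(rng, {"a": (0, 0, 0, 0), "b": (2, 0, 0, 0)}, 15)
        curve = cellfp.vip_removal_sensitivity(X, y, n_components=1,
                                               max_removed_fraction=0.5, step=1, seed=3)
        baseline = cellfp.cv_f1(lambda: cellfp.PLSDAPipeline(1), X, y, 5, seed=3)
        assert curve.iloc[0]["cv_f1"] == pytest.approx(baseline)
        assert len(curve) == int(0.5 * 4 / 1) + 1

    def test_redundant_signal_tolerates_removal(self, four_class_split):
        """Class information spread over correlated buckets: F1 should hold
        until a sizeable share of top-VIP buckets is gone."""
        X, y = four_class_split["X_train"], np.asarray(four_class_split["y_train"])
        curve = cellfp.vip_removal_sensitivity(X, y, n_components=3,
                                               max_removed_fraction=0.10,
                                               step=11, seed=0)
        baseline = curve.iloc[0]["cv_f1"]
        assert np.all(curve["cv_f1"] >= baseline - 0.05)
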