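"""Splitting, AUC, cross-validation, gating/weighting and the ensemble."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ensdm import (
    EnsembleSDM,
    OccurrenceSet,
    compute_auc,
    cross_validate,
    gate_and_weight,
    split_data,
    variable_importance,
)
from ensdm.errors import DataError, GateError
from ensdm.geodata import BACKGROUND, PRESENCE

from conftest import ConstantSDM


def brute_force_auc(p, b):
    """All-pairs oracle: wins + half-ties over all presence/background pairs."""
    wins = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in p for y in b)
    return wins / (len(p) * len(b))


def _occ(n_pres, n_bg):
    lon = np.linspace(0, 1, n_pres + n_bg)
    return OccurrenceSet.from_arrays(
        lon, lon, [PRESENCE] * n_pres + [BACKGROUND] * n_bg
    )


class TestSplitData:
    def test_study_size_split_counts(self):
        train, test = split_data(_occ(84, 500), train_fraction=0.7, seed=0)
        assert abs(train.n_presence - 58.8) <= 1
        assert abs(test.n_presence - 25.2) <= 1
        assert abs(train.n_background - 350) <= 1
        assert abs(test.n_background - 150) <= 1

    def test_same_seed_reproduces(self):
        t1, s1 = split_data(_occ(40, 100), seed=5)
        t2, s2 = split_data(_occ(40, 100), seed=5)
        pd.testing.assert_frame_equal(t1.points, t2.points)
        pd.testing.assert_frame_equal(s1.points, s2.points)

    def test_disjoint_and_exhaustive(self):
        occ = _occ(30, 70)
        train, test = split_data(occ, seed=1)
        lons = sorted(train.points["lon"]) + sorted(test.points["lon"])
        assert sorted(lons) == sorted(occ.points["lon"])
        assert not set(train.points["lon"]) & set(test.points["lon"])

    def test_tiny_class_rejected(self):
        with pytest.raises(DataError):
            split_data(_occ(1, 100))


class TestComputeAuc:
    def test_perfect_separation(self):
        assert compute_auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_identical_lists_give_half(self):
        assert compute_auc([0.3, 0.7], [0.3, 0.7]) == 0.5

    def test_hand_computed_ties(self):
        # pairs: (.9>.7)+(.9>.8)+(.8>.7)+(.8==.8 -> 1/2) over 4 pairs
        assert compute_auc([0.9, 0.8], [0.7, 0.8]) == pytest.approx(0.875)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n_p = int(rng.integers(1, 101))
            n_b = int(rng.integers(1, 101))
            # coarse grid of scores to force plenty of ties
            p = rng.integers(0, 10, n_p) / 10
            b = rng.integers(0, 10, n_b) / 10
            assert compute_auc(p, b) == pytest.approx(
                brute_force_auc(list(p), list(b)), abs=1e-12
            )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        p, b = rng.random(50), rng.random(80)
        y = np.r_[np.ones(50), np.zeros(80)]
        assert compute_auc(p, b) == pytest.approx(
            roc_auc_score(y, np.r_[p, b]), abs=1e-12
        )


class TestCrossValidate:
    def _data(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.standard_normal((n, 2)), columns=["a", "b"])
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
        return X, y

    def test_constant_scorer_gives_half_every_fold(self):
        X, y = self._data()
        res = cross_validate(ConstantSDM(0.4), X, y, k=5, seed=0)
        assert res.fold_aucs == [0.5] * 5

    def test_k5_gives_five_folds(self):
        X, y = self._data()
        res = cross_validate("glm", X, y, k=5, seed=0)
        assert len(res.fold_aucs) == 5
        assert 0 <= res.mean_auc <= 1

    def test_cv_consistent_with_holdout_for_true_model(self, fitted_world):
        """A member's CV AUC should track its holdout AUC on one world."""
        fw = fitted_world
        from ensdm.ensemble import auc_from_labels

        for aid, member in fw.ensemble.members_.items():
            hold = auc_from_labels(
                fw.y[fw.test_idx], member.score_samples(fw.X.iloc[fw.test_idx])
            )
            cv = fw.ensemble.cv_results_[aid].mean_auc
            assert abs(cv - hold) < 0.07


class TestGateAndWeight:
    def test_gate_drops_below_077(self):
        w = gate_and_weight({"a": 0.9, "b": 0.6})
        assert w == {"a": 1.0}

    def test_two_survivors_auc_proportional(self):
        w = gate_and_weight({"a": 0.9, "b": 0.8})
        assert w["a"] == pytest.approx(0.9 / 1.7)
        assert w["b"] == pytest.approx(0.8 / 1.7)

    def test_contribution_floor_drops_and_renormalizes(self):
        # c's share 0.70/2.40 ~ 0.29 ... d at 0.04 share after gate
        aucs = {"a": 0.95, "b": 0.93, "c": 0.90, "d": 0.80}
        # craft a case: weight share of d = .8/3.58 = 0.223 > 5%; use many members
        aucs = {f"m{i}": 0.9 for i in range(19)} | {"small": 0.77}
        w = gate_and_weight(aucs, min_contribution=0.05)
        # 20 members -> share 0.045 each for the 0.9s is < 5%? total=17.87;
        # small=0.77/17.87=0.0431 < 5% -> dropped; then 19 x 0.9 ties retained
        assert "small" not in w
        assert len(w) == 19
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)

    def test_all_tied_below_floor_are_retained(self):
        aucs = {f"m{i}": 0.9 for i in range(25)}
        w = gate_and_weight(aucs, min_contribution=0.05)
        assert len(w) == 25  # dropping any one would be arbitrary
        assert all(v == pytest.approx(0.04) for v in w.values())

    def test_no_survivor_raises_gate_error(self):
        with pytest.raises(GateError):
            gate_and_weight({"a": 0.5, "b": 0.6})

    def test_weights_always_normalized(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            aucs = {f"m{i}": float(a) for i, a in enumerate(rng.uniform(0.5, 1, 6))}
            try:
                w = gate_and_weight(aucs)
            except GateError:
                continue
            assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)
            assert all(v >= 0.05 - 1e-12 for v in w.values()) or len(set(w.values())) == 1


class TestEnsemblePrediction:
    def _toy_ensemble(self, weights, values):
        ens = EnsembleSDM()
        X = np.zeros((6, 2))
        ens.members_ = {
            f"m{i}": ConstantSDM(v).fit(X) for i, v in enumerate(values)
        }
        ens.weights_ = {f"m{i}": w for i, w in enumerate(weights)}
        ens.variable_names_ = None
        return ens

    def test_single_member_is_identity(self):
        ens = self._toy_ensemble([1.0], [0.73])
        np.testing.assert_allclose(ens.score_samples(np.zeros((4, 2))), 0.73)

    def test_equal_weights_average(self):
        ens = self._toy_ensemble([0.5, 0.5], [0.2, 0.8])
        np.testing.assert_allclose(ens.score_samples(np.zeros((4, 2))), 0.5)

    def test_weighted_average_arithmetic(self):
        ens = self._toy_ensemble([0.9, 0.8], [0.2, 0.8])
        expected = (0.9 * 0.2 + 0.8 * 0.8) / 1.7
        np.testing.assert_allclose(ens.score_samples(np.zeros((4, 2))), expected)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        weights=st.lists(st.floats(0.5, 1.0), min_size=1, max_size=5),
        values=st.lists(st.floats(0.0, 1.0), min_size=5, max_size=5),
    )
    def test_convexity(self, weights, values):
        values = values[: len(weights)]
        weights = weights[: len(values)]
        ens = self._toy_ensemble(weights, values)
        s = ens.score_samples(np.zeros((3, 2)))
        assert min(values) - 1e-12 <= s[0] <= max(values) + 1e-12

    def test_fit_reproducible(self, fitted_world):
        fw = fitted_world
        ens2 = EnsembleSDM(random_state=1).fit(
            fw.X.iloc[fw.train_idx], fw.y[fw.train_idx]
        )
        assert ens2.weights_ == fw.ensemble.weights_
        for aid, r in ens2.cv_results_.items():
            assert r.fold_aucs == fw.ensemble.cv_results_[aid].fold_aucs


class TestVariableImportance:
    def test_percentages_sum_to_100(self, fitted_world):
        fw = fitted_world
        imp = variable_importance(fw.ensemble, fw.X, fw.y, n_permutations=3, seed=0)
        assert imp.sum() == pytest.approx(100.0, abs=1e-6)
        assert (imp >= 0).all()

    def test_unused_variable_has_zero_importance(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(
            {"sig": rng.standard_normal(400), "noise": rng.standard_normal(400)}
        )
        y = (rng.random(400) < 1 / (1 + np.exp(-3 * X["sig"]))).astype(int)
        ens = EnsembleSDM(algorithms=["glm"], auc_gate=0.0, random_state=0)
        ens.fit(X, y)
        # zero out the fitted coefficient on the noise column -> truly unused
        ens.members_["glm"].coef_[1] = 0.0
        imp = variable_importance(ens, X, y, n_permutations=5, seed=1)
        assert imp["noise"] == 0.0
        assert imp["sig"] == pytest.approx(100.0)
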