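"""Random survival forest and Harrell's concordance."""

import numpy as np
import pandas as pd
import pytest

from resistsurv.survival_forest import (
    ForestSpec,
    compare_predictions,
    fit_forest,
    harrells_c,
    permutation_importance,
)


def brute_force_concordance(score, t, d):
    """All-pairs enumeration of Harrell's C (independent of the implementation)."""
    conc = comp = 0.0
    n = len(t)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # i must be the earlier, observed event
            if d[i] != 1:
                continue
            if not (t[i] < t[j] or (t[i] == t[j] and d[j] == 0)):
                continue
            comp += 1
            if score[i] > score[j]:
                conc += 1
            elif score[i] == score[j]:
                conc += 0.5
    if comp == 0:
        raise ValueError("no comparable pairs")
    return conc / comp


class TestHarrellsC:
    def test_perfect_ordering(self):
        s = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert harrells_c(s, t, np.ones(5, int)) == 1.0

    def test_reversed_ordering(self):
        s = np.array([1.0, 2.0, 3.0])
        t = np.array([1.0, 2.0, 3.0])
        assert harrells_c(s, t, np.ones(3, int)) == 0.0

    def test_matches_all_pairs_oracle_under_censoring(self):
        r = np.random.default_rng(3)
        for _ in range(25):
            n = r.integers(6, 21)
            t = r.integers(1, 10, n).astype(float)
            d = r.integers(0, 2, n)
            s = r.normal(size=n)
            if d.sum() == 0:
                continue
            try:
                expected = brute_force_concordance(s, t, d)
            except ValueError:
                with pytest.raises(ValueError):
                    harrells_c(s, t, d)
                continue
            assert harrells_c(s, t, d) == pytest.approx(expected, abs=1e-12)

    def test_antisymmetry_for_tie_free_scores(self):
        r = np.random.default_rng(7)
        t = r.exponential(5, 30)
        d = r.integers(0, 2, 30)
        d[0] = 1
        s = r.normal(size=30)
        assert harrells_c(s, t, d) + harrells_c(-s, t, d) == pytest.approx(1.0)

    def test_agrees_with_lifelines(self):
        from lifelines.utils import concordance_index

        r = np.random.default_rng(11)
        t = r.exponential(5, 200) + r.random(200) * 1e-6  # tie-free
        d = r.integers(0, 2, 200)
        s = r.normal(size=200)
        # lifelines orders by predicted survival time (= -risk)
        assert harrells_c(s, t, d) == pytest.approx(concordance_index(t, -s, d), abs=1e-12)

    def test_no_comparable_pairs_errors(self):
        with pytest.raises(ValueError):
            harrells_c(np.array([1.0, 2.0]), np.array([5.0, 5.0]), np.array([1, 1]))

    def test_agrees_with_scikit_survival(self):
        from sksurv.metrics import concordance_index_censored

        r = np.random.default_rng(13)
        t = r.exponential(5, 150) + r.random(150) * 1e-6
        d = r.integers(0, 2, 150).astype(bool)
        d[:2] = True
        s = r.normal(size=150)
        expected = concordance_index_censored(d, t, s)[0]
        assert harrells_c(s, t, d.astype(int)) == pytest.approx(expected, abs=1e-12)


def _noise_frame(n, seed):
    r = np.random.default_rng(seed)
    return pd.DataFrame(
        {"a": r.normal(size=n), "b": r.normal(size=n),
         "duration": r.exponential(10, n), "event": 1}
    )


def _separable_frame(n, seed):
    r = np.random.default_rng(seed)
    x = r.normal(size=n)
    return pd.DataFrame({"x": x, "duration": 100 - 10 * x, "event": 1})


class TestForestBehavior:
    def test_pure_noise_oob_error_near_half(self):
        errs = [
            fit_forest(_noise_frame(300, 50 + s), ForestSpec(n_trees=80, seed=s),
                       predictors=["a", "b"], categorical=()).oob_error
            for s in range(3)
        ]
        assert abs(np.mean(errs) - 0.5) < 0.05

    def test_separable_instance_oob_error_small(self):
        fit = fit_forest(
            _separable_frame(300, 1),
            ForestSpec(n_trees=80, seed=2, min_node_size=5, min_leaf_size=2),
            predictors=["x"], categorical=(),
        )
        assert fit.oob_error < 0.1

    def test_oob_error_invariant_to_record_order(self, design):
        spec = ForestSpec(n_trees=25, seed=3)
        f1 = fit_forest(design, spec)
        perm = np.random.default_rng(0).permutation(len(design))
        f2 = fit_forest(design.iloc[perm].reset_index(drop=True), spec)
        assert f1.oob_error == f2.oob_error

    def test_more_trees_do_not_hurt_on_separable_instance(self):
        means = []
        for n_trees in (10, 50, 150):
            errs = [
                fit_forest(_separable_frame(150, 20 + s),
                           ForestSpec(n_trees=n_trees, seed=s, min_node_size=5, min_leaf_size=2),
                           predictors=["x"], categorical=()).oob_error
                for s in range(5)
            ]
            means.append(np.mean(errs))
        assert means[0] >= means[1] - 0.01
        assert means[1] >= means[2] - 0.01

    def test_predictions_track_reference_forest_implementation(self, design):
        # cross-check, not equivalence: an independently grown survival
        # forest should rank records similarly on proportional-hazards data
        from scipy.stats import spearmanr
        from sksurv.ensemble import RandomSurvivalForest
        from sksurv.util import Surv

        sub = design.sample(400, random_state=1).reset_index(drop=True)
        cols = ["x_diet", "x_diet2", "x_sim", "x_sim2", "x_doc"]
        ours = fit_forest(sub, ForestSpec(n_trees=100, seed=0), predictors=cols, categorical=())
        ref = RandomSurvivalForest(n_estimators=100, min_samples_leaf=15, random_state=0)
        y = Surv.from_arrays(sub["event"].astype(bool), sub["duration"])
        ref.fit(sub[cols], y)
        rho = spearmanr(ours.risk, ref.predict(sub[cols])).statistic
        assert rho > 0.8

    def test_all_censored_bootstrap_redrawn(self):
        r = np.random.default_rng(1)
        n = 40
        df = pd.DataFrame({"x": r.normal(size=n), "duration": r.exponential(10, n),
                           "event": np.r_[np.ones(2, int), np.zeros(n - 2, int)]})
        fit = fit_forest(df, ForestSpec(n_trees=30, seed=4), predictors=["x"], categorical=())
        assert fit.oob_error >= 0  # completed despite sparse events


class TestImportance:
    def test_signal_variable_ranks_first_and_covers_all_predictors(self):
        r = np.random.default_rng(5)
        n = 300
        x = r.normal(size=n)
        df = pd.DataFrame(
            {"x": x, "junk1": r.normal(size=n), "junk2": r.normal(size=n),
             "duration": 100 - 10 * x + r.normal(0, 1, n), "event": 1}
        )
        fit = fit_forest(df, ForestSpec(n_trees=60, seed=6, min_node_size=5, min_leaf_size=2),
                         predictors=["x", "junk1", "junk2"], categorical=())
        imp = permutation_importance(fit, seed=1, n_repeats=3)
        assert set(imp["variable"]) == {"x", "junk1", "junk2"}
        assert imp.iloc[0]["variable"] == "x"

    def test_never_split_variable_has_zero_importance(self):
        r = np.random.default_rng(8)
        n = 200
        x = r.normal(size=n)
        df = pd.DataFrame(
            {"x": x, "const": np.zeros(n), "duration": 100 - 10 * x, "event": 1}
        )
        fit = fit_forest(df, ForestSpec(n_trees=40, seed=9, min_node_size=5, min_leaf_size=2),
                         predictors=["x", "const"], categorical=())
        imp = permutation_importance(fit, seed=2, n_repeats=2).set_index("variable")
        assert imp.loc["const", "importance"] == pytest.approx(0.0, abs=1e-12)


class TestComparePredictions:
    def test_identical_vectors_correlate_perfectly(self):
        v = np.arange(10.0)
        r, p = compare_predictions(v, v)
        assert r == pytest.approx(1.0)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            compare_predictions(np.ones(5), np.arange(5.0))

    def test_independent_vectors_mostly_uncorrelated(self):
        ok = 0
        for s in range(20):
            r_ = np.random.default_rng(s)
            r, _ = compare_predictions(r_.normal(size=100), r_.normal(size=100))
            ok += abs(r) < 0.3
        assert ok >= 19
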