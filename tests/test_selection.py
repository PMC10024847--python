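"""Bootstrap screening, frequency filter, correlation pruning, CV search."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import RidgeClassifier

from esotox.selection import (EmptySelectionError, _ridge_decision,
                              bootstrap_screen, correlation_prune,
                              cv_subset_search, frequency_filter,
                              select_features)


@pytest.fixture()
def labels_161(rng):
    y = np.zeros(161, dtype=int)
    y[:51] = 1
    rng.shuffle(y)
    return y


class TestBootstrapScreen:
    def test_constant_feature_never_survives(self, rng, labels_161):
        X = pd.DataFrame({
            "constant": np.full(161, 3.0),
            "noise": rng.standard_normal(161),
        })
        screen = bootstrap_screen(X, labels_161, seed=1)
        assert screen.at["constant", "frequency"] == 0

    def test_perfect_separation_always_survives(self, rng, labels_161):
        X = pd.DataFrame({
            "oracle": labels_161.astype(float),
            "noise": rng.standard_normal(161),
        })
        screen = bootstrap_screen(X, labels_161, seed=2)
        assert screen.at["oracle", "frequency"] == 100
        assert screen.at["oracle", "median_p"] == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pure_noise_survival_near_test_level(self, seed, labels_161):
        rng = np.random.default_rng(1000 + seed)
        X = pd.DataFrame({"noise": rng.standard_normal(161)})
        screen = bootstrap_screen(X, labels_161, seed=seed)
        # F-test at level 0.1 -> expected survival ~10/100 iterations
        assert 0 <= screen.at["noise", "frequency"] <= 30

    def test_deterministic_given_seed(self, rng, labels_161):
        X = pd.DataFrame(rng.standard_normal((161, 5)))
        X.columns = [f"f{i}" for i in range(5)]
        a = bootstrap_screen(X, labels_161, seed=3)
        b = bootstrap_screen(X, labels_161, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_single_class_labels_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 2)))
        with pytest.raises(ValueError, match="binary"):
            bootstrap_screen(X, np.zeros(20, dtype=int))


class TestFrequencyFilter:
    def _screen(self, freqs):
        names = [f"f{i:03d}" for i in range(len(freqs))]
        return pd.DataFrame({"frequency": freqs,
                             "median_p": np.linspace(0.01, 0.09, len(freqs))},
                            index=names)

    def test_ten_percent_of_200(self):
        screen = self._screen(np.arange(1, 201))
        assert len(frequency_filter(screen)) == 20

    def test_minimum_of_ten(self):
        screen = self._screen(np.arange(1, 41))
        assert len(frequency_filter(screen)) == 10

    def test_ordering_and_tie_break_deterministic(self):
        screen = pd.DataFrame({
            "frequency": [50, 80, 80, 80, 10, 0],
            "median_p": [0.05, 0.03, 0.01, 0.03, 0.02, 0.5],
        }, index=["a", "b", "c", "d", "e", "f"])
        kept = frequency_filter(screen, min_features=4)
        # freq desc, then median p asc, then name
        assert kept[:4] == ["c", "b", "d", "a"]
        assert frequency_filter(screen, min_features=4) == kept

    def test_all_zero_frequencies_raise(self):
        screen = self._screen([0, 0, 0])
        with pytest.raises(EmptySelectionError):
            frequency_filter(screen)


class TestCorrelationPrune:
    def test_duplicate_feature_dropped(self, rng):
        base = rng.standard_normal(100)
        X = pd.DataFrame({"a": base, "b": base.copy(), "c": rng.standard_normal(100)})
        assert correlation_prune(X, ["a", "b", "c"]) == ["a", "c"]

    def test_orthogonal_features_all_kept(self):
        X = pd.DataFrame(np.eye(4), columns=list("abcd"))
        assert correlation_prune(X, list("abcd")) == list("abcd")

    def test_pairwise_oracle_no_surviving_pair_above_threshold(self, rng):
        X = pd.DataFrame(rng.standard_normal((60, 12)),
                         columns=[f"f{i:02d}" for i in range(12)])
        # inject correlated clones
        X["f01"] = X["f00"] + 0.1 * rng.standard_normal(60)
        X["f07"] = -X["f03"] + 0.2 * rng.standard_normal(60)
        kept = correlation_prune(X, list(X.columns), r_threshold=0.5)
        corr = X[kept].corr().abs().to_numpy()
        off_diag = corr[~np.eye(len(kept), dtype=bool)]
        assert np.all(off_diag <= 0.5)
        # every dropped feature violates against some kept feature ranked earlier
        for name in set(X.columns) - set(kept):
            earlier = kept[: [c for c in X.columns].index(name)]
            rs = [abs(np.corrcoef(X[name], X[e])[0, 1]) for e in kept]
            assert max(rs) > 0.5


class TestCvSubsetSearch:
    def test_closed_form_ridge_equals_sklearn(self, rng):
        xtr = rng.standard_normal((50, 6))
        xte = rng.standard_normal((20, 6))
        y = (rng.random(50) < 0.4).astype(int)
        for alpha in (0.1, 1.0, 100.0):
            clf = RidgeClassifier(alpha=alpha).fit(xtr, y)
            ours = _ridge_decision(xtr, 2.0 * y - 1.0, xte, alpha)
            np.testing.assert_allclose(ours, clf.decision_function(xte), atol=1e-8)

    def test_trace_length_equals_candidate_count(self, rng, labels_161):
        X = pd.DataFrame(rng.standard_normal((161, 6)),
                         columns=[f"f{i}" for i in range(6)])
        _, trace = cv_subset_search(X, labels_161, list(X.columns), n_rep=3, seed=0)
        assert len(trace) == 6

    def test_informative_feature_recovered_across_seeds(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            y = (rng.random(161) < 0.317).astype(int)
            X = pd.DataFrame(rng.standard_normal((161, 13)),
                             columns=["signal"] + [f"n{i:02d}" for i in range(12)])
            X["signal"] += 1.5 * y
            selected, _ = cv_subset_search(X, y, list(X.columns), n_rep=5, seed=seed)
            hits += "signal" in selected
        assert hits >= 9

    def test_null_trace_hovers_near_chance(self):
        rng = np.random.default_rng(42)
        y = (rng.random(161) < 0.317).astype(int)
        X = pd.DataFrame(rng.standard_normal((161, 8)),
                         columns=[f"n{i}" for i in range(8)])
        selected, trace = cv_subset_search(X, y, list(X.columns), seed=0)
        assert abs(trace["mean_auc"].mean() - 0.5) < 0.1
        assert len(selected) <= len(X.columns)

    def test_empty_candidates_rejected(self, rng, labels_161):
        X = pd.DataFrame(rng.standard_normal((161, 2)), columns=["a", "b"])
        with pytest.raises(EmptySelectionError):
            cv_subset_search(X, labels_161, [])


class TestSelectFeatures:
    @pytest.fixture()
    def signal_table(self):
        rng = np.random.default_rng(77)
        n = 161
        y = (rng.random(n) < 0.317).astype(int)
        X = pd.DataFrame(rng.standard_normal((n, 25)),
                         columns=[f"f{i:02d}" for i in range(25)])
        X["f00"] += 1.8 * y   # planted
        X["f01"] += 1.2 * y   # planted, weaker
        return X, y

    def test_full_determinism(self, signal_table):
        X, y = signal_table
        a = select_features(X, y, seed=9)
        b = select_features(X, y, seed=9)
        assert a.selected == b.selected
        pd.testing.assert_series_equal(a.frequencies, b.frequencies)

    def test_stage_nesting_and_decisions(self, signal_table):
        X, y = signal_table
        report = select_features(X, y, seed=9)
        assert set(report.selected) <= set(report.pruned) <= set(report.candidates)
        assert set(report.decisions) == set(X.columns)
        assert len(report.trace) == len(report.pruned)

    def test_planted_features_dominate_frequencies(self, signal_table):
        X, y = signal_table
        report = select_features(X, y, seed=9)
        assert report.frequencies["f00"] == 100
        assert "f00" in report.selected

    def test_selected_correlation_bound_post_hoc(self, signal_table):
        X, y = signal_table
        report = select_features(X, y, seed=9)
        if len(report.selected) > 1:
            corr = X[report.selected].corr().abs().to_numpy()
            assert np.all(corr[~np.eye(len(report.selected), dtype=bool)] <= 0.5)

    def test_variance_filter_subsumes_f_test(self, rng, signal_table):
        # a zero-variance feature can never pass the F-test: frequency 0
        X, y = signal_table
        X = X.copy()
        X["dead"] = 1.0
        report = select_features(X, y, seed=9)
        assert report.frequencies["dead"] == 0
        assert report.decisions["dead"] == "variance_or_f_test"
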