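"""Screening statistics, feature selection and classical baselines."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from awcop.metrics import auc_score
from awcop.simulate import CohortSpec, synth_clinical
from awcop.stats import (TopKImportanceSelector, baseline_feature_table,
                         benjamini_hochberg, compare_groups,
                         comparisons_frame, run_baselines,
                         select_top_features)


def _table(n_per_class, effects=None, seed=0, spec_kw=None):
    rng = np.random.default_rng(seed)
    spec = CohortSpec(n_patients=10, clinical_effects=effects or {},
                      **(spec_kw or {}))
    rows, y = [], []
    for i in range(2 * n_per_class):
        cls = i % 2
        rows.append(synth_clinical(cls, spec, rng))
        y.append(cls)
    return pd.DataFrame(rows).reset_index(drop=True), np.array(y)


class TestCompareGroups:
    def test_identical_groups_give_p_near_one(self):
        rng = np.random.default_rng(0)
        block = pd.DataFrame({"a": rng.normal(size=20),
                              "b": rng.normal(size=20)})
        table = pd.concat([block, block], ignore_index=True)
        y = np.array([0] * 20 + [1] * 20)
        for r in compare_groups(table, y):
            assert r.p_value > 0.9

    def test_toy_contingency_chi_square_is_twenty(self):
        table = pd.DataFrame({"risk": [1] * 10 + [0] * 10})
        y = np.array([0] * 10 + [1] * 10)
        (r,) = compare_groups(table, y)
        assert r.test == "chi_square"
        assert r.statistic == pytest.approx(20.0)  # no continuity correction

    def test_planted_marker_detected_with_power(self):
        hits = 0
        for seed in range(10):
            table, y = _table(100, effects={"fibrinogen_like": 0.8}, seed=seed)
            res = {r.feature: r for r in compare_groups(table, y)}
            hits += res["fibrinogen_like"].p_value < 0.01
        assert hits >= 8

    def test_constant_feature_flagged_not_fatal(self):
        table = pd.DataFrame({"const": np.zeros(20),
                              "ok": np.r_[np.zeros(10), np.ones(10)]})
        y = np.array([0] * 10 + [1] * 10)
        res = {r.feature: r for r in compare_groups(table, y)}
        assert "degenerate" in res["const"].note
        assert np.isnan(res["const"].p_value)
        assert np.isfinite(res["ok"].p_value)

    def test_mann_whitney_matches_enumeration_oracle(self):
        """Exact-permutation oracle at n1, n2 <= 8: the U statistic must
        agree exactly and the asymptotic p must track the exact p."""
        rng = np.random.default_rng(3)
        for n1, n2, ties in [(4, 5, False), (6, 6, True), (8, 7, False),
                             (8, 8, True)]:
            x = rng.normal(size=n1 + n2)
            if ties:
                x = np.round(x * 2) / 2
            y = np.array([0] * n1 + [1] * n2)
            table = pd.DataFrame({"f": x})
            (r,) = compare_groups(table, y)

            # enumeration: U of group 0 over every label assignment
            def u_stat(mask):
                ranks = rankdata(x)
                r0 = ranks[mask].sum()
                return r0 - n1 * (n1 + 1) / 2

            obs = u_stat(y == 0)
            assert r.statistic == pytest.approx(obs)
            mu = n1 * n2 / 2
            count, total = 0, 0
            for combo in itertools.combinations(range(n1 + n2), n1):
                mask = np.zeros(n1 + n2, dtype=bool)
                mask[list(combo)] = True
                if abs(u_stat(mask) - mu) >= abs(obs - mu) - 1e-9:
                    count += 1
                total += 1
            p_exact = count / total
            assert r.p_value == pytest.approx(p_exact, abs=0.05)

    def test_bh_adjustment_monotone_and_bounded(self):
        p = np.array([0.001, 0.02, 0.03, 0.5, np.nan])
        adj = benjamini_hochberg(p)
        finite = adj[np.isfinite(adj)]
        assert np.all(finite >= p[np.isfinite(p)] - 1e-12)
        assert np.all(finite <= 1.0)
        frame = comparisons_frame(compare_groups(
            pd.DataFrame({"a": np.arange(20.0)}),
            np.array([0] * 10 + [1] * 10), bh_column=True))
        assert frame["note"].str.contains("p_adj_bh").all()


class TestFeatureSelection:
    def test_exactly_k_selected_importances_sum_to_one(self):
        table, y = _table(40)
        ranking = select_top_features(table, y, k=15, n_estimators=100, seed=0)
        assert len(ranking.selected) == 15
        total = sum(imp for _, imp in ranking.ranking)
        assert total == pytest.approx(1.0)
        assert all(imp >= 0 for _, imp in ranking.ranking)

    def test_single_informative_feature_ranked_first(self):
        first = 0
        for seed in range(10):
            table, y = _table(60, effects={"fibrinogen_like": 2.0}, seed=seed)
            ranking = select_top_features(table, y, k=5,
                                          n_estimators=200, seed=seed)
            first += ranking.ranking[0][0] == "fibrinogen_like"
        assert first >= 9

    def test_duplicated_column_splits_importance(self):
        table, y = _table(60, effects={"fibrinogen_like": 2.0}, seed=1)
        solo = select_top_features(table, y, k=5, n_estimators=300, seed=0)
        imp_solo = dict(solo.ranking)["fibrinogen_like"]
        dup = table.copy()
        dup["fibrinogen_dup"] = dup["fibrinogen_like"]
        pair = dict(select_top_features(dup, y, k=5, n_estimators=300,
                                        seed=0).ranking)
        # the signal splits between the two copies (neither inherits the full
        # solo share) while their combined share stays the same order
        assert pair["fibrinogen_like"] < imp_solo
        assert pair["fibrinogen_dup"] < imp_solo
        combined = pair["fibrinogen_like"] + pair["fibrinogen_dup"]
        assert 0.5 * imp_solo <= combined <= 2.0 * imp_solo

    def test_selection_not_preferential_under_shuffled_labels(self):
        planted = {"fibrinogen_like", "d_dimer_like", "myoglobin_like"}
        rng = np.random.default_rng(0)
        freq = []
        table, y = _table(50, effects={f: 1.0 for f in planted}, seed=2)
        for seed in range(20):
            ys = rng.permutation(y)
            ranking = select_top_features(table, ys, k=15,
                                          n_estimators=100, seed=seed)
            freq.append(len(planted & set(ranking.selected)) / len(planted))
        assert np.mean(freq) == pytest.approx(15 / 50, abs=0.15)

    def test_k_larger_than_features_rejected(self):
        table, y = _table(10)
        with pytest.raises(ValueError, match="exceeds"):
            TopKImportanceSelector(k=60).fit(table, y)


class TestBaselines:
    @staticmethod
    def _random_features(n=300, p=20, seed=0, null=True):
        rng = np.random.default_rng(seed)
        x = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"f{i}" for i in range(p)])
        y = rng.integers(0, 2, n)
        splits = np.array(["train"] * int(0.6 * n)
                          + ["internal"] * int(0.2 * n)
                          + ["external"] * (n - int(0.8 * n)))
        return x, y, splits

    def test_five_models_two_splits_reported(self):
        x, y, splits = self._random_features()
        out = run_baselines(x, y, splits, seed=0)
        assert set(out) == {"logistic_regression", "random_forest", "svm",
                            "knn", "xgboost"}
        for reports in out.values():
            assert set(reports) == {"internal", "external"}
            for rep in reports.values():
                assert 0 <= rep.auc <= 1

    def test_null_features_give_chance_auc(self):
        x, y, splits = self._random_features(seed=7)
        out = run_baselines(x, y, splits, seed=0)
        for name, reports in out.items():
            for rep in reports.values():
                assert 0.35 <= rep.auc <= 0.65, (name, rep)

    def test_deterministic_under_fixed_seed(self):
        x, y, splits = self._random_features(n=120, seed=2)
        a = run_baselines(x, y, splits, seed=3)
        b = run_baselines(x, y, splits, seed=3)
        for name in ("logistic_regression", "random_forest", "xgboost"):
            assert a[name]["internal"].auc == b[name]["internal"].auc

    def test_feature_table_concatenates_three_blocks(self, tiny_cohort):
        _, manifest, _ = tiny_cohort
        selected = list(manifest.clinical.columns[:15])
        table = baseline_feature_table(manifest, selected,
                                       image_size=(16, 16))
        assert len(table) == 24
        assert "h3_over_h1" in table.columns          # pulse block
        assert "tongue_coating_hsv_h_mean" in table.columns  # image block
        assert set(selected) <= set(table.columns)    # screened labs
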