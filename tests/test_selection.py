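"""ANOVA filter, Boruta decisions, combination registry and fusion."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dosederm.cohort import CohortConfig, sample_population
from dosederm.selection import (
    COMBINATIONS,
    anova_filter,
    boruta_shap,
    fuse,
    two_stage_select,
)


def _frame(values, prefix="hcr_f"):
    return pd.DataFrame(values, columns=[f"{prefix}{j}"
                                         for j in range(values.shape[1])])


class TestAnovaFilter:
    def test_null_feature_rejected(self, rng):
        y = np.repeat([0, 1], 40)
        X = _frame(rng.normal(0, 1, (80, 1)))
        rep = anova_filter(X, y, alpha=0.001)
        assert rep.anova_retained == []

    def test_f_equals_squared_pooled_t(self, rng):
        y = np.repeat([0, 1], 25)
        x = np.concatenate([rng.normal(0, 1, 25), rng.normal(0.8, 1, 25)])
        rep = anova_filter(_frame(x[:, None]), y)
        t, _ = stats.ttest_ind(x[y == 1], x[y == 0], equal_var=True)
        assert rep.anova_f["hcr_f0"] == pytest.approx(t ** 2, rel=1e-9)

    def test_zero_variance_rejected(self, rng):
        y = np.repeat([0, 1], 10)
        X = _frame(np.ones((20, 1)))
        rep = anova_filter(X, y)
        assert rep.anova_p["hcr_f0"] == 1.0
        assert rep.anova_retained == []

    def test_monotone_alpha(self, rng):
        y = np.repeat([0, 1], 30)
        X = _frame(rng.normal(0, 1, (60, 20))
                   + 0.4 * y[:, None] * rng.random(20)[None, :])
        strict = set(anova_filter(X, y, alpha=0.01).anova_retained)
        loose = set(anova_filter(X, y, alpha=0.05).anova_retained)
        assert strict <= loose

    def test_recovers_v25_link_across_seeds(self):
        """The planted V25 effect survives the filter in >= 90% of seeds."""
        hits = 0
        for seed in range(10):
            _, dvh, labels, _ = sample_population(CohortConfig(), 500, seed=seed)
            X = pd.DataFrame({"dvh_skin5mm_V25Gy": dvh["skin5mm_V25Gy"]})
            rep = anova_filter(X, labels)
            hits += "dvh_skin5mm_V25Gy" in rep.anova_retained
        assert hits >= 9

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="binary"):
            anova_filter(_frame(rng.normal(size=(10, 2))), np.zeros(10))


class TestBorutaShap:
    def test_perfect_predictor_accepted(self, rng):
        n = 60
        y = rng.integers(0, 2, n)
        X = _frame(np.column_stack([y.astype(float), rng.normal(size=(n, 3))]))
        rep = boruta_shap(X, y, n_iter=25, seed=0, n_trees=30)
        assert rep.decisions["hcr_f0"] == "accepted"
        assert rep.boruta_hits["hcr_f0"] >= 23  # hits near n_iter

    def test_deterministic_given_seed(self, rng):
        n = 50
        y = rng.integers(0, 2, n)
        X = _frame(rng.normal(size=(n, 4)))
        a = boruta_shap(X, y, n_iter=10, seed=3, n_trees=20)
        b = boruta_shap(X, y, n_iter=10, seed=3, n_trees=20)
        assert a.boruta_hits == b.boruta_hits
        assert a.decisions == b.decisions

    def test_pure_noise_acceptance_rate_below_alpha(self):
        """Null false-acceptance: <= 5% of 50 noise features, seed-averaged."""
        rates = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            X = _frame(rng.normal(size=(148, 50)))
            y = rng.integers(0, 2, 148)
            rep = boruta_shap(X, y, n_iter=30, seed=seed, n_trees=50)
            rates.append(np.mean([d == "accepted" for d in rep.decisions.values()]))
        assert np.mean(rates) <= 0.05

    def test_planted_predictor_stable_across_seeds(self, rng):
        n = 120
        y = rng.integers(0, 2, n)
        signal = y + 0.3 * rng.normal(size=n)
        X = _frame(np.column_stack([signal, rng.normal(size=(n, 5))]))
        accepted = sum(
            boruta_shap(X, y, n_iter=20, seed=s, n_trees=30)
            .decisions["hcr_f0"] == "accepted"
            for s in range(10))
        assert accepted >= 9

    def test_invalid_iterations(self, rng):
        with pytest.raises(ValueError, match="invalid iterations"):
            boruta_shap(_frame(rng.normal(size=(10, 2))),
                        np.repeat([0, 1], 5), n_iter=0)


class TestCombinationsRegistry:
    def test_eleven_entries_match_reference_groups(self):
        assert set(COMBINATIONS) == set(range(1, 12))
        assert COMBINATIONS[1].blocks == ("clinical", "dvh")
        assert COMBINATIONS[2].blocks == ("hcr",)
        assert COMBINATIONS[6].blocks == ("dlr_v5gy",)
        assert COMBINATIONS[7].blocks == ("clinical", "dvh", "hcr")
        assert COMBINATIONS[11].blocks == ("clinical", "dvh", "dlr_v5gy")


class TestFuse:
    def _table(self, rng, n=20):
        cols = {}
        for j in range(3):
            cols[f"clin_c{j}"] = rng.normal(size=n)
        for j in range(4):
            cols[f"dvh_d{j}"] = rng.normal(size=n)
        for j in range(5):
            cols[f"hcr_h{j}"] = rng.normal(size=n)
        for j in range(5):
            cols[f"dlr_v5gy_conv1_{j}"] = rng.normal(size=n)
        return pd.DataFrame(cols)

    def test_combination_1_clinical_dvh_only(self, rng):
        X = self._table(rng)
        out = fuse(X, {}, COMBINATIONS[1])
        assert all(c.startswith(("clin_", "dvh_")) for c in out.columns)
        assert out.shape[1] == 7

    def test_combination_6_v5gy_only(self, rng):
        X = self._table(rng)
        out = fuse(X, {}, COMBINATIONS[6])
        assert all(c.startswith("dlr_v5gy_") for c in out.columns)

    def test_names_unique_and_traceable(self, rng):
        from dosederm.features import block_of

        X = self._table(rng)
        out = fuse(X, {}, COMBINATIONS[11])
        assert out.columns.is_unique
        assert {block_of(c) for c in out.columns} == \
            {"clinical", "dvh", "dlr_v5gy"}

    def test_selection_restricts_block(self, rng):
        X = self._table(rng)
        y = np.repeat([0, 1], 10)
        rep = two_stage_select(X[[c for c in X if c.startswith("hcr_")]], y,
                               n_iter=0, fold_id="outer0")
        rep.decisions = {"hcr_h0": "accepted", "hcr_h1": "rejected"}
        out = fuse(X, {"hcr": rep}, COMBINATIONS[2], fold_id="outer0")
        assert list(out.columns) == ["hcr_h0"]

    def test_fold_id_mismatch_raises(self, rng):
        X = self._table(rng)
        rep = anova_filter(X[["hcr_h0"]], np.repeat([0, 1], 10),
                           fold_id="outer1")
        with pytest.raises(AssertionError, match="fold"):
            fuse(X, {"hcr": rep}, COMBINATIONS[2], fold_id="outer0")

    def test_nothing_survives_raises(self, rng):
        X = self._table(rng)
        rep = anova_filter(X[["hcr_h0"]], np.repeat([0, 1], 10), alpha=1e-12)
        with pytest.raises(ValueError, match="no features survived"):
            fuse(X, {"hcr": rep}, COMBINATIONS[2])
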