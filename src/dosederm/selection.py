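"""Two-stage feature selection: ANOVA filter then Boruta with TreeSHAP.

Stage 1 keeps features whose one-way ANOVA across the two outcome groups
(with a binary outcome this is the two-group F test, the square of the
pooled t statistic) reaches p < alpha.

Stage 2 is the Boruta scheme with SHAP importances: at every iteration the
retained columns are independently permuted to create "shadow" features, a
random forest without depth limit is fit on [real | shadow], per-feature
importance is the mean |TreeSHAP value| over samples, and a real feature
scores a hit when its importance exceeds the best shadow importance.  After
``n_iter`` rounds each feature's hit count is compared against
Binomial(n_iter, 1/2) with a two-sided test at alpha = 0.05: significantly
above -> accepted, significantly below -> rejected, otherwise tentative
(treated as rejected at the modeling boundary).

Selection objects carry the fold id they were fitted on; fusion asserts it,
so a report fitted on one training fold can never silently select features
for another fold's data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif

from dosederm.features import block_of
from dosederm.treeshap import forest_shap_values


@dataclass
class SelectionReport:
    """Outcome of one selection stage on one training fold."""

    anova_f: dict[str, float] = field(default_factory=dict)
    anova_p: dict[str, float] = field(default_factory=dict)
    anova_retained: list[str] = field(default_factory=list)
    boruta_hits: dict[str, int] = field(default_factory=dict)
    decisions: dict[str, str] = field(default_factory=dict)  # accepted/rejected/tentative
    n_iter: int = 0
    seed: int = 0
    fold_id: str = ""

    @property
    def accepted(self) -> list[str]:
        return [f for f, d in self.decisions.items() if d == "accepted"]

    def selected_features(self) -> list[str]:
        """Features surviving both stages (tentative counts as rejected)."""
        if self.decisions:
            return self.accepted
        return list(self.anova_retained)


def anova_filter(X: pd.DataFrame, y, alpha: float = 0.05,
                 fold_id: str = "") -> SelectionReport:
    """Stage 1: per-feature one-way ANOVA, retain p < alpha.

    Zero-variance features get p = 1 and are rejected.
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("y must be binary with both classes present")
    values = X.to_numpy(dtype=float)
    variances = values.var(axis=0)
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # constant features handled below
        F, p = f_classif(values, y)
    F = np.where(np.isfinite(F), F, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    p = np.where(variances > 0, p, 1.0)
    report = SelectionReport(fold_id=fold_id)
    for name, fv, pv in zip(X.columns, F, p):
        report.anova_f[name] = float(fv)
        report.anova_p[name] = float(pv)
    report.anova_retained = [n for n in X.columns if report.anova_p[n] < alpha]
    return report


def boruta_shap(X: pd.DataFrame, y, n_iter: int = 200, seed: int = 0,
                n_trees: int = 200, alpha: float = 0.05,
                fold_id: str = "") -> SelectionReport:
    """Stage 2: Boruta decisions from shadow-beating SHAP importances."""
    if n_iter < 1:
        raise ValueError("invalid iterations: n_iter must be >= 1")
    if X.shape[1] < 1:
        raise ValueError("need >= 1 retained feature")
    y = np.asarray(y).astype(int)
    values = np.ascontiguousarray(X.to_numpy(dtype=float))
    n, m = values.shape
    rng = np.random.default_rng(seed)
    hits = np.zeros(m, dtype=int)
    for it in range(n_iter):
        shadow = values.copy()
        for j in range(m):  # shadows regenerated each round
            shadow[:, j] = values[rng.permutation(n), j]
        design = np.hstack([values, shadow])
        forest = RandomForestClassifier(
            n_estimators=n_trees, max_depth=None,
            random_state=int(rng.integers(0, 2 ** 31 - 1)), n_jobs=1,
        ).fit(design, y)
        phi = forest_shap_values(forest, design)
        importance = np.abs(phi).mean(axis=0)
        best_shadow = importance[m:].max()
        hits += importance[:m] > best_shadow

    report = SelectionReport(n_iter=n_iter, seed=seed, fold_id=fold_id)
    for name, h in zip(X.columns, hits):
        report.boruta_hits[name] = int(h)
        res = stats.binomtest(int(h), n_iter, 0.5, alternative="two-sided")
        if res.pvalue < alpha:
            report.decisions[name] = "accepted" if h > n_iter / 2 else "rejected"
        else:
            report.decisions[name] = "tentative"
    return report


def two_stage_select(X: pd.DataFrame, y, alpha: float = 0.05,
                     n_iter: int = 200, seed: int = 0, n_trees: int = 200,
                     fold_id: str = "") -> SelectionReport:
    """ANOVA filter followed by Boruta on the retained columns.

    ``n_iter=0`` skips the Boruta stage (ANOVA-only selection).
    """
    report = anova_filter(X, y, alpha=alpha, fold_id=fold_id)
    if not report.anova_retained or n_iter == 0:
        return report
    stage2 = boruta_shap(X[report.anova_retained], y, n_iter=n_iter,
                         seed=seed, n_trees=n_trees, fold_id=fold_id)
    report.boruta_hits = stage2.boruta_hits
    report.decisions = stage2.decisions
    report.n_iter = n_iter
    report.seed = seed
    return report


@dataclass(frozen=True)
class FeatureCombination:
    """One row of the 11-entry feature-set registry."""

    id: int
    name: str
    blocks: tuple[str, ...]


COMBINATIONS: dict[int, FeatureCombination] = {
    1: FeatureCombination(1, "Clinical+DVH", ("clinical", "dvh")),
    2: FeatureCombination(2, "HCR", ("hcr",)),
    3: FeatureCombination(3, "DLR_Original", ("dlr_original",)),
    4: FeatureCombination(4, "DLR_Skin5mm", ("dlr_skin5mm",)),
    5: FeatureCombination(5, "DLR_PTV100", ("dlr_ptv100",)),
    6: FeatureCombination(6, "DLR_V5Gy", ("dlr_v5gy",)),
    7: FeatureCombination(7, "Clinical+DVH+HCR", ("clinical", "dvh", "hcr")),
    8: FeatureCombination(8, "Clinical+DVH+DLR_Original",
                          ("clinical", "dvh", "dlr_original")),
    9: FeatureCombination(9, "Clinical+DVH+DLR_Skin5mm",
                          ("clinical", "dvh", "dlr_skin5mm")),
    10: FeatureCombination(10, "Clinical+DVH+DLR_PTV100",
                           ("clinical", "dvh", "dlr_ptv100")),
    11: FeatureCombination(11, "Clinical+DVH+DLR_V5Gy",
                           ("clinical", "dvh", "dlr_v5gy")),
}


def fuse(X: pd.DataFrame, reports: dict[str, SelectionReport],
         combination: FeatureCombination, fold_id: str = "") -> pd.DataFrame:
    """Concatenate the combination's blocks, restricted to selected features.

    Blocks with a selection report contribute only their surviving columns;
    blocks without one pass through unchanged.  Raises when nothing
    survives.  Asserts every report was fitted on the requesting fold.
    """
    cols: list[str] = []
    for block in combination.blocks:
        block_cols = [c for c in X.columns if block_of(c) == block]
        report = reports.get(block)
        if report is not None:
            if report.fold_id != fold_id:
                raise AssertionError(
                    f"selection report for block {block!r} was fitted on fold "
                    f"{report.fold_id!r}, not {fold_id!r}")
            keep = set(report.selected_features())
            block_cols = [c for c in block_cols if c in keep]
        cols.extend(block_cols)
    if not cols:
        raise ValueError("no features survived selection for this combination")
    return X[cols]
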