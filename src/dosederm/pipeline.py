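"""Rebalancing, stacking ensemble and nested cross-validation.

The evaluation protocol is a stratified 5x5 nested cross-validation: the
outer loop estimates generalization, the inner loop drives a randomized
hyperparameter search (scored by mean inner-fold AUC).  Everything fitted
-- feature selection, scaling, SMOTE-ENN rebalancing, hyperparameters,
models -- sees training-fold rows only; test folds are touched exactly once
for prediction.

The classifier is a stacking ensemble: logistic regression, random forest
and gradient-boosted trees as base learners, their out-of-sample predicted
probabilities feeding a logistic meta-classifier (classic leak-safe
stacking via internal cross-validation).

SMOTE-ENN runs strictly inside training folds: minority samples are
oversampled by convex interpolation between nearest minority neighbors
until classes balance, then edited-nearest-neighbor cleaning removes any
sample whose k nearest neighbors vote against its label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.ensemble import StackingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from dosederm.metrics import MetricReport, auc, brier_score, confusion_metrics
from dosederm.selection import COMBINATIONS, FeatureCombination, fuse, two_stage_select


@dataclass
class FoldPlan:
    """Stratified outer folds plus, per outer fold, inner folds on its train ids."""

    outer: list[tuple[np.ndarray, np.ndarray]]
    inner: list[list[tuple[np.ndarray, np.ndarray]]]
    seed: int


def make_fold_plan(labels, k_outer: int = 5, k_inner: int = 5,
                   seed: int = 0) -> FoldPlan:
    """Patient-level stratified nested fold plan (deterministic in seed)."""
    y = np.asarray(labels).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k_outer:
        raise ValueError("insufficient class size for stratified outer folds")
    outer_cv = StratifiedKFold(n_splits=k_outer, shuffle=True, random_state=seed)
    outer = [(tr.copy(), te.copy()) for tr, te in outer_cv.split(np.zeros_like(y), y)]
    inner = []
    for f, (tr, _) in enumerate(outer):
        inner_cv = StratifiedKFold(n_splits=k_inner, shuffle=True,
                                   random_state=seed + 1000 + f)
        inner.append([(tr[i], tr[v]) for i, v in
                      inner_cv.split(np.zeros(len(tr)), y[tr])])
    return FoldPlan(outer=outer, inner=inner, seed=seed)


def smote_enn(X, y, k_smote: int = 5, k_enn: int = 3, seed: int = 0):
    """SMOTE to equal class counts, then edited-nearest-neighbor cleaning."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("degenerate training fold: single class")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    rng = np.random.default_rng(seed)

    X_min = X[y == minority]
    n_new = n_maj - n_min
    if n_new > 0:
        if n_min <= k_smote:
            raise ValueError("minority count must exceed k_smote")
        nn = NearestNeighbors(n_neighbors=k_smote + 1).fit(X_min)
        _, idx = nn.kneighbors(X_min)  # column 0 is the point itself
        base = rng.integers(0, n_min, size=n_new)
        pick = rng.integers(1, k_smote + 1, size=n_new)
        u = rng.random(size=(n_new, 1))
        neigh = X_min[idx[base, pick]]
        synth = X_min[base] + u * (neigh - X_min[base])
        X_bal = np.vstack([X, synth])
        y_bal = np.concatenate([y, np.full(n_new, minority)])
    else:
        X_bal, y_bal = X.copy(), y.copy()

    nn = NearestNeighbors(n_neighbors=k_enn + 1).fit(X_bal)
    _, idx = nn.kneighbors(X_bal)
    votes = y_bal[idx[:, 1:]]  # exclude self
    agree = (votes == y_bal[:, None]).sum(axis=1) * 2 > k_enn
    if agree.sum() == 0 or len(np.unique(y_bal[agree])) < 2:
        return X_bal, y_bal  # refuse to empty a class; skip cleaning
    return X_bal[agree], y_bal[agree]


@dataclass
class SearchSpace:
    """Randomized-search distributions for the three base learners."""

    rf_n_estimators: tuple[int, int] = (100, 500)
    rf_max_depth: tuple = (None, 3, 15)  # None or uniform integer in [3, 15]
    gbdt_n_estimators: tuple[int, int] = (50, 300)
    gbdt_learning_rate: tuple[float, float] = (0.01, 0.3)
    gbdt_max_depth: tuple[int, int] = (2, 5)
    lr_log10_c: tuple[float, float] = (-3.0, 3.0)
    n_draws: int = 30

    def sample(self, rng: np.random.Generator) -> dict:
        if rng.random() < 0.25:
            depth = None
        else:
            depth = int(rng.integers(self.rf_max_depth[1], self.rf_max_depth[2] + 1))
        return {
            "rf_n_estimators": int(rng.integers(*self.rf_n_estimators)),
            "rf_max_depth": depth,
            "gbdt_n_estimators": int(rng.integers(*self.gbdt_n_estimators)),
            "gbdt_learning_rate": float(rng.uniform(*self.gbdt_learning_rate)),
            "gbdt_max_depth": int(rng.integers(self.gbdt_max_depth[0],
                                               self.gbdt_max_depth[1] + 1)),
            "lr_c": float(10 ** rng.uniform(*self.lr_log10_c)),
        }


@dataclass
class PipelineConfig:
    """Everything the nested-CV driver needs, reproducible from one seed."""

    k_outer: int = 5
    k_inner: int = 5
    seed: int = 0
    search: SearchSpace = field(default_factory=SearchSpace)
    meta_cv: int = 5
    smote_k: int = 5
    enn_k: int = 3
    anova_alpha: float = 0.05
    boruta_iters: int = 200        # 0 disables stage 2 (ANOVA only)
    boruta_trees: int = 200
    select_clinical_dvh: bool = True  # pass clinical/DVH through both stages
    selected_blocks: tuple = ("hcr", "dlr_original", "dlr_skin5mm",
                              "dlr_ptv100", "dlr_v5gy")


def fast_config(seed: int = 0, boruta_iters: int = 0) -> PipelineConfig:
    """Desk-scale settings: small search and forests, same protocol."""
    return PipelineConfig(
        seed=seed,
        k_inner=3,
        meta_cv=3,
        boruta_iters=boruta_iters,
        boruta_trees=50,
        search=SearchSpace(rf_n_estimators=(25, 60), gbdt_n_estimators=(20, 50),
                           n_draws=3),
    )


def _base_learners(params: dict, seed: int):
    lr = LogisticRegression(C=params["lr_c"], max_iter=2000)
    rf = RandomForestClassifier(
        n_estimators=params["rf_n_estimators"], max_depth=params["rf_max_depth"],
        random_state=seed, n_jobs=1)
    gbdt = GradientBoostingClassifier(
        n_estimators=params["gbdt_n_estimators"],
        learning_rate=params["gbdt_learning_rate"],
        max_depth=params["gbdt_max_depth"], random_state=seed + 1)
    return lr, rf, gbdt


def make_model(params: dict, seed: int, model: str = "stacked",
               meta_cv: int = 5) -> Pipeline:
    """Preprocessing + classifier pipeline for one hyperparameter draw."""
    lr, rf, gbdt = _base_learners(params, seed)
    if model == "lr":
        clf = lr
    elif model == "rf":
        clf = rf
    elif model == "gbdt":
        clf = gbdt
    elif model == "stacked":
        clf = StackingClassifier(
            estimators=[("lr", lr), ("rf", rf), ("gbdt", gbdt)],
            final_estimator=LogisticRegression(max_iter=2000),
            stack_method="predict_proba",
            cv=StratifiedKFold(n_splits=meta_cv, shuffle=True,
                               random_state=seed + 2),
            n_jobs=1,
        )
    else:
        raise ValueError(f"unknown model {model!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def fit_stacked(X, y, space: SearchSpace, inner_folds, seed: int,
                config: PipelineConfig | None = None, model: str = "stacked"):
    """Randomized search on the inner folds, then refit on all of (X, y).

    Inner-fold training splits are rebalanced with SMOTE-ENN before
    fitting; validation rows stay untouched.  Returns the fitted model and
    the search log (one row per draw with mean inner AUC and F1).
    """
    config = config or PipelineConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(seed)
    draws = [space.sample(rng) for _ in range(space.n_draws)]
    # rebalance each inner training split once; draws share the same folds
    rebalanced = [
        (smote_enn(X[tr], y[tr], config.smote_k, config.enn_k, seed=seed + k), va)
        for k, (tr, va) in enumerate(inner_folds)
    ]
    log_rows = []
    best = None
    for d_idx, params in enumerate(draws):
        aucs, f1s = [], []
        for (X_res, y_res), va in rebalanced:
            mdl = make_model(params, seed=seed + d_idx, model=model,
                             meta_cv=config.meta_cv)
            mdl.fit(X_res, y_res)
            probs = mdl.predict_proba(X[va])[:, 1]
            if len(np.unique(y[va])) == 2:
                aucs.append(auc(y[va], probs))
            f1s.append(confusion_metrics(y[va], (probs >= 0.5).astype(int)).f1)
        mean_auc = float(np.mean(aucs)) if aucs else 0.5
        mean_f1 = float(np.mean(f1s))
        log_rows.append({**params, "mean_auc": mean_auc, "mean_f1": mean_f1})
        if best is None or mean_auc > best[0]:
            best = (mean_auc, params, d_idx)
    if best is None:
        raise RuntimeError("search failed: no draw evaluated")
    _, best_params, best_idx = best
    final = make_model(best_params, seed=seed + best_idx, model=model,
                       meta_cv=config.meta_cv)
    final.fit(X, y)
    log = pd.DataFrame(log_rows)
    if "rf_max_depth" in log.columns:
        log["rf_max_depth"] = log["rf_max_depth"].astype(object)
    return final, log


@dataclass
class NestedCvResult:
    report: MetricReport
    fold_models: list
    fold_features: list[list[str]]
    search_log: pd.DataFrame
    plan: FoldPlan


def _select_for_fold(X_tr: pd.DataFrame, y_tr, combination: FeatureCombination,
                     config: PipelineConfig, fold_id: str):
    from dosederm.features import block_of
    blocks_to_select = set(config.selected_blocks)
    if config.select_clinical_dvh:
        blocks_to_select |= {"clinical", "dvh"}
    reports = {}
    for block in combination.blocks:
        if block not in blocks_to_select:
            continue
        cols = [c for c in X_tr.columns if block_of(c) == block]
        if not cols:
            continue
        if config.boruta_iters > 0:
            reports[block] = two_stage_select(
                X_tr[cols], y_tr, alpha=config.anova_alpha,
                n_iter=config.boruta_iters, seed=config.seed,
                n_trees=config.boruta_trees, fold_id=fold_id)
        else:
            from dosederm.selection import anova_filter
            reports[block] = anova_filter(X_tr[cols], y_tr,
                                          alpha=config.anova_alpha,
                                          fold_id=fold_id)
    return reports


def run_nested_cv(X: pd.DataFrame, y, combination: FeatureCombination | int,
                  config: PipelineConfig | None = None,
                  model: str = "stacked") -> NestedCvResult:
    """Full nested-CV evaluation of one feature combination.

    Per outer fold: feature selection on the training rows, SMOTE-ENN
    rebalancing inside training splits, randomized search on the inner
    folds, refit, and a single prediction pass over the held-out fold.
    """
    config = config or PipelineConfig()
    if isinstance(combination, int):
        combination = COMBINATIONS[combination]
    y = np.asarray(y).astype(int)
    plan = make_fold_plan(y, config.k_outer, config.k_inner, config.seed)
    folds, models, feats, logs = [], [], [], []
    pooled_y, pooled_p = [], []
    for f, (tr, te) in enumerate(plan.outer):
        fold_id = f"outer{f}"
        X_tr = X.iloc[tr]
        reports = _select_for_fold(X_tr, y[tr], combination, config, fold_id)
        X_tr_f = fuse(X_tr, reports, combination, fold_id=fold_id)
        cols = list(X_tr_f.columns)

        # map plan's absolute inner indices to positions within the train fold
        pos = {idx: k for k, idx in enumerate(tr)}
        inner = [(np.array([pos[i] for i in itr]), np.array([pos[i] for i in iva]))
                 for itr, iva in plan.inner[f]]

        X_res, y_res = smote_enn(X_tr_f.to_numpy(dtype=float), y[tr],
                                 config.smote_k, config.enn_k,
                                 seed=config.seed + 17 * f)
        mdl, log = fit_stacked(X_tr_f.to_numpy(dtype=float), y[tr],
                               config.search, inner, seed=config.seed + 31 * f,
                               config=config, model=model)
        # final refit on the rebalanced full training fold
        mdl.fit(X_res, y_res)

        X_te_f = X.iloc[te][cols]
        assert len(X_te_f) == len(te), "test fold size changed"
        probs = mdl.predict_proba(X_te_f.to_numpy(dtype=float))[:, 1]
        m = confusion_metrics(y[te], (probs >= 0.5).astype(int))
        m.auc = auc(y[te], probs) if len(np.unique(y[te])) == 2 else None
        m.brier = brier_score(y[te], probs)
        folds.append(m)
        models.append(mdl)
        feats.append(cols)
        log["outer_fold"] = f
        logs.append(log)
        pooled_y.append(y[te])
        pooled_p.append(probs)
    report = MetricReport(folds=folds, pooled_y=np.concatenate(pooled_y),
                          pooled_probs=np.concatenate(pooled_p))
    return NestedCvResult(report=report, fold_models=models,
                          fold_features=feats,
                          search_log=pd.concat(logs, ignore_index=True),
                          plan=plan)


def run_ablation(X: pd.DataFrame, y, combination: FeatureCombination | int,
                 config: PipelineConfig | None = None) -> dict[str, NestedCvResult]:
    """Nested CV for each base learner alone plus the stacking ensemble."""
    return {name: run_nested_cv(X, y, combination, config, model=name)
            for name in ("lr", "rf", "gbdt", "stacked")}


def hyperparam_sensitivity(search_log: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Mean F1 grouped by each searched tree hyperparameter."""
    if search_log is None or len(search_log) == 0:
        raise ValueError("no search data")
    out = {}
    for param in ("rf_n_estimators", "rf_max_depth", "gbdt_n_estimators",
                  "gbdt_learning_rate", "gbdt_max_depth"):
        if param not in search_log.columns:
            continue
        col = search_log[param]
        if col.dtype == float and col.nunique() > 12:
            grouping = pd.cut(col, bins=4)
        else:
            grouping = col.astype(object).where(col.notna(), "None")
        grp = search_log.groupby(grouping, observed=True)["mean_f1"]
        out[param] = pd.DataFrame({"mean_f1": grp.mean(), "count": grp.size()})
    return out
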