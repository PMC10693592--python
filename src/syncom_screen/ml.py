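"""Random-forest and elastic-net models of pathogen outcome from community
composition.

Twelve analysis configurations are trained: {random forest, elastic net} x
{median-aggregated, individual-plant rows} x {classification on
presence/absence, regression on presence/absence, regression on end-point
colonization} — classification uses presence features only.  Tuning uses
10 rounds of 5-fold cross-validation with all rows of one community kept in
the same fold (the microbox is confounded with the community, so anything
less leaks composition into the validation folds).  Classification tunes on
Cohen's kappa, regression on RMSE; final models are refitted on all
training rows with the tuned parameters and judged on an independent test
screen.  Baselines: a random classifier assigning the positive class with
the training prevalence, and a constant prediction of the training mean.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import ElasticNet, LogisticRegression
from sklearn.metrics import cohen_kappa_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .bimodality import assign_classes, bootstrap_stability, estimate_density, find_threshold
from .records import ScreenDataset, aggregate_by_box, log10_transform, normalize_pathogen, partition_ambiguous

__all__ = [
    "FeatureMatrix",
    "AnalysisConfig",
    "PerformanceReport",
    "enumerate_configs",
    "build_features",
    "classification_thresholds",
    "grouped_folds",
    "grouped_repeated_cv",
    "fit_final",
    "evaluate_on_test",
    "random_classifier_baseline",
    "constant_mean_baseline",
    "relative_importance",
    "median_importance",
    "threshold_sensitivity_refit",
    "DEFAULT_SEEDS",
]

POSITIVE = "protected"
DEFAULT_SEEDS = (11, 23, 37, 41, 59, 67, 83, 97)


@dataclass(frozen=True)
class AnalysisConfig:
    algorithm: str        # 'RF' | 'GLMNet'
    task: str             # 'classification' | 'regression'
    features: str         # 'presence' | 'colonization'
    level: str            # 'median' | 'individual'

    def __post_init__(self) -> None:
        if self.algorithm not in ("RF", "GLMNet"):
            raise ValueError("algorithm must be RF or GLMNet")
        if self.task not in ("classification", "regression"):
            raise ValueError("bad task")
        if self.features not in ("presence", "colonization"):
            raise ValueError("bad features")
        if self.level not in ("median", "individual"):
            raise ValueError("bad level")
        if self.task == "classification" and self.features != "presence":
            raise ValueError("classification uses presence features only")

    @property
    def label(self) -> str:
        return f"{self.algorithm}-{self.task}-{self.features}-{self.level}"


def enumerate_configs() -> list[AnalysisConfig]:
    """The 12 model-algorithm combinations, in deterministic order."""
    out = []
    for algo, level in itertools.product(("RF", "GLMNet"), ("median", "individual")):
        out.append(AnalysisConfig(algo, "classification", "presence", level))
        out.append(AnalysisConfig(algo, "regression", "presence", level))
        out.append(AnalysisConfig(algo, "regression", "colonization", level))
    return out


@dataclass
class FeatureMatrix:
    X: pd.DataFrame              # rows x strain features
    y: pd.Series                 # class label or normalized reduction
    groups: pd.Series            # community id per row
    experiment: pd.Series
    config_level: str
    config_features: str


def _prepared(dataset: ScreenDataset) -> ScreenDataset:
    """log10 + mean-normalized copy (the ML response scale)."""
    ds = dataset
    if ds.scale == "linear":
        ds = log10_transform(ds)
    if not ds.normalized:
        ds = normalize_pathogen(ds, center="mean")
    return ds


def _stable_threshold(values: np.ndarray, exp: str) -> float:
    """Class threshold for one experiment's values.

    The point estimate is the multiscale density minimum; it is then
    stabilised as the median of the bootstrap distribution of minima
    around it (a single KDE minimum wanders across the valley floor on
    wide shallow valleys; the bootstrap median does not).
    """
    thr = find_threshold(values)
    if thr is None:
        raise ValueError(f"no density minimum found for experiment {exp!r}")
    rng = np.random.default_rng(0)
    found = []
    for _ in range(200):
        m = find_threshold(rng.choice(values, size=values.size, replace=True))
        if m is not None:
            found.append(m)
    if len(found) >= 20:
        return float(np.median(found))
    return thr


def classification_thresholds(dataset: ScreenDataset, level: str = "median"
                              ) -> dict[str, float]:
    """Per-experiment density-minimum thresholds on the normalized scale."""
    ds = _prepared(dataset)
    out: dict[str, float] = {}
    if level == "median":
        box = aggregate_by_box(ds).table
        ids = set(ds.communities.community_ids)
        box = box[box["treatment"].isin(ids)]
        for exp, grp in box.groupby("experiment"):
            out[exp] = _stable_threshold(grp["pathogen_median"].to_numpy(), exp)
    else:
        for exp in ds.experiments:
            vals = [r.pathogen_cfu for r in ds.community_records() if r.experiment == exp]
            if not vals:
                continue
            out[exp] = _stable_threshold(np.asarray(vals), exp)
    return out


def build_features(dataset: ScreenDataset, features: str = "presence",
                   level: str = "median", task: str = "classification",
                   thresholds: dict[str, float] | None = None) -> FeatureMatrix:
    """Strain-feature matrix plus response for one screen.

    Presence features are 1 iff the strain was inoculated; colonization
    features are end-point log10 abundances (ambiguous counts partitioned,
    absent strains at 0).  ``level='median'`` aggregates the four plants of
    a box by their median first.  Classification responses come from the
    per-experiment density-minimum thresholds (computed from the data when
    not supplied); regression responses are the normalized pathogen
    reduction.
    """
    if dataset.communities is None:
        raise ValueError("dataset has no community set")
    ds = _prepared(dataset)
    members = ds.communities.membership()
    # feature columns: every strain appearing in the screen's memberships
    strains = sorted({s for m in members.values() for s in m})

    rows, resp, grp, exps, ids = [], [], [], [], []
    if level == "individual":
        for r in ds.community_records():
            comm = members[r.treatment]
            if features == "presence":
                vec = [1.0 if s in comm else 0.0 for s in strains]
            else:
                part = partition_ambiguous(r)
                vec = [part.strain_cfu.get(s, 0.0) if s in comm else 0.0 for s in strains]
            rows.append(vec)
            resp.append(r.pathogen_cfu)
            grp.append(r.treatment)
            exps.append(r.experiment)
            ids.append(r.plant_id)
    else:
        per_comm: dict[str, list] = {}
        for r in ds.community_records():
            per_comm.setdefault(r.treatment, []).append(r)
        for cid in sorted(per_comm):
            recs = per_comm[cid]
            comm = members[cid]
            if features == "presence":
                vec = [1.0 if s in comm else 0.0 for s in strains]
            else:
                parts = [partition_ambiguous(r) for r in recs]
                vec = [float(np.median([p.strain_cfu.get(s, 0.0) for p in parts]))
                       if s in comm else 0.0 for s in strains]
            rows.append(vec)
            resp.append(float(np.median([r.pathogen_cfu for r in recs])))
            grp.append(cid)
            exps.append(recs[0].experiment)
            ids.append(cid)

    X = pd.DataFrame(rows, columns=strains, index=ids)
    y = pd.Series(resp, index=ids, name="response")
    if task == "classification":
        if thresholds is None:
            thresholds = classification_thresholds(dataset, level=level)
        labels = {}
        for rid, exp, v in zip(ids, exps, resp):
            labels[rid] = "protected" if v < thresholds[exp] else "non_protected"
        y = pd.Series(labels, name="class").loc[ids]
    return FeatureMatrix(X, y, pd.Series(grp, index=ids, name="community"),
                         pd.Series(exps, index=ids, name="experiment"),
                         level, features)


# --------------------------------------------------------------- CV & tuning


def grouped_folds(groups: pd.Series, n_folds: int, n_repeats: int,
                  seed: int) -> list[list[np.ndarray]]:
    """Repeated group-level fold assignment: each repeat shuffles the
    communities and partitions them into ``n_folds`` folds; every row of a
    community lands in exactly one fold per repeat."""
    uniq = np.asarray(sorted(groups.unique()))
    if len(uniq) < n_folds:
        raise ValueError("fewer groups than folds")
    rng = np.random.default_rng(seed)
    out = []
    g = groups.to_numpy()
    for _ in range(n_repeats):
        perm = rng.permutation(uniq)
        chunks = np.array_split(perm, n_folds)
        fold_rows = [np.flatnonzero(np.isin(g, chunk)) for chunk in chunks]
        out.append(fold_rows)
    return out


def _rf_grid(p: int) -> list[dict]:
    vals = []
    for mf in (1, max(1, int(np.sqrt(p))), max(1, p // 3), min(8, p)):
        if mf not in vals:
            vals.append(mf)
    return [{"max_features": mf} for mf in vals]


def _glmnet_grid() -> list[dict]:
    alphas = np.logspace(-3, 0.5, 10)
    return [{"l1_ratio": l1, "alpha": a}
            for l1 in (0.1, 0.55, 1.0) for a in alphas]


def _make_model(config: AnalysisConfig, params: dict, seed: int):
    if config.algorithm == "RF":
        cls = RandomForestClassifier if config.task == "classification" else RandomForestRegressor
        return cls(n_estimators=500, max_features=params["max_features"],
                   random_state=seed, n_jobs=1)
    if config.task == "regression":
        est = ElasticNet(alpha=params["alpha"], l1_ratio=params["l1_ratio"],
                         max_iter=5000)
    else:
        est = LogisticRegression(solver="saga", C=1.0 / max(params["alpha"], 1e-8),
                                 l1_ratio=params["l1_ratio"], max_iter=5000)
    return Pipeline([("scale", StandardScaler()), ("glmnet", est)])


def _score(config: AnalysisConfig, y_true, y_pred) -> float:
    if config.task == "classification":
        return cohen_kappa_score(y_true, y_pred)
    return -float(np.sqrt(np.mean((np.asarray(y_true, float) - np.asarray(y_pred, float)) ** 2)))


def grouped_repeated_cv(fm: FeatureMatrix, config: AnalysisConfig, seed: int,
                        n_folds: int = 5, n_repeats: int = 10,
                        grid: list[dict] | None = None) -> dict:
    """Tune hyperparameters by community-grouped repeated CV.

    Returns the parameter set with the best mean tuning metric (kappa for
    classification, RMSE for regression) over the ``n_repeats x n_folds``
    fold fits.
    """
    if grid is None:
        grid = _rf_grid(fm.X.shape[1]) if config.algorithm == "RF" else _glmnet_grid()
    if len(grid) == 1:
        return dict(grid[0])
    folds = grouped_folds(fm.groups, n_folds, n_repeats, seed)
    X = fm.X.to_numpy()
    y = fm.y.to_numpy()
    best_params, best_score = None, -np.inf
    for params in grid:
        scores = []
        for repeat in folds:
            for val_rows in repeat:
                mask = np.ones(len(y), dtype=bool)
                mask[val_rows] = False
                if config.task == "classification" and len(set(y[mask])) < 2:
                    continue
                model = _make_model(config, params, seed)
                model.fit(X[mask], y[mask])
                scores.append(_score(config, y[val_rows], model.predict(X[val_rows])))
        mean = float(np.mean(scores)) if scores else -np.inf
        if mean > best_score:
            best_score, best_params = mean, dict(params)
    return best_params


def fit_final(fm: FeatureMatrix, config: AnalysisConfig, params: dict, seed: int):
    """Refit on all training rows with the tuned parameters."""
    model = _make_model(config, params, seed)
    model.fit(fm.X.to_numpy(), fm.y.to_numpy())
    return model


# ----------------------------------------------------------------- metrics


@dataclass
class PerformanceReport:
    config: AnalysisConfig | None
    metrics: dict[str, float] = field(default_factory=dict)


def _confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    t = np.asarray(y_true) == POSITIVE
    p = np.asarray(y_pred) == POSITIVE
    tp = int(np.sum(t & p)); fn = int(np.sum(t & ~p))
    fp = int(np.sum(~t & p)); tn = int(np.sum(~t & ~p))
    def _div(a, b):
        return a / b if b else np.nan
    return {
        "accuracy": _div(tp + tn, tp + tn + fp + fn),
        "precision": _div(tp, tp + fp),
        "recall": _div(tp, tp + fn),
        "specificity": _div(tn, tn + fp),
        "kappa": cohen_kappa_score(y_true, y_pred) if len(set(y_true)) > 1 else np.nan,
        "tp": tp, "fn": fn, "fp": fp, "tn": tn,
    }


def evaluate_on_test(model, test_fm: FeatureMatrix,
                     config: AnalysisConfig) -> PerformanceReport:
    """Test-set metrics: confusion-based rates for classification, RMSE for
    regression."""
    pred = model.predict(test_fm.X.to_numpy())
    if config.task == "classification":
        metrics = _confusion_metrics(test_fm.y.to_numpy(), pred)
    else:
        err = test_fm.y.to_numpy(float) - np.asarray(pred, float)
        metrics = {"rmse": float(np.sqrt(np.mean(err ** 2)))}
    return PerformanceReport(config, metrics)


def random_classifier_baseline(train_classes: pd.Series, test_classes: pd.Series,
                               reps: int = 1000, seed: int = 0) -> PerformanceReport:
    """Monte-Carlo random classifier: assigns the positive class with the
    training positive prevalence; metrics averaged over replicates."""
    rng = np.random.default_rng(seed)
    prev = float(np.mean(np.asarray(train_classes) == POSITIVE))
    y_true = np.asarray(test_classes)
    acc: dict[str, list[float]] = {}
    for _ in range(reps):
        pred = np.where(rng.random(len(y_true)) < prev, POSITIVE, "non_protected")
        for k, v in _confusion_metrics(y_true, pred).items():
            acc.setdefault(k, []).append(v)
    metrics = {k: float(np.nanmean(v)) for k, v in acc.items()}
    metrics["assignment_probability"] = prev
    return PerformanceReport(None, metrics)


def constant_mean_baseline(train_response: pd.Series | np.ndarray,
                           test_response: pd.Series | np.ndarray) -> float:
    """RMSE of predicting the training global mean for every test row."""
    mean = float(np.mean(np.asarray(train_response, float)))
    err = np.asarray(test_response, float) - mean
    return float(np.sqrt(np.mean(err ** 2)))


# -------------------------------------------------------------- importance


def relative_importance(model, fm: FeatureMatrix, config: AnalysisConfig,
                        seed: int = 0, n_repeats: int = 5) -> pd.Series:
    """Per-strain relative importance, scaled so the maximum is 100.

    Random forests use permutation importance on the training rows (for
    comparability with coefficient-based importance); elastic nets use the
    absolute standardized coefficients.
    """
    if config.algorithm == "RF":
        res = permutation_importance(model, fm.X.to_numpy(), fm.y.to_numpy(),
                                     n_repeats=n_repeats,
                                     random_state=seed, n_jobs=1)
        raw = np.maximum(res.importances_mean, 0.0)
    else:
        est = model.named_steps["glmnet"]
        coef = est.coef_
        raw = np.abs(coef[0] if coef.ndim > 1 else coef)
    top = raw.max()
    scaled = raw / top * 100.0 if top > 0 else raw
    return pd.Series(scaled, index=fm.X.columns, name="importance")


def median_importance(tables: list[pd.Series]) -> pd.Series:
    """Median importance across seeds (or across analyses), descending."""
    df = pd.concat(tables, axis=1)
    return df.median(axis=1).sort_values(ascending=False)


def threshold_sensitivity_refit(fm: FeatureMatrix, experiments: pd.Series,
                                thresholds_by_exp: list[dict[str, float]],
                                raw_response: pd.Series, config: AnalysisConfig,
                                params: dict, seed: int = 0) -> pd.DataFrame:
    """Refit the classifier after reclassifying with alternative thresholds.

    For each threshold set (one per experiment), training rows are
    reassigned, the model refitted with the given tuned parameters, and the
    importance ranks recorded.  Thresholds that empty one class are
    skipped.  Returns a table: threshold index x strain -> rank.
    """
    rows = {}
    for i, thr in enumerate(thresholds_by_exp):
        labels = np.array([
            "protected" if raw_response.loc[rid] < thr[experiments.loc[rid]] else "non_protected"
            for rid in fm.X.index])
        if len(set(labels)) < 2:
            continue
        refit_fm = FeatureMatrix(fm.X, pd.Series(labels, index=fm.X.index),
                                 fm.groups, experiments, fm.config_level,
                                 fm.config_features)
        model = fit_final(refit_fm, config, params, seed)
        imp = relative_importance(model, refit_fm, config, seed=seed)
        ranks = imp.rank(ascending=False, method="min")
        rows[i] = ranks
    return pd.DataFrame(rows).T
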