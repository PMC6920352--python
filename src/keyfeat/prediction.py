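"""Recurrence prediction and cohort statistics.

Covers the clinical end of the pipeline: the exclusion cascade, outcome
labelling against a time horizon (biochemical recurrence within 12 or 60
months), model fitting (lasso, ridge, RBF-SVM, grade-group logistic, and
feature+grade combinations), stratified 10-fold cross-validation with
fold-averaged AUC and a fold-variance 95% CI, external validation with a
rank-statistic CI, Nagelkerke pseudo-R² with a likelihood-ratio test, and
Fisher/Wilcoxon cohort characteristic tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

#: cascade order; the log records each patient's first matching reason
EXCLUSION_ORDER = ("neoadjuvant", "adjuvant", "missing_slides", "lost_followup")


# ---------------------------------------------------------------------------
# cohort operations
# ---------------------------------------------------------------------------

def apply_cohort_filter(cohort: pd.DataFrame
                        ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Apply the exclusion cascade and return the analysis set plus a log.

    Patients flagged in ``exclude_reason`` are removed in the canonical
    order (neoadjuvant, adjuvant, missing slides, lost to follow-up); each
    excluded id is logged once under its first matching reason.
    """
    log: dict[str, list[str]] = {}
    excluded: set[str] = set()
    reasons = cohort.get("exclude_reason")
    if reasons is None:
        return cohort.copy(), log
    reasons = reasons.fillna("")
    known = set(EXCLUSION_ORDER)
    extra = sorted(set(reasons.unique()) - known - {""})
    if extra:
        raise ValueError(f"unknown exclusion reasons: {extra}")
    for reason in EXCLUSION_ORDER:
        ids = cohort.loc[(reasons == reason)
                         & ~cohort["patient_id"].isin(excluded), "patient_id"]
        if len(ids):
            log[reason] = list(ids)
            excluded.update(ids)
    kept = cohort[~cohort["patient_id"].isin(excluded)].reset_index(drop=True)
    return kept, log


def define_label(recurrence_months: float, followup_months: float,
                 horizon_months: float) -> Optional[int]:
    """Outcome at a horizon: 1 recurred, 0 followed past the horizon, None censored."""
    if horizon_months <= 0:
        raise ValueError("horizon must be positive")
    rec = np.nan if recurrence_months is None else float(recurrence_months)
    fup = np.nan if followup_months is None else float(followup_months)
    if np.isnan(rec) and np.isnan(fup):
        raise ValueError("a record needs recurrence or follow-up months")
    if not np.isnan(rec) and rec <= horizon_months:
        return 1
    if not np.isnan(fup) and fup >= horizon_months:
        return 0
    return None  # censored before the horizon


def cohort_labels(cohort: pd.DataFrame, horizon_months: float) -> pd.Series:
    """Vectorised :func:`define_label`; NaN marks censored patients."""
    out = [define_label(r, f, horizon_months) for r, f in
           zip(cohort["recurrence_months"], cohort["followup_months"])]
    return pd.Series([np.nan if v is None else v for v in out],
                     index=cohort.index, name="label")


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def _default_lambda_grid() -> tuple[float, ...]:
    return tuple(float(c) for c in np.logspace(-2, 2, 7))


@dataclass
class ModelSpec:
    """One prediction model with its hyperparameter search grid.

    ``lasso``/``ridge`` are L1/L2-penalised logistic models on the weighted
    feature matrix, ``svm`` an RBF support vector machine scored by its
    decision values, ``gleason_logistic`` an unpenalised logistic model on
    the numeric ISUP grade group, and ``combined`` the penalised/SVM model
    on features with the grade appended as one extra column (the caller
    builds that matrix; see :func:`combine_features`).
    """

    model: str = "lasso"
    c_grid: tuple[float, ...] = field(default_factory=_default_lambda_grid)
    gamma_grid: tuple[float, ...] = ("scale", 0.01, 0.1, 1.0)
    base_model: str = "lasso"   # estimator used when model == "combined"
    inner_cv: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.c_grid:
            raise ValueError("hyperparameter grid must be non-empty")
        known = {"lasso", "ridge", "svm", "gleason_logistic", "combined"}
        if self.model not in known:
            raise ValueError(f"model must be one of {sorted(known)}")

    def build(self):
        """(estimator, grid): ready for inner-CV hyperparameter search."""
        name = self.base_model if self.model == "combined" else self.model
        if name in ("lasso", "ridge"):
            est = Pipeline([
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(
                    l1_ratio=1.0 if name == "lasso" else 0.0,
                    solver="liblinear", random_state=self.seed, max_iter=2000)),
            ])
            return est, {"clf__C": list(self.c_grid)}
        if name == "svm":
            est = Pipeline([
                ("scale", StandardScaler()),
                ("clf", SVC(kernel="rbf", random_state=self.seed)),
            ])
            return est, {"clf__C": list(self.c_grid),
                         "clf__gamma": list(self.gamma_grid)}
        # grade-group logistic: no penalty, no grid
        est = Pipeline([
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(C=np.inf, max_iter=2000)),
        ])
        return est, {}


def combine_features(features: pd.DataFrame, grades: Sequence[int]
                     ) -> pd.DataFrame:
    """Append the numeric ISUP grade group as one extra feature column."""
    grades = np.asarray(grades)
    if ((grades < 1) | (grades > 5)).any():
        raise ValueError("ISUP grade groups must lie in 1..5")
    out = features.copy()
    out["grade_group"] = grades
    return out


def fit_gleason_model(grades: Sequence[int], labels: Sequence[int],
                      seed: int = 0):
    """Unpenalised logistic model of outcome on the numeric grade group."""
    grades = np.asarray(grades, dtype=float).reshape(-1, 1)
    labels = np.asarray(labels)
    if ((grades < 1) | (grades > 5)).any():
        raise ValueError("ISUP grade groups must lie in 1..5")
    if len(np.unique(labels)) < 2:
        raise ValueError("outcome labels contain a single class")
    est, _ = ModelSpec(model="gleason_logistic", seed=seed).build()
    return est.fit(grades, labels)


def _model_scores(estimator, x: np.ndarray) -> np.ndarray:
    if hasattr(estimator, "predict_proba"):
        return estimator.predict_proba(x)[:, 1]
    return estimator.decision_function(x)


# ---------------------------------------------------------------------------
# evaluation statistics
# ---------------------------------------------------------------------------

def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalised Mann-Whitney rank statistic (ties averaged)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both outcome classes")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc ** 2)
           + (n_neg - 1) * (q2 - auc ** 2)) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def nagelkerke_r2(scores: np.ndarray, labels: np.ndarray
                  ) -> tuple[float, float]:
    """Nagelkerke pseudo-R² of a logistic refit of outcome on score.

    Returns ``(r2, p)`` where ``p`` is the likelihood-ratio test of the
    score model against the intercept-only null.  Defined this way the
    statistic applies uniformly to all scorers, including the SVM, which
    has no native likelihood.
    """
    labels = np.asarray(labels).astype(float)
    scores = np.asarray(scores, dtype=np.float64)
    n = len(labels)
    x = sm.add_constant(scores)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(labels, x).fit(disp=0, maxiter=200, method="bfgs")
            llf, llnull = fit.llf, fit.llnull
        except Exception:  # perfect separation: likelihood attains 0
            p1 = labels.mean()
            llnull = n * (p1 * np.log(p1) + (1 - p1) * np.log(1 - p1))
            llf = 0.0
    cox_snell = 1.0 - np.exp(2.0 * (llnull - llf) / n)
    max_cs = 1.0 - np.exp(2.0 * llnull / n)
    r2 = float(cox_snell / max_cs) if max_cs > 0 else 0.0
    lr = max(2.0 * (llf - llnull), 0.0)
    p = float(stats.chi2.sf(lr, df=1))
    return min(max(r2, 0.0), 1.0), p


def roc_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    from sklearn.metrics import roc_curve
    fpr, tpr, thr = roc_curve(labels, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


@dataclass
class EvalResult:
    """AUC with 95% CI, pseudo-R² with its test p-value, and ROC points."""

    auc: float
    ci_low: float
    ci_high: float
    pseudo_r2: float
    p_value: float
    roc: pd.DataFrame
    fold_aucs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ci_low = float(min(max(self.ci_low, 0.0), self.auc))
        self.ci_high = float(max(min(self.ci_high, 1.0), self.auc))

    def to_dict(self) -> dict:
        return {"auc": self.auc, "ci_low": self.ci_low, "ci_high": self.ci_high,
                "pseudo_r2": self.pseudo_r2, "p_value": self.p_value}


def evaluate(scores: np.ndarray, labels: np.ndarray) -> EvalResult:
    """Evaluate fixed scores: rank AUC, Hanley-McNeil CI, pseudo-R²."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(scores)) == 1:
        warnings.warn("constant scores: AUC is 0.5 by convention")
        auc = 0.5
    else:
        auc = rank_auc(scores, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    se = _hanley_mcneil_se(auc, n_pos, n_neg)
    r2, p = nagelkerke_r2(scores, labels)
    return EvalResult(auc, auc - 1.96 * se, auc + 1.96 * se, r2, p,
                      roc_points(scores, labels))


# ---------------------------------------------------------------------------
# cross-validation and external validation
# ---------------------------------------------------------------------------

def _as_matrix(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=np.float64)
    return np.asarray(features, dtype=np.float64)


def fold_composition(labels: Sequence[int], n_folds: int = 10, seed: int = 0
                     ) -> pd.DataFrame:
    """Positives/negatives per stratified test fold (CV bookkeeping)."""
    y = np.asarray(labels).astype(int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rows = [(f, int(y[te].sum()), int(len(te) - y[te].sum()))
            for f, (_, te) in enumerate(skf.split(np.zeros_like(y), y))]
    return pd.DataFrame(rows, columns=["fold", "n_positive", "n_negative"])


def _fit_with_search(spec: ModelSpec, x: np.ndarray, y: np.ndarray):
    est, grid = spec.build()
    if not grid:
        return clone(est).fit(x, y)
    # inner CV cannot use more folds than the rarer class has members
    inner = min(spec.inner_cv, int(np.bincount(y).min()))
    if inner < 2:
        fitted = clone(est)
        fitted.set_params(**{k: v[len(v) // 2] for k, v in grid.items()})
        return fitted.fit(x, y)
    search = GridSearchCV(
        est, grid, scoring="roc_auc",
        cv=StratifiedKFold(inner, shuffle=True, random_state=spec.seed),
        n_jobs=1,
    )
    return search.fit(x, y).best_estimator_


def crossval_predict(features, labels, spec: ModelSpec,
                     n_folds: int = 10, seed: int = 0) -> EvalResult:
    """Stratified outer 10-fold CV with inner-CV hyperparameter selection.

    Hyperparameters are re-chosen on each outer training set only (no
    leakage).  The reported AUC is the mean of the fold-wise test AUCs with
    a 95% CI from the fold-level variance; the pseudo-R² is computed on the
    pooled out-of-fold scores.
    """
    x = _as_matrix(features)
    y = np.asarray(labels).astype(int)
    n_pos = int(y.sum())
    if n_pos < n_folds or (len(y) - n_pos) < n_folds:
        raise ValueError(
            f"stratified {n_folds}-fold CV needs at least {n_folds} patients "
            "of each class; use fewer folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_aucs = []
    oof = np.empty(len(y))
    for train, test in skf.split(x, y):
        if len(np.unique(y[test])) < 2:
            raise ValueError(
                "a test fold lacks one class; stratify or use fewer folds"
            )
        fitted = _fit_with_search(spec, x[train], y[train])
        s = _model_scores(fitted, x[test])
        oof[test] = s
        fold_aucs.append(rank_auc(s, y[test]))
    fold_aucs = np.asarray(fold_aucs)
    auc = float(fold_aucs.mean())
    se = float(fold_aucs.std(ddof=1) / np.sqrt(n_folds))
    r2, p = nagelkerke_r2(oof, y)
    return EvalResult(auc, auc - 1.96 * se, auc + 1.96 * se, r2, p,
                      roc_points(oof, y), fold_aucs)


def external_validate(train_features, train_labels, test_features, test_labels,
                      spec: ModelSpec,
                      train_ids: Optional[Sequence[str]] = None,
                      test_ids: Optional[Sequence[str]] = None) -> EvalResult:
    """Fit once on the training cohort, evaluate on a disjoint test cohort.

    Hyperparameters are selected by inner CV on the training cohort only;
    the AUC CI uses the large-sample rank-statistic (Hanley-McNeil)
    variance on the test scores.
    """
    if train_ids is not None and test_ids is not None:
        overlap = set(train_ids) & set(test_ids)
        if overlap:
            raise ValueError(f"train/test patient ids overlap: {sorted(overlap)[:5]}")
    xtr, xte = _as_matrix(train_features), _as_matrix(test_features)
    ytr = np.asarray(train_labels).astype(int)
    yte = np.asarray(test_labels).astype(int)
    fitted = _fit_with_search(spec, xtr, ytr)
    return evaluate(_model_scores(fitted, xte), yte)


# ---------------------------------------------------------------------------
# cohort characteristic tables
# ---------------------------------------------------------------------------

def cohort_stats(cohort: pd.DataFrame, outcome: Sequence[int],
                 categorical: Sequence[str] = (),
                 continuous: Sequence[str] = ()) -> pd.DataFrame:
    """Fisher's exact / Wilcoxon rank-sum tests of cohort characteristics.

    ``categorical`` columns must be binary (two-sided Fisher's exact on the
    2x2 variable-by-outcome table); ``continuous`` columns get a two-sided
    Wilcoxon rank-sum test.  Tests on empty categories are skipped with a
    note.  The conventional 0.05 threshold is reported, not enforced.
    """
    y = np.asarray(outcome).astype(int)
    if min(y.sum(), len(y) - y.sum()) < 2:
        raise ValueError("need at least 2 patients per outcome group")
    rows = []
    for col in categorical:
        v = np.asarray(cohort[col]).astype(bool)
        table = np.array([
            [int((v & (y == 1)).sum()), int((~v & (y == 1)).sum())],
            [int((v & (y == 0)).sum()), int((~v & (y == 0)).sum())],
        ])
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            rows.append((col, "fisher_exact", np.nan, np.nan,
                         "skipped: empty category"))
            continue
        # rows = outcome groups, columns = variable; Fisher p is orientation-free
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append((col, "fisher_exact", np.nan, p, ""))
    for col in continuous:
        v = np.asarray(cohort[col], dtype=float)
        s, p = stats.ranksums(v[y == 1], v[y == 0])
        rows.append((col, "wilcoxon_rank_sum", s, p, ""))
    out = pd.DataFrame(rows, columns=["variable", "test", "statistic",
                                      "p_value", "note"])
    out["significant_at_0.05"] = out["p_value"] < 0.05
    return out
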