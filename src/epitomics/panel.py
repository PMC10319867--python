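"""Biomarker panel construction and evaluation.

Feature selection follows the screening protocol used for the 21-epitope lung
cancer panel: each mAb variable is compared between cases and controls with a
Mann-Whitney U test, effect direction and size are summarised as the ROC AUC
(which equals U / (n1*n2) under the midrank convention), p-values are adjusted
by Benjamini-Hochberg, and variables passing FDR < 0.01 enter the model.

The panel model itself is an unpenalized maximum-likelihood logistic
regression whose per-variable report mirrors the standard SPSS layout:
B (log-odds coefficient), S.E., Wald = (B/S.E.)^2 (chi-square, df = 1),
Sig. (p), and Exp(B) = exp(B) (odds ratio), plus a "Constant" intercept row.

Evaluation uses a stratified train/test split (default 70/30) with repeated
10-fold cross-validation on the training set only; the untouched test set is
scored once for the reported ROC. Subgroup ROC re-evaluates the fitted scores
within levels of a metadata field (sex, COPD grade, BMI class, ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold, cross_val_score, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

__all__ = [
    "ROCResult",
    "CVProtocol",
    "LogisticPanelModel",
    "mann_whitney",
    "roc_auc",
    "bh_fdr",
    "feature_stats",
    "select_features",
    "logistic_report_row",
    "fit_logistic_panel",
    "evaluate_protocol",
    "subgroup_roc",
]

EXACT_LIMIT = 400  # n1*n2 at or below which the exact U distribution is used


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    sensitivity: float   # at the Youden-optimal operating point
    specificity: float
    n_case: int
    n_control: int


@dataclass
class CVProtocol:
    """Split and cross-validation settings for panel evaluation."""

    train_frac: float = 0.70   # 0.66 for the library-wide models, 0.70 for the 21-mAb panel
    folds: int = 10
    repeats: int = 3
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if self.folds < 2 or self.repeats < 1:
            raise ValueError("need folds >= 2 and repeats >= 1")


def mann_whitney(case, control) -> tuple[float, float]:
    """Mann-Whitney U (midranks, oriented to the case group) and two-sided p.

    The exact null distribution is used for small problems (n1*n2 <= 400,
    no ties); otherwise the tie-corrected normal approximation.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([case, control])
    if np.all(pooled == pooled[0]):
        return case.size * control.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (case.size * control.size <= EXACT_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(case, control, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def roc_auc(scores, labels) -> ROCResult:
    """Empirical ROC with midrank (trapezoid) handling of tied scores.

    ``labels`` are 0/1 with 1 = case; the AUC equals the Mann-Whitney U of
    case scores versus control scores divided by n1*n2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_case = int(labels.sum())
    n_control = int(labels.size - n_case)
    if n_case == 0 or n_control == 0:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    youden = tpr - fpr
    k = int(np.argmax(youden))
    return ROCResult(
        fpr=fpr, tpr=tpr, auc=auc,
        sensitivity=float(tpr[k]), specificity=float(1.0 - fpr[k]),
        n_case=n_case, n_control=n_control,
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def feature_stats(features: pd.DataFrame, labels) -> pd.DataFrame:
    """Per-mAb U, p, AUC and BH q over a sample x mAb feature matrix."""
    labels = np.asarray(labels, dtype=int)
    rows = []
    for mab in features.columns:
        x = features[mab].to_numpy(dtype=float)
        keep = np.isfinite(x)
        case, ctrl = x[keep & (labels == 1)], x[keep & (labels == 0)]
        u, p = mann_whitney(case, ctrl)
        rows.append((mab, u, p, u / (case.size * ctrl.size)))
    out = pd.DataFrame(rows, columns=["mab_id", "U", "p", "auc"]).set_index("mab_id")
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def select_features(stats_table: pd.DataFrame, q_threshold: float = 0.01) -> list:
    """Variables with q < threshold, ranked by |AUC - 0.5| descending."""
    hits = stats_table[stats_table["q"] < q_threshold].copy()
    hits["effect"] = (hits["auc"] - 0.5).abs()
    return list(hits.sort_values(["effect", "q"], ascending=[False, True]).index)


def logistic_report_row(B: float, SE: float) -> dict:
    """SPSS-style derived statistics for one coefficient."""
    wald = (B / SE) ** 2
    return {
        "B": B,
        "SE": SE,
        "Wald": wald,
        "df": 1,
        "Sig": float(stats.chi2.sf(wald, df=1)),
        "ExpB": float(np.exp(B)),
    }


@dataclass
class LogisticPanelModel:
    table: pd.DataFrame          # rows: variables + "Constant"; SPSS column layout
    result: object               # statsmodels fit result
    separation_warning: bool = False
    variables: list = field(default_factory=list)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(features[self.variables].to_numpy(dtype=float), has_constant="add")
        return np.asarray(self.result.predict(X), dtype=float)


def fit_logistic_panel(features: pd.DataFrame, labels) -> LogisticPanelModel:
    """Unpenalized ML logistic fit with the SPSS-style coefficient report.

    SE comes from the inverse observed information; perfect separation is
    flagged (coefficients are still reported) rather than raised.
    """
    labels = np.asarray(labels, dtype=int)
    X = features.to_numpy(dtype=float)
    if np.any(~np.isfinite(X)):
        raise ValueError("feature matrix contains missing values; impute first")
    const_cols = [c for c, v in zip(features.columns, X.var(axis=0)) if v == 0]
    if const_cols:
        raise ValueError(f"constant feature columns: {const_cols}")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more samples than variables")
    Xc = sm.add_constant(X, has_constant="add")
    sep = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(labels, Xc).fit(disp=0, maxiter=200)
        except np.linalg.LinAlgError:
            # (quasi-)separation leaves the observed information singular for
            # Newton; fall back to BFGS and flag the fit
            res = sm.Logit(labels, Xc).fit(disp=0, method="bfgs", maxiter=500)
            sep = True
        sep = sep or any(
            "separation" in str(w.message).lower() or "convergence" in str(w.message).lower()
            for w in caught
        )
    names = ["Constant"] + list(features.columns)
    rows = []
    for name, b, se in zip(names, res.params, res.bse):
        rows.append({"variable": name, **logistic_report_row(float(b), float(se))})
    table = pd.DataFrame(rows).set_index("variable")
    # SPSS prints the constant last
    table = table.reindex(list(features.columns) + ["Constant"])
    return LogisticPanelModel(
        table=table, result=res, separation_warning=sep, variables=list(features.columns)
    )


def _make_model(kind: str, seed: int) -> Pipeline:
    models = {
        "logistic": LogisticRegression(C=np.inf, max_iter=2000),
        "svm": SVC(kernel="rbf", random_state=seed),
        "knn": KNeighborsClassifier(n_neighbors=5),
        "rf": RandomForestClassifier(n_estimators=200, random_state=seed),
    }
    if kind not in models:
        raise ValueError(f"unknown model kind {kind!r}; choose from {sorted(models)}")
    # mean imputation and scaling are fit inside each training fold only
    return Pipeline(
        [("impute", SimpleImputer(strategy="mean")),
         ("scale", StandardScaler()),
         ("model", models[kind])]
    )


def _scores(pipe: Pipeline, X) -> np.ndarray:
    model = pipe.named_steps["model"]
    if hasattr(model, "predict_proba") and model.__class__ is not SVC:
        return pipe.predict_proba(X)[:, 1]
    return pipe.decision_function(X)


def evaluate_protocol(
    features: pd.DataFrame, labels, protocol: CVProtocol, model_kind: str = "logistic"
) -> dict:
    """Train/test split + repeated k-fold CV on the training set only.

    Returns the per-fold CV AUCs (training-set internal validation), the
    fitted pipeline, and the single ROC evaluation on the held-out test set.
    """
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < protocol.folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples, fewer than {protocol.folds} folds; "
            "reduce the fold count"
        )
    X = features.to_numpy(dtype=float)
    idx = np.arange(labels.size)
    tr, te = train_test_split(
        idx,
        train_size=protocol.train_frac,
        random_state=protocol.seed,
        stratify=labels if protocol.stratified else None,
        shuffle=True,
    )
    pipe = _make_model(model_kind, protocol.seed)
    cv = RepeatedStratifiedKFold(
        n_splits=protocol.folds, n_repeats=protocol.repeats, random_state=protocol.seed
    )
    cv_aucs = cross_val_score(pipe, X[tr], labels[tr], cv=cv, scoring="roc_auc")
    pipe.fit(X[tr], labels[tr])
    test_scores = _scores(pipe, X[te])
    roc = roc_auc(test_scores, labels[te])
    return {
        "cv_aucs": np.asarray(cv_aucs, dtype=float),
        "cv_auc_mean": float(np.mean(cv_aucs)),
        "pipeline": pipe,
        "test_roc": roc,
        "train_idx": tr,
        "test_idx": te,
    }


def subgroup_roc(scores, labels, metadata: pd.DataFrame, column: str) -> dict:
    """Per-level ROC of precomputed model scores within a metadata field.

    Scores are computed once on all samples by the caller; each level of
    ``column`` is evaluated with its own cases versus its own controls.
    Levels lacking either class are reported as skipped, not evaluated.
    """
    if column not in metadata.columns:
        raise ValueError(f"metadata has no column {column!r}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    results: dict[str, ROCResult] = {}
    skipped = []
    for level, grp_idx in metadata.groupby(column, dropna=False).groups.items():
        pos = metadata.index.get_indexer(grp_idx)
        lv_labels = labels[pos]
        if lv_labels.min() == lv_labels.max():
            skipped.append(level)
            continue
        results[level] = roc_auc(scores[pos], lv_labels)
    return {"levels": results, "skipped": skipped}
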