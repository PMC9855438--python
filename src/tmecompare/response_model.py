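"""LASSO gene selection and multi-algorithm immunotherapy-response classifiers.

The modeling stage mirrors a common ICI-response workflow: L1-penalized
logistic regression (penalty chosen by internal cross-validation) selects a
gene subset from a candidate list; six classifiers — adaptive boosting
(ADB), a small fully-connected network (ANN), gradient boosting decision
trees (GBDT), random forest (RFC), extreme gradient boosting (XGB) and
k-nearest neighbors (KNN) — are then trained with stratified k-fold
cross-validation and evaluated by ROC AUC on a validation cohort and on
every two-cohort combination of test cohorts.  The "most matched"
combination rule reports the maximum combination AUC; because that choice
is made after seeing the AUCs it is optimistic, so the mean over
combinations and the full per-combination table are always reported
alongside it.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

ALGORITHMS = ("ADB", "ANN", "GBDT", "RFC", "XGB", "KNN")
RESPONSE_COL = "response"


def _xy(cohort: pd.DataFrame, genes: list[str]) -> tuple[np.ndarray, np.ndarray]:
    missing = [g for g in genes if g not in cohort.columns]
    if missing:
        raise KeyError(f"cohort lacks genes: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    X = cohort[genes].to_numpy(dtype=float)
    y = cohort[RESPONSE_COL].to_numpy(dtype=int)
    return X, y


def lasso_select(
    cohort: pd.DataFrame,
    candidate_genes: list[str],
    seed: int = 0,
    n_cs: int = 20,
    cv: int = 5,
) -> list[str]:
    """Genes with nonzero L1-logistic coefficients at the CV-chosen penalty."""
    X, y = _xy(cohort, candidate_genes)
    if len(np.unique(y)) < 2:
        raise ValueError("training cohort has a single response class")
    if min(np.bincount(y)) < 2:
        raise ValueError("need at least two samples per response class")
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    cv_folds = min(cv, int(min(np.bincount(y))))
    model = LogisticRegressionCV(
        l1_ratios=(1.0,),
        solver="liblinear",
        Cs=np.logspace(-2, 2, n_cs),
        cv=StratifiedKFold(cv_folds, shuffle=True, random_state=seed),
        scoring="roc_auc",
        max_iter=2000,
        random_state=seed,
        use_legacy_attributes=False,
    ).fit(Xs, y)
    coef = model.coef_.ravel()
    return [g for g, c in zip(candidate_genes, coef) if c != 0.0]


def _make_classifier(name: str, seed: int, ann_hidden: int = 16):
    base = {
        "ADB": lambda: AdaBoostClassifier(random_state=seed),
        "ANN": lambda: MLPClassifier(
            hidden_layer_sizes=(ann_hidden,), max_iter=3000, random_state=seed
        ),
        "GBDT": lambda: GradientBoostingClassifier(random_state=seed),
        "RFC": lambda: RandomForestClassifier(random_state=seed),
        "XGB": lambda: XGBClassifier(
            random_state=seed, eval_metric="logloss", verbosity=0
        ),
        "KNN": lambda: KNeighborsClassifier(),
    }
    if name not in base:
        raise ValueError(f"unknown algorithm {name!r}; supported: {ALGORITHMS}")
    return Pipeline([("scale", StandardScaler()), ("clf", base[name]())])


def _proba(model, X: np.ndarray) -> np.ndarray:
    return model.predict_proba(X)[:, 1]


def _used_genes(model: Pipeline, genes: list[str]) -> list[str]:
    """Genes the fitted model actually leans on (importance > 0 where defined)."""
    clf = model.named_steps["clf"]
    if hasattr(clf, "feature_importances_"):
        imp = np.asarray(clf.feature_importances_)
        return [g for g, v in zip(genes, imp) if v > 0]
    if hasattr(clf, "coef_"):
        coef = np.asarray(clf.coef_).ravel()
        return [g for g, v in zip(genes, coef) if v != 0]
    return list(genes)


def train_and_evaluate(
    cohorts: dict[str, pd.DataFrame],
    genes: list[str],
    algorithms: tuple[str, ...] = ALGORITHMS,
    k_folds: int = 5,
    seed: int = 0,
) -> dict:
    """Cross-validated training plus validation- and test-cohort AUCs.

    ``cohorts`` maps roles to frames with gene columns and a ``response``
    column; roles ``train`` and ``validation`` are required, every other
    role is a test cohort.  Per algorithm the report carries per-fold and
    pooled (out-of-fold) training AUC, validation AUC, the per-combination
    test table with its max ("most matched") and mean, the genes the model
    leans on, and whether score orientation was flipped.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be at least 2")
    if "train" not in cohorts or "validation" not in cohorts:
        raise ValueError("cohorts must include 'train' and 'validation' roles")
    test_roles = sorted(r for r in cohorts if r not in ("train", "validation"))
    Xtr, ytr = _xy(cohorts["train"], genes)
    Xva, yva = _xy(cohorts["validation"], genes)
    if len(np.unique(ytr)) < 2:
        raise ValueError("training cohort has a single response class")

    if k_folds <= min(np.bincount(ytr)):
        splitter = StratifiedKFold(k_folds, shuffle=True, random_state=seed)
    else:
        splitter = KFold(min(k_folds, len(ytr)), shuffle=True, random_state=seed)

    report: dict = {"k_folds": k_folds, "seed": seed, "genes": list(genes), "algorithms": {}}
    for name in algorithms:
        oof = np.full(len(ytr), np.nan)
        fold_aucs = []
        for tr_idx, te_idx in splitter.split(Xtr, ytr):
            if len(np.unique(ytr[tr_idx])) < 2:
                continue
            m = _make_classifier(name, seed).fit(Xtr[tr_idx], ytr[tr_idx])
            scores = _proba(m, Xtr[te_idx])
            oof[te_idx] = scores
            if len(np.unique(ytr[te_idx])) == 2:
                fold_aucs.append(float(roc_auc_score(ytr[te_idx], scores)))
        valid = ~np.isnan(oof)
        pooled = float(roc_auc_score(ytr[valid], oof[valid]))
        flipped = pooled < 0.5
        if flipped:
            pooled = 1.0 - pooled

        model = _make_classifier(name, seed).fit(Xtr, ytr)

        def auc_on(X, y):
            if len(np.unique(y)) < 2:
                return float("nan")
            a = float(roc_auc_score(y, _proba(model, X)))
            return 1.0 - a if flipped else a

        val_auc = auc_on(Xva, yva)
        combos = {}
        if len(test_roles) >= 2:
            for r1, r2 in itertools.combinations(test_roles, 2):
                both = pd.concat([cohorts[r1], cohorts[r2]])
                Xt, yt = _xy(both, genes)
                combos[f"{r1}+{r2}"] = auc_on(Xt, yt)
        elif test_roles:
            warnings.warn(
                "fewer than two test cohorts; reporting single-cohort AUC", stacklevel=2
            )
            r = test_roles[0]
            Xt, yt = _xy(cohorts[r], genes)
            combos[r] = auc_on(Xt, yt)
        combo_vals = [v for v in combos.values() if not np.isnan(v)]
        best = max(combos, key=lambda k: combos[k]) if combo_vals else None
        report["algorithms"][name] = {
            "fold_aucs": fold_aucs,
            "train_cv_auc": pooled,
            "validation_auc": val_auc,
            "test_combination_aucs": combos,
            "test_auc_most_matched": combos[best] if best else float("nan"),
            "most_matched_combination": best,
            "most_matched_is_optimistic": True,
            "test_auc_mean_combination": float(np.mean(combo_vals)) if combo_vals else float("nan"),
            "orientation_flipped": bool(flipped),
            "used_genes": _used_genes(model, list(genes)),
        }
    return report


def model_intersection(report: dict, algorithms: list[str] | set[str]) -> list[str]:
    """Genes common to the named algorithms' used-gene lists."""
    algorithms = list(algorithms)
    if len(algorithms) < 2:
        raise ValueError("name at least two algorithms")
    sets = []
    for name in algorithms:
        if name not in report["algorithms"]:
            raise KeyError(f"algorithm {name!r} absent from report")
        sets.append(set(report["algorithms"][name]["used_genes"]))
    return sorted(set.intersection(*sets))
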