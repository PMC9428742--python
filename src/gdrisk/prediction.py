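"""Cross-validated AUC harness for the clinical GD prediction model and its
PRS/METs augmentations.

A logistic classifier is evaluated by stratified k-fold cross-validation;
out-of-fold predicted probabilities are pooled and the AUC computed by the
rank (Mann-Whitney) statistic with tie correction.  The 95% CI comes from a
bootstrap over the pooled out-of-fold (score, label) pairs.  The classifier
is L2-regularised logistic regression (C = 1.0) by default — the choice of
classifier is an assumption of this harness, not a given, and alternatives
can be passed in.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler

from .cohort import Cohort


class Transform(str, enum.Enum):
    IDENTITY = "identity"
    STANDARDIZE = "standardize"
    ONEHOT = "onehot"


@dataclass(frozen=True)
class FeatureSpec:
    """A model feature: its name, the Participant field it reads, and the
    preprocessing transform."""

    name: str
    source: str
    transform: Transform = Transform.IDENTITY


@dataclass
class CvResult:
    mean_auc: float
    sd_auc: float
    ci_low: float
    ci_high: float
    n_folds: int
    n_boot: int
    model_name: str
    seed: int
    fold_aucs: list[float] = field(default_factory=list)


def baseline_features() -> list[FeatureSpec]:
    """Clinical features available to a nulliparous cohort at the first
    visit: age, BMI, race/ethnicity, family history of diabetes, PCOS,
    hypertension, and waist size (pregnancy history and HbA1c omitted)."""
    return [
        FeatureSpec("age", "age", Transform.STANDARDIZE),
        FeatureSpec("bmi", "bmi", Transform.STANDARDIZE),
        FeatureSpec("race_ethnicity", "race_ethnicity", Transform.ONEHOT),
        FeatureSpec("family_history", "family_history_diabetes"),
        FeatureSpec("pcos", "pcos"),
        FeatureSpec("hypertension", "hypertension"),
        FeatureSpec("waist", "waist", Transform.STANDARDIZE),
    ]


def with_prs(features: Sequence[FeatureSpec]) -> list[FeatureSpec]:
    return list(features) + [FeatureSpec("prs", "prs", Transform.STANDARDIZE)]


def with_mets(features: Sequence[FeatureSpec]) -> list[FeatureSpec]:
    return list(features) + [FeatureSpec("mets", "mets", Transform.STANDARDIZE)]


def _feature_frame(cohort: Cohort, features: Sequence[FeatureSpec]
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    df = cohort.to_frame()
    y = df["gd"].astype(bool).to_numpy()
    X = pd.DataFrame(index=df.index)
    for f in features:
        if f.source not in df.columns:
            raise ValueError(f"feature {f.name}: no Participant field {f.source!r}")
        col = df[f.source]
        if f.transform is Transform.ONEHOT:
            X[f.name] = col.astype("object").where(col.notna(), "missing")
        else:
            num = pd.to_numeric(col, errors="coerce")
            if num.isna().any():
                # median imputation with a missingness indicator
                X[f.name + "_missing"] = num.isna().astype(float)
                num = num.fillna(num.median())
            X[f.name] = num.astype(float)
    return X, y


def _build_pipeline(features: Sequence[FeatureSpec], X: pd.DataFrame, classifier):
    std = [f.name for f in features if f.transform is Transform.STANDARDIZE
           and f.name in X.columns]
    onehot = [f.name for f in features if f.transform is Transform.ONEHOT
              and f.name in X.columns]
    passthrough = [c for c in X.columns if c not in std + onehot]
    pre = ColumnTransformer(
        [("std", StandardScaler(), std),
         ("onehot", OneHotEncoder(handle_unknown="ignore"), onehot)],
        remainder="passthrough",
    )
    return Pipeline([("pre", pre), ("clf", classifier)])


def pooled_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the rank statistic (tie-corrected Mann-Whitney)."""
    return float(roc_auc_score(labels, scores))


def evaluate_model(
    cohort: Cohort,
    features: Sequence[FeatureSpec],
    n_folds: int = 10,
    n_boot: int = 100,
    seed: int = 0,
    classifier=None,
    model_name: str = "logistic",
) -> CvResult:
    """Stratified k-fold CV of a logistic classifier; pooled out-of-fold AUC
    with a bootstrap CI over the pooled (score, label) pairs.  Deterministic
    under ``seed``."""
    X, y = _feature_frame(cohort, features)
    n_cases = int(y.sum())
    if n_cases < n_folds or int((~y).sum()) < n_folds:
        raise ValueError(
            f"stratification impossible: need >= {n_folds} cases and controls, "
            f"got {n_cases}/{int((~y).sum())}"
        )
    if classifier is None:
        classifier = LogisticRegression(C=1.0, max_iter=1000)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    fold_aucs = []
    for train, test in skf.split(X, y):
        pipe = _build_pipeline(features, X, classifier)
        pipe.fit(X.iloc[train], y[train])
        p = pipe.predict_proba(X.iloc[test])[:, 1]
        oof[test] = p
        fold_aucs.append(pooled_auc(p, y[test]))
    mean_auc = pooled_auc(oof, y)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n = len(y)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.all() or not yb.any():
            boots[b] = np.nan
            continue
        boots[b] = pooled_auc(oof[idx], yb)
    boots = boots[~np.isnan(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return CvResult(
        mean_auc=mean_auc,
        sd_auc=float(np.std(fold_aucs, ddof=1)),
        ci_low=float(min(lo, mean_auc)),
        ci_high=float(max(hi, mean_auc)),
        n_folds=n_folds,
        n_boot=n_boot,
        model_name=model_name,
        seed=seed,
        fold_aucs=[float(a) for a in fold_aucs],
    )
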