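"""Multiclass risk classifiers on trait features, with permutation importance.

Random forest and gradient boosting learners are fitted on a one-hot
encoded trait matrix labelled with quartile risk levels.  Feature
importance is model-agnostic: the drop in predictive accuracy when one
feature's values are shuffled across rows, averaged over repeats ("mean
drop in performance").  Evaluation follows the usual multiclass metrics —
accuracy, Cohen's kappa, per-class precision/recall/F1 and the confusion
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, train_test_split
from xgboost import XGBClassifier

from .errors import ConfigurationError, ValidationError
from .importance_ranking import RISK_LEVELS
from .survey_io import CATEGORICAL_VOCAB, CONTINUOUS_TRAITS, TraitTable


@dataclass
class FeatureMatrix:
    """Encoded design matrix: continuous traits first, then one-hot columns."""

    X: pd.DataFrame
    y: pd.Series  # risk level, ordered categorical over RISK_LEVELS
    groups: dict[str, list[str]]  # categorical variable -> its one-hot columns

    def __len__(self) -> int:
        return len(self.X)


@dataclass
class ClassifierReport:
    accuracy: float
    kappa: float
    per_class: pd.DataFrame  # precision/recall/f1/support per class
    confusion: pd.DataFrame  # rows = true class, cols = predicted

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "per_class": self.per_class.to_dict(orient="index"),
            "confusion": self.confusion.to_numpy().tolist(),
            "classes": list(self.confusion.index),
        }


def encode_features(traits: TraitTable, labels: pd.DataFrame) -> FeatureMatrix:
    """One-hot encode categorical traits and attach risk labels.

    ``labels`` is a risk ranking with species and risk_level columns; every
    labelled species must have a trait row.  Column order is deterministic:
    continuous traits first, then one-hot indicators in alphabetical order.
    """
    lab = labels.set_index("species")["risk_level"] if "species" in labels.columns else labels["risk_level"]
    missing = [s for s in lab.index if s not in traits.data.index]
    if missing:
        raise ValidationError(f"species without trait rows: {missing[:5]}")
    df = traits.data.loc[lab.index]

    cont = [c for c in CONTINUOUS_TRAITS if c in df.columns]
    X = df[cont].astype(float).copy()
    groups: dict[str, list[str]] = {}
    for var in sorted(CATEGORICAL_VOCAB):
        if var not in df.columns:
            continue
        levels = traits.vocab[var]
        bad = set(df[var]) - set(levels)
        if bad:
            raise ValidationError(f"{var}: levels {sorted(bad)} not in vocabulary")
        cols = []
        for lvl in sorted(levels):
            col = f"{var}={lvl}"
            X[col] = (df[var] == lvl).astype(float)
            cols.append(col)
        groups[var] = cols
    if X.isna().any().any():
        raise ValidationError("missing values in encoded feature matrix")
    y = pd.Series(
        pd.Categorical(lab.to_numpy(), categories=RISK_LEVELS, ordered=True),
        index=lab.index,
        name="risk_level",
    )
    return FeatureMatrix(X=X, y=y, groups=groups)


def expand_to_observations(
    fm: FeatureMatrix, survey_records: pd.DataFrame
) -> FeatureMatrix:
    """Replicate each species' feature row once per site where it occurs.

    Mirrors observation-level training designs; note that rows of the same
    species then appear in both train and test splits, which leaks species
    identity and inflates test metrics.
    """
    occ = survey_records.loc[survey_records["count"] > 0, ["site", "species"]].drop_duplicates()
    occ = occ[occ["species"].isin(fm.X.index)]
    idx = occ["species"].to_numpy()
    X = fm.X.loc[idx].reset_index(drop=True)
    y = fm.y.loc[idx].reset_index(drop=True)
    return FeatureMatrix(X=X, y=y, groups=fm.groups)


def split_train_test(
    fm: FeatureMatrix, fraction: float = 0.7, seed: int = 0
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Stratified train/test split (falls back to unstratified if a class
    has fewer than 2 members)."""
    if not 0 < fraction < 1:
        raise ConfigurationError(f"fraction must be in (0,1), got {fraction}")
    strat = fm.y
    if fm.y.value_counts().min() < 2:
        import warnings

        warnings.warn("a class has <2 members; splitting without stratification")
        strat = None
    Xtr, Xte, ytr, yte = train_test_split(
        fm.X, fm.y, train_size=fraction, random_state=seed, stratify=strat
    )
    return (
        FeatureMatrix(X=Xtr, y=ytr, groups=fm.groups),
        FeatureMatrix(X=Xte, y=yte, groups=fm.groups),
    )


_FOREST_GRID = {"n_estimators": [200, 500], "max_features": ["sqrt", 0.33]}
_BOOST_GRID = {"learning_rate": [0.1, 0.3], "max_depth": [3, 6]}


class _FittedModel:
    """Thin predictor wrapper holding the label encoding."""

    def __init__(self, est, classes: list[str], columns: list[str]):
        self.est = est
        self.classes = classes
        self.columns = columns

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        codes = self.est.predict(X[self.columns].to_numpy())
        return np.asarray(self.classes, dtype=object)[codes]

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.est.predict_proba(X[self.columns].to_numpy())


def fit_classifier(
    train: FeatureMatrix,
    algorithm: str = "forest",
    hyperparams: dict | None = None,
    seed: int = 0,
    cv_folds: int = 5,
) -> _FittedModel:
    """Fit a forest or boosting classifier; small CV grid when no
    hyperparameters are given."""
    if len(train) == 0:
        raise ValidationError("empty training set")
    classes = list(RISK_LEVELS)
    y_codes = pd.Categorical(train.y, categories=classes).codes
    present = np.unique(y_codes)
    # map to a dense code space (xgboost requires 0..k-1)
    remap = {c: i for i, c in enumerate(present)}
    y_dense = np.array([remap[c] for c in y_codes])
    dense_classes = [classes[c] for c in present]
    Xa = train.X.to_numpy()

    if algorithm == "forest":
        base = RandomForestClassifier(random_state=seed)
        grid = _FOREST_GRID
    elif algorithm == "boosting":
        base = XGBClassifier(
            random_state=seed,
            n_estimators=200,
            n_jobs=1,
            verbosity=0,
            objective="multi:softprob" if len(present) > 2 else "binary:logistic",
        )
        grid = _BOOST_GRID
    else:
        raise ConfigurationError(
            f"unknown algorithm {algorithm!r}; expected 'forest' or 'boosting'"
        )

    if hyperparams:
        base.set_params(**hyperparams)
        est = base
    else:
        counts = np.bincount(y_dense)
        folds = min(cv_folds, counts.min()) if counts.min() >= 2 else 2
        if len(np.unique(y_dense)) < 2 or folds < 2:
            est = base
        else:
            est = GridSearchCV(base, grid, cv=folds, n_jobs=1)
    est.fit(Xa, y_dense)
    if isinstance(est, GridSearchCV):
        est = est.best_estimator_
    return _FittedModel(est, dense_classes, list(train.X.columns))


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> pd.DataFrame:
    classes = list(RISK_LEVELS)
    mat = np.zeros((4, 4), dtype=int)
    pos = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        mat[pos[t], pos[p]] += 1
    return pd.DataFrame(mat, index=classes, columns=classes)


def report_from_confusion(confusion: pd.DataFrame) -> ClassifierReport:
    """Compute accuracy, kappa, and per-class precision/recall/F1 from a
    confusion matrix (rows = truth).  Classes absent from the test set get
    NaN metrics rather than zeros."""
    m = confusion.to_numpy(dtype=float)
    n = m.sum()
    acc = np.trace(m) / n
    row = m.sum(axis=1)
    col = m.sum(axis=0)
    p_e = float((row * col).sum()) / n**2
    kappa = (acc - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0

    rows = {}
    for i, cls in enumerate(confusion.index):
        tp = m[i, i]
        support = row[i]
        precision = tp / col[i] if col[i] > 0 else np.nan
        recall = tp / support if support > 0 else np.nan
        if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
            f1 = np.nan if (support == 0) else 0.0
        else:
            f1 = 2 * precision * recall / (precision + recall)
        rows[cls] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": int(support),
        }
    return ClassifierReport(
        accuracy=float(acc),
        kappa=float(kappa),
        per_class=pd.DataFrame(rows).T,
        confusion=confusion,
    )


def evaluate(model: _FittedModel, test: FeatureMatrix) -> ClassifierReport:
    """Evaluate a fitted model on held-out data."""
    if len(test) == 0:
        raise ValidationError("empty test set")
    y_pred = model.predict(test.X)
    y_true = np.asarray(test.y, dtype=object)
    return report_from_confusion(_confusion(y_true, y_pred))


def permutation_importance(
    model: _FittedModel,
    data: FeatureMatrix,
    n_repeats: int = 50,
    seed: int = 0,
    grouping: str = "column",
) -> pd.DataFrame:
    """Mean drop in accuracy when each feature (or one-hot group) is shuffled.

    The baseline accuracy is computed once; each feature is then permuted
    across rows ``n_repeats`` times with independent draws and the metric
    recomputed.  Returns a table with mean_drop, sd_drop, n_repeats per
    feature, sorted by mean_drop descending.
    """
    if n_repeats < 2:
        raise ConfigurationError("n_repeats must be >= 2")
    if grouping == "column":
        units = {c: [c] for c in data.X.columns}
    elif grouping == "variable":
        grouped = {v: cols for v, cols in data.groups.items()}
        in_groups = {c for cols in grouped.values() for c in cols}
        units = {c: [c] for c in data.X.columns if c not in in_groups}
        units.update(grouped)
    else:
        raise ConfigurationError(
            f"unknown grouping {grouping!r}; expected 'column' or 'variable'"
        )
    rng = np.random.default_rng(seed)
    y_true = np.asarray(data.y, dtype=object)
    baseline = float(np.mean(model.predict(data.X) == y_true))
    n = len(data)
    rows = []
    for name, cols in units.items():
        drops = np.empty(n_repeats)
        Xp = data.X.copy()
        for r in range(n_repeats):
            perm = rng.permutation(n)
            Xp[cols] = data.X[cols].to_numpy()[perm]
            acc = float(np.mean(model.predict(Xp) == y_true))
            drops[r] = baseline - acc
        rows.append(
            {
                "feature": name,
                "mean_drop": drops.mean(),
                "sd_drop": drops.std(ddof=1),
                "n_repeats": n_repeats,
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["mean_drop", "feature"], ascending=[False, True], kind="mergesort"
    )
    out.attrs["baseline"] = baseline
    return out.reset_index(drop=True)


def importance_concordance(a: pd.DataFrame, b: pd.DataFrame, k: int = 2) -> dict:
    """Rank agreement between two importance tables: top-k set equality and
    Spearman rank correlation of mean_drop."""
    fa, fb = set(a["feature"]), set(b["feature"])
    if fa != fb:
        raise ValidationError(f"feature sets differ: {sorted(fa ^ fb)[:5]}")
    merged = a.set_index("feature")["mean_drop"].to_frame("a").join(
        b.set_index("feature")["mean_drop"].rename("b")
    )
    rho = spearmanr(merged["a"], merged["b"]).statistic
    top_a = set(a.nlargest(k, "mean_drop")["feature"])
    top_b = set(b.nlargest(k, "mean_drop")["feature"])
    return {
        "spearman_rho": float(rho),
        "top_k_equal": top_a == top_b,
        "top_k_a": sorted(top_a),
        "top_k_b": sorted(top_b),
    }
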