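"""Trait-weighted presence-background species distribution model.

Species presence points are weighted by a composite TraitScore (min-max
normalised functional traits, default SLA only) and fitted against
uniformly sampled background points with a penalized weighted logistic
regression — the "infinitely-weighted" logistic approximation of the
presence/background point-process model that MaxEnt solves.  Presences
carry their trait weight; background points carry a large fixed weight
(default 100) so the fit targets the relative occurrence intensity.
Features are linear + quadratic terms of each environmental layer; the L1
penalty acts on features standardised by their weighted standard
deviation, which is equivalent to scaling the penalty per feature.
Predictions use the cloglog transform by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from .errors import ConfigurationError, ValidationError
from .survey_io import EnvStack, TraitTable

WEIGHT_FLOOR = 1e-3


@dataclass
class TraitScore:
    scores: pd.Series  # species -> composite in [0, 1]
    components: pd.DataFrame  # species x trait, min-max normalised


@dataclass
class WeightedPresenceSet:
    presences: pd.DataFrame  # x, y, species, weight + env feature columns
    background: pd.DataFrame  # x, y, weight=1 + env feature columns
    layer_names: list[str]


@dataclass
class MaxentFit:
    coef: pd.Series  # per feature (env linear + quadratic terms)
    intercept: float
    penalty: float
    background_weight: float
    transform: str
    feature_means: pd.Series
    feature_sds: pd.Series
    layer_names: list[str]


def trait_score(traits: TraitTable, selected: list[str] | None = None) -> TraitScore:
    """Composite TraitScore: per-trait min-max to [0, 1], then the mean.

    Default selection is SLA alone (the trait tracking the climate
    gradient); any continuous traits may be combined.
    """
    selected = selected or ["sla"]
    comp = {}
    for t in selected:
        if t not in traits.data.columns:
            raise ValidationError(f"trait {t!r} not in trait table")
        v = traits.data[t].to_numpy(dtype=float)
        lo, hi = v.min(), v.max()
        if hi == lo:
            raise ValidationError(
                f"trait {t!r} is constant across species; min-max normalisation undefined"
            )
        comp[t] = (v - lo) / (hi - lo)
    components = pd.DataFrame(comp, index=traits.data.index)
    return TraitScore(scores=components.mean(axis=1), components=components)


def build_presence_set(
    occurrences: pd.DataFrame,
    scores: TraitScore,
    env: EnvStack,
    background_ratio: float = 10.0,
    seed: int = 0,
) -> WeightedPresenceSet:
    """Attach trait weights and env features to presences; sample background.

    Presences on masked/out-of-grid cells are dropped with a warning.
    Weights are the species' TraitScore floored at 1e-3 so minimum-score
    species still contribute.  Background points are drawn uniformly from
    unmasked cells (without replacement when enough cells exist), jittered
    to cell centers, at ``background_ratio`` times the presence count.
    """
    if occurrences.empty:
        raise ValidationError("no presence points given")
    missing = set(occurrences["species"]) - set(scores.scores.index)
    if missing:
        raise ValidationError(f"species without trait scores: {sorted(missing)[:5]}")
    feats = env.extract(occurrences["x"].to_numpy(), occurrences["y"].to_numpy())
    ok = ~feats.isna().any(axis=1)
    if not ok.any():
        raise ValidationError("all presence points fall on masked or out-of-grid cells")
    if (~ok).any():
        import warnings

        warnings.warn(f"dropping {(~ok).sum()} presence point(s) off the valid grid")
    pres = occurrences.loc[ok.to_numpy()].reset_index(drop=True)
    feats = feats.loc[ok.to_numpy()].reset_index(drop=True)
    w = scores.scores.loc[pres["species"]].to_numpy()
    pres = pd.concat([pres, feats], axis=1)
    pres["weight"] = np.maximum(w, WEIGHT_FLOOR)

    n_bg = int(round(background_ratio * len(pres)))
    rng = np.random.default_rng(seed)
    nrows, ncols = env.shape
    rows, cols = np.nonzero(~env.nodata_mask)
    replace = n_bg > len(rows)
    pick = rng.choice(len(rows), size=n_bg, replace=replace)
    r, c = rows[pick], cols[pick]
    xy = np.array(
        [env.transform.cell_center(ri, ci, nrows) for ri, ci in zip(r, c)]
    )
    bg = pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1]})
    bg_feats = pd.DataFrame(
        {name: env.layers[name][r, c].astype(float) for name in env.layer_names}
    )
    bg = pd.concat([bg, bg_feats], axis=1)
    bg["weight"] = 1.0
    return WeightedPresenceSet(
        presences=pres, background=bg, layer_names=env.layer_names
    )


def _design(df: pd.DataFrame, layer_names: list[str], quadratic: bool) -> pd.DataFrame:
    X = df[layer_names].copy()
    if quadratic:
        for name in layer_names:
            X[f"{name}^2"] = df[name] ** 2
    return X


def fit_weighted_maxent(
    data: WeightedPresenceSet,
    penalty: float = 0.01,
    background_weight: float = 100.0,
    quadratic: bool = True,
    transform: str = "cloglog",
    max_iter: int = 10_000,
) -> MaxentFit:
    """Fit the weighted penalized logistic approximation to MaxEnt.

    Maximises the case-weighted log-likelihood of presence (1) vs
    background (0) minus an L1 penalty; presence rows carry their trait
    weight, background rows ``background_weight``.  Standardising features
    by their weighted SD makes the uniform penalty act per-feature scaled.
    """
    if transform not in {"cloglog", "logistic", "raw"}:
        raise ConfigurationError(f"unknown output transform {transform!r}")
    if len(data.presences) == 0 or len(data.background) == 0:
        raise ValidationError("need at least one presence and one background point")
    Xp = _design(data.presences, data.layer_names, quadratic)
    Xb = _design(data.background, data.layer_names, quadratic)
    X = pd.concat([Xp, Xb], ignore_index=True)
    if not np.isfinite(X.to_numpy()).all():
        raise ValidationError("non-finite environmental feature values")
    y = np.r_[np.ones(len(Xp)), np.zeros(len(Xb))]
    w = np.r_[
        data.presences["weight"].to_numpy(),
        background_weight * data.background["weight"].to_numpy(),
    ]

    wsum = w.sum()
    mean = (w @ X.to_numpy()) / wsum
    sd = np.sqrt((w @ (X.to_numpy() - mean) ** 2) / wsum)
    sd[sd == 0] = 1.0
    Xs = (X.to_numpy() - mean) / sd

    # liblinear minimises C * sum_i w_i * logloss + ||beta||_1
    C = 1.0 / penalty if penalty > 0 else 1e10
    clf = LogisticRegression(
        l1_ratio=1.0,
        C=C,
        solver="liblinear",
        fit_intercept=True,
        max_iter=max_iter,
        tol=1e-8,
        random_state=0,
    )
    clf.fit(Xs, y, sample_weight=w)
    beta_std = clf.coef_.ravel()
    beta = beta_std / sd
    intercept = float(clf.intercept_[0] - np.sum(beta_std * mean / sd))
    return MaxentFit(
        coef=pd.Series(beta, index=X.columns),
        intercept=intercept,
        penalty=penalty,
        background_weight=background_weight,
        transform=transform,
        feature_means=pd.Series(mean, index=X.columns),
        feature_sds=pd.Series(sd, index=X.columns),
        layer_names=data.layer_names,
    )


def _linear_predictor(fit: MaxentFit, features: pd.DataFrame) -> np.ndarray:
    eta = np.full(len(features), fit.intercept)
    for name, b in fit.coef.items():
        if name.endswith("^2"):
            base = name[:-2]
            eta += b * features[base].to_numpy() ** 2
        else:
            eta += b * features[name].to_numpy()
    return eta


def _transform(eta: np.ndarray, kind: str) -> np.ndarray:
    if kind == "cloglog":
        return 1.0 - np.exp(-np.exp(eta))
    if kind == "logistic":
        return 1.0 / (1.0 + np.exp(-eta))
    return eta


def predict_points(fit: MaxentFit, features: pd.DataFrame) -> np.ndarray:
    """Suitability at arbitrary points given their env feature columns."""
    missing = [n for n in fit.layer_names if n not in features.columns]
    if missing:
        raise ValidationError(f"missing env layer column(s): {missing}")
    return _transform(_linear_predictor(fit, features), fit.transform)


def predict_surface(fit: MaxentFit, env: EnvStack) -> np.ndarray:
    """Per-cell suitability grid; masked cells become NaN."""
    missing = [n for n in fit.layer_names if n not in env.layers]
    if missing:
        raise ValidationError(f"env stack missing layer(s): {missing}")
    flat = pd.DataFrame({n: env.layers[n].ravel().astype(float) for n in fit.layer_names})
    out = predict_points(fit, flat).reshape(env.shape).astype(float)
    out[env.nodata_mask] = np.nan
    return out


def split_presence_background(
    data: WeightedPresenceSet, fraction: float = 0.7, seed: int = 0
) -> tuple[WeightedPresenceSet, WeightedPresenceSet]:
    """70/30-style split applied to presences and background separately."""
    if not 0 < fraction < 1:
        raise ConfigurationError(f"fraction must be in (0,1), got {fraction}")
    rng = np.random.default_rng(seed)

    def _split(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        n = len(df)
        n_train = int(round(fraction * n))
        perm = rng.permutation(n)
        return (
            df.iloc[perm[:n_train]].reset_index(drop=True),
            df.iloc[perm[n_train:]].reset_index(drop=True),
        )

    ptr, pte = _split(data.presences)
    btr, bte = _split(data.background)
    return (
        WeightedPresenceSet(ptr, btr, data.layer_names),
        WeightedPresenceSet(pte, bte, data.layer_names),
    )


@dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_auc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> RocResult:
    """ROC curve and AUC via the rank (Mann-Whitney) formulation.

    AUC is the probability a random positive outscores a random negative,
    ties counted 1/2; the curve is a sweep over the unique scores.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both score sets must be nonempty")
    combined = np.r_[pos, neg]
    ranks = rankdata(combined)  # average ranks handle ties
    auc = (ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2) / (
        len(pos) * len(neg)
    )
    thresholds = np.r_[np.inf, np.unique(combined)[::-1]]
    tpr = np.array([(pos >= t).mean() for t in thresholds])
    fpr = np.array([(neg >= t).mean() for t in thresholds])
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=float(auc))
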