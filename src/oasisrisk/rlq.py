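"""Three-table RLQ ordination linking environment, composition and traits.

Given a site x environment table R, a site x species abundance table L and
a species x trait table Q, the abundance table is converted to relative
frequencies P = L / L.sum(); its row and column sums give site weights r
and species weights c.  R's columns are centred and scaled under r, Q's
under c, and the fourth-corner cross matrix

    Z[j, k] = sum_i sum_s P[i, s] * R~[i, j] * Q~[s, k]

is decomposed by SVD.  Left/right singular vectors give canonical scores
of environmental variables and traits; the squared singular values sum to
the total co-inertia ||Z||_F^2.  Traits scoring high and positive on axis
1 are the ones tracking the main environmental gradient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RLQResult:
    singular_values: np.ndarray  # descending, length = n_axes kept
    env_scores: pd.DataFrame  # env variable x axis
    trait_scores: pd.DataFrame  # trait x axis
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    total_coinertia: float
    row_weights: pd.Series
    col_weights: pd.Series


def _weighted_standardize(M: np.ndarray, w: np.ndarray, scale: bool = True) -> np.ndarray:
    """Centre (and optionally scale to unit variance) columns under weights w."""
    mean = w @ M
    C = M - mean
    if scale:
        sd = np.sqrt(w @ C**2)
        sd[sd == 0] = 1.0
        C = C / sd
    return C


def fourth_corner_matrix(
    R: pd.DataFrame, L: pd.DataFrame, Q: pd.DataFrame, scale: bool = True
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Weighted trait x environment cross matrix Z plus row/col weights."""
    P = L.to_numpy(dtype=float)
    total = P.sum()
    if total <= 0:
        raise ValidationError("abundance table has non-positive grand total")
    P = P / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    Rt = _weighted_standardize(R.to_numpy(dtype=float), r, scale=scale)
    Qt = _weighted_standardize(Q.to_numpy(dtype=float), c, scale=scale)
    Z = Rt.T @ P @ Qt  # env x trait
    return pd.DataFrame(Z, index=R.columns, columns=Q.columns), r, c


def rlq_fit(
    R: pd.DataFrame,
    L: pd.DataFrame,
    Q: pd.DataFrame,
    n_axes: int = 2,
    scale: bool = True,
) -> RLQResult:
    """Fit the RLQ ordination.

    Empty rows (sites) or columns (species) of L are dropped with a
    warning; R and Q must be indexed compatibly with L.  Axis signs are
    fixed so the env variable with the largest |score| on each axis is
    positive.
    """
    if L.shape[0] != R.shape[0]:
        raise ValidationError(
            f"R has {R.shape[0]} rows but L has {L.shape[0]} sites"
        )
    if L.shape[1] != Q.shape[0]:
        raise ValidationError(
            f"Q has {Q.shape[0]} rows but L has {L.shape[1]} species"
        )
    if (L.to_numpy() < 0).any():
        raise ValidationError("abundances must be non-negative")
    row_sum = L.sum(axis=1)
    col_sum = L.sum(axis=0)
    if (row_sum == 0).any():
        dropped = list(L.index[row_sum == 0])
        logger.warning("dropping %d empty sites: %s", len(dropped), dropped[:5])
        keep = row_sum > 0
        L, R = L.loc[keep], R.loc[keep]
    if (col_sum == 0).any():
        dropped = list(L.columns[col_sum == 0])
        logger.warning("dropping %d empty species: %s", len(dropped), dropped[:5])
        keep = col_sum > 0
        L, Q = L.loc[:, keep], Q.loc[keep]
    if L.to_numpy().sum() <= 0:
        raise ValidationError("abundance table is all zero")

    Zdf, r, c = fourth_corner_matrix(R, L, Q, scale=scale)
    Z = Zdf.to_numpy()
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    k = min(n_axes, rank) if rank else min(n_axes, len(s))
    U, s, V = U[:, :k], s[:k], Vt[:k].T

    # deterministic sign: largest-|loading| env variable positive per axis
    for a in range(k):
        j = int(np.argmax(np.abs(U[:, a])))
        if U[j, a] < 0:
            U[:, a] *= -1
            V[:, a] *= -1

    axes = [f"axis{a + 1}" for a in range(k)]
    env_scores = pd.DataFrame(U * s, index=R.columns, columns=axes)
    trait_scores = pd.DataFrame(V * s, index=Q.columns, columns=axes)
    Rt = _weighted_standardize(R.to_numpy(dtype=float), r, scale=scale)
    Qt = _weighted_standardize(Q.to_numpy(dtype=float), c, scale=scale)
    site_scores = pd.DataFrame(Rt @ U, index=R.index, columns=axes)
    species_scores = pd.DataFrame(Qt @ V, index=Q.index, columns=axes)
    return RLQResult(
        singular_values=s,
        env_scores=env_scores,
        trait_scores=trait_scores,
        site_scores=site_scores,
        species_scores=species_scores,
        total_coinertia=float(np.sum(Z**2)),
        row_weights=pd.Series(r, index=R.index),
        col_weights=pd.Series(c, index=L.columns),
    )


def permutation_test(
    R: pd.DataFrame,
    L: pd.DataFrame,
    Q: pd.DataFrame,
    n_permutations: int = 199,
    seed: int = 0,
    scale: bool = True,
) -> dict:
    """Site-permutation test of the total co-inertia.

    Rows of R are shuffled relative to L; the p-value is the fraction of
    permuted statistics >= the observed one (with the +1 convention).
    """
    rng = np.random.default_rng(seed)
    obs = rlq_fit(R, L, Q, scale=scale).total_coinertia
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(len(R))
        Rp = pd.DataFrame(R.to_numpy()[perm], index=R.index, columns=R.columns)
        null[b] = rlq_fit(Rp, L, Q, scale=scale).total_coinertia
    p = (1 + np.sum(null >= obs)) / (n_permutations + 1)
    return {"observed": obs, "null": null, "p_value": float(p)}


def tables_from_points(
    presences: pd.DataFrame,
    env,
    traits,
    trait_cols: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Build R/L/Q tables by binning presence points onto the env grid.

    Each occupied grid cell becomes one "site": L counts points per cell
    and species, R takes the cell's env values, Q the species' continuous
    traits (log-transformed, as trait distributions are right-skewed).
    """
    from .survey_io import CONTINUOUS_TRAITS

    trait_cols = trait_cols or [c for c in CONTINUOUS_TRAITS if c in traits.data.columns]
    nrows, _ = env.shape
    col = np.floor(
        (presences["x"].to_numpy() - env.transform.xllcorner) / env.transform.cellsize
    ).astype(int)
    row = nrows - 1 - np.floor(
        (presences["y"].to_numpy() - env.transform.yllcorner) / env.transform.cellsize
    ).astype(int)
    cell = row * env.shape[1] + col
    counts = (
        pd.DataFrame({"cell": cell, "species": presences["species"].to_numpy(), "n": 1})
        .groupby(["cell", "species"])["n"]
        .sum()
        .unstack(fill_value=0)
    )
    r_idx = counts.index.to_numpy() // env.shape[1]
    c_idx = counts.index.to_numpy() % env.shape[1]
    R = pd.DataFrame(
        {name: env.layers[name][r_idx, c_idx] for name in env.layer_names},
        index=counts.index,
    )
    Q = np.log(traits.data.loc[counts.columns, trait_cols].astype(float))
    return R, counts, Q


def select_traits(
    result: RLQResult, threshold: float | None = None
) -> pd.DataFrame:
    """Traits responding to the main gradient (axis 1).

    Default rule: traits whose |axis-1 score| is in the top quartile AND
    whose score is positive, ordered by |score| descending.  With an
    explicit ``threshold``, all positive-axis-1 traits with |score| >
    threshold are returned.
    """
    s1 = result.trait_scores["axis1"]
    absolute = s1.abs()
    if threshold is None:
        if (absolute == 0).all():
            return pd.DataFrame({"trait": [], "axis1_score": []})
        threshold = float(absolute.quantile(0.75))
        chosen = s1[(absolute >= threshold) & (s1 > 0)]
    else:
        chosen = s1[(absolute > threshold) & (s1 > 0)]
    chosen = chosen.loc[chosen.abs().sort_values(ascending=False).index]
    return pd.DataFrame({"trait": chosen.index, "axis1_score": chosen.to_numpy()})
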