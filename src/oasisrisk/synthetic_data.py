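"""Synthetic oasis-community generator with known ground truth.

Emulates the study design this pipeline targets: a nested vegetation survey
(sites x plots x quadrats, default 3 plots of 5 quadrats each), a species
pool whose latent invasiveness is driven by specific leaf area (SLA) and
seed hundred-grain weight, and a landscape where high-SLA species track the
main environmental gradient.  Every generator is a pure function of
(config, seed) so recovery tests have an exact oracle.

The generative model, stage by stage:

* traits — SLA ~ LogNormal(5.0, 0.4) cm^2/g, hundred-grain weight ~
  LogNormal(-1, 1) g; latent invasiveness
  eta = beta_sla * z(log SLA) + beta_seed * z(log HGW) + small categorical
  effects + N(0, 0.3).
* survey — per quadrat, a species is present with probability
  logistic(occupancy_intercept + occupancy_slope * eta); conditional counts
  are 1 + NegBin with mean exp(0.5 + 0.6 * eta); cover is count times a
  per-species leafiness, rescaled so each quadrat's total cover <= 1.
* environment — layer env1 is a smooth west-east gradient plus noise;
  further layers are seeded smoothed Gaussian random fields.
* presences — cell intensity per species
  lambda(cell) ∝ exp((base + alpha * s_sla) * env1 - 0.5 * env2^2) where
  s_sla is the species' standardised log SLA: every alien species shares a
  baseline affinity for the resource-rich end of the gradient (the oasis),
  and SLA modulates its strength, so high-SLA species concentrate most
  strongly there.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .importance_ranking import RISK_LEVELS, risk_class_sizes
from .survey_io import (
    CATEGORICAL_VOCAB,
    EnvStack,
    GridTransform,
    SurveyTable,
    TraitTable,
)

_FAMILIES = [
    "Asteraceae", "Amaranthaceae", "Fabaceae", "Poaceae", "Brassicaceae",
    "Solanaceae", "Euphorbiaceae", "Malvaceae", "Convolvulaceae",
    "Chenopodiaceae", "Onagraceae", "Apiaceae", "Caryophyllaceae",
    "Cucurbitaceae", "Lamiaceae", "Oxalidaceae", "Plantaginaceae",
    "Verbenaceae",
]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic community; defaults define the study conditions.

    ``n_sites`` defaults to a scaled-down 120 (full-scale surveys use 611
    sites); the nested design of 3 plots x 5 quadrats per site is kept.
    """

    n_species: int = 62
    n_sites: int = 120
    plots_per_site: int = 3
    quadrats_per_plot: int = 5
    beta_sla: float = 1.0
    beta_seed: float = 0.8
    occupancy_intercept: float = -2.5
    occupancy_slope: float = 1.5
    abundance_dispersion: float = 1.0
    nx: int = 60
    ny: int = 40
    n_env_layers: int = 3
    env_noise_sd: float = 0.3
    mask_fraction: float = 0.0
    niche_alpha: float = 2.0
    niche_baseline: float = 2.0
    presences_per_species: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 8:
            raise ValueError("need at least 8 species")
        if min(self.n_sites, self.plots_per_site, self.quadrats_per_plot) < 1:
            raise ValueError("survey design counts must be positive")
        if self.abundance_dispersion <= 0:
            raise ValueError("abundance dispersion must be positive")
        if min(self.nx, self.ny) < 10:
            raise ValueError("grid must be at least 10 x 10")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted parameters recovery tests check against."""

    eta: pd.Series  # latent invasiveness per species
    true_risk: pd.Series  # quartile class of eta (High/Medium/Low/No)
    niche: pd.DataFrame  # per-species env1 coefficient; shared env2 curvature
    leafiness: pd.Series = field(default=None)


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=0)


def gen_traits(config: GeneratorConfig) -> tuple[TraitTable, GroundTruth]:
    """Draw the species pool: traits, taxonomy, and latent invasiveness."""
    rng = np.random.default_rng(config.seed)
    n = config.n_species
    ids = [f"sp{i + 1:03d}" for i in range(n)]

    log_sla = rng.normal(5.0, 0.4, n)
    log_hgw = rng.normal(-1.0, 1.0, n)
    height = np.exp(rng.normal(4.0, 0.5, n))
    flowering = np.exp(rng.normal(1.0, 0.4, n))

    # Skewed taxonomy: a few large families, many monotypic ones.
    fam_weights = 1.0 / np.arange(1, len(_FAMILIES) + 1) ** 1.2
    fam_weights /= fam_weights.sum()
    families = rng.choice(_FAMILIES, size=n, p=fam_weights)
    genera = []
    for i, fam in enumerate(families):
        g_idx = rng.integers(1, 4)  # few genera per family
        genera.append(f"{fam[:-4]}genus{g_idx}")

    cats = {}
    for col, levels in CATEGORICAL_VOCAB.items():
        w = rng.dirichlet(np.ones(len(levels)) * 2.0)
        cats[col] = rng.choice(levels, size=n, p=w)

    cat_effect = (
        0.2 * np.isin(cats["fruit_type"], ["capsule", "utricle"]).astype(float)
        + 0.2 * (cats["dispersal_mode"] == "gravity").astype(float)
    )
    eta = (
        config.beta_sla * _zscore(log_sla)
        + config.beta_seed * _zscore(log_hgw)
        + cat_effect
        + rng.normal(0.0, 0.3, n)
    )

    df = pd.DataFrame(
        {
            "family": families,
            "genus": genera,
            "sla": np.exp(log_sla),
            "height": height,
            "hundred_grain_weight": np.exp(log_hgw),
            "flowering_duration": flowering,
            **cats,
        },
        index=pd.Index(ids, name="species"),
    )

    order = np.argsort(-eta, kind="stable")
    sizes = risk_class_sizes(n)
    levels = np.empty(n, dtype=object)
    start = 0
    for lvl, k in zip(RISK_LEVELS, sizes):
        levels[order[start : start + k]] = lvl
        start += k
    eta_s = pd.Series(eta, index=df.index, name="eta")
    truth = GroundTruth(
        eta=eta_s,
        true_risk=pd.Series(levels, index=df.index, name="true_risk"),
        niche=pd.DataFrame(
            {
                "env1_coef": config.niche_baseline
                + config.niche_alpha * _zscore(log_sla)
            },
            index=df.index,
        ),
        leafiness=pd.Series(np.exp(rng.normal(-3.0, 0.3, n)), index=df.index),
    )
    return TraitTable(data=df), truth


def _minmax(v: np.ndarray) -> np.ndarray:
    return (v - v.min()) / (v.max() - v.min())


def gen_survey(
    traits: TraitTable, truth: GroundTruth, config: GeneratorConfig
) -> SurveyTable:
    """Simulate the nested quadrat survey from the planted invasiveness."""
    rng = np.random.default_rng(config.seed + 1)
    n_sp = len(traits)
    eta = truth.eta.to_numpy()
    leaf = truth.leafiness.to_numpy()
    n_quads = config.n_sites * config.plots_per_site * config.quadrats_per_plot

    p_pres = expit(config.occupancy_intercept + config.occupancy_slope * eta)
    mu = np.exp(0.5 + 0.6 * eta)
    k = config.abundance_dispersion
    p_nb = k / (k + mu)

    present = rng.random((n_quads, n_sp)) < p_pres  # quadrat x species
    counts = np.zeros((n_quads, n_sp), dtype=int)
    idx = np.nonzero(present)
    counts[idx] = 1 + rng.negative_binomial(k, p_nb[idx[1]])

    raw_cover = counts * leaf[None, :]
    totals = raw_cover.sum(axis=1)
    scale = np.ones(n_quads)
    over = totals > 1.0
    scale[over] = 0.95 / totals[over]
    cover = raw_cover * scale[:, None]

    q_idx, s_idx = idx
    site = q_idx // (config.plots_per_site * config.quadrats_per_plot)
    plot = (q_idx // config.quadrats_per_plot) % config.plots_per_site
    quad = q_idx % config.quadrats_per_plot
    records = pd.DataFrame(
        {
            "site": [f"S{v + 1:04d}" for v in site],
            "plot": [f"P{v + 1}" for v in plot],
            "quadrat": [f"Q{v + 1}" for v in quad],
            "species": [traits.species[j] for j in s_idx],
            "count": counts[q_idx, s_idx],
            "cover": cover[q_idx, s_idx],
        }
    )
    return SurveyTable(
        records=records,
        design=(config.n_sites, config.plots_per_site, config.quadrats_per_plot),
    )


def gen_env(config: GeneratorConfig) -> EnvStack:
    """Synthetic environmental layers: one west-east gradient + random fields."""
    rng = np.random.default_rng(config.seed + 2)
    ny, nx = config.ny, config.nx
    layers: dict[str, np.ndarray] = {}

    grad = np.tile(np.linspace(-1.5, 1.5, nx), (ny, 1))
    env1 = grad + rng.normal(0.0, config.env_noise_sd, (ny, nx))
    layers["env1"] = _zscore(env1.ravel()).reshape(ny, nx)

    sigma = min(nx, ny) / 8.0
    for i in range(1, config.n_env_layers):
        field_ = gaussian_filter(rng.normal(0.0, 1.0, (ny, nx)), sigma)
        layers[f"env{i + 1}"] = _zscore(field_.ravel()).reshape(ny, nx)

    mask = np.zeros((ny, nx), dtype=bool)
    if config.mask_fraction > 0:
        mask = rng.random((ny, nx)) < config.mask_fraction
    transform = GridTransform(xllcorner=0.0, yllcorner=0.0, cellsize=1.0)
    return EnvStack(layers=layers, transform=transform, nodata_mask=mask)


def gen_presences(
    traits: TraitTable,
    truth: GroundTruth,
    env: EnvStack,
    config: GeneratorConfig,
    species: list[str] | None = None,
) -> pd.DataFrame:
    """Sample presence points from each species' planted niche intensity."""
    rng = np.random.default_rng(config.seed + 3)
    ny, nx = env.shape
    env1 = env.layers["env1"]
    env2 = env.layers.get("env2", np.zeros_like(env1))
    ok = ~env.nodata_mask
    rows, cols = np.nonzero(ok)
    if species is None:
        species = traits.species
    frames = []
    for sp in species:
        a = truth.niche.loc[sp, "env1_coef"]
        log_lam = a * env1[rows, cols] - 0.5 * env2[rows, cols] ** 2
        lam = np.exp(log_lam - log_lam.max())
        lam /= lam.sum()
        pick = rng.choice(len(rows), size=config.presences_per_species, p=lam)
        r, c = rows[pick], cols[pick]
        # uniform jitter within the chosen cell
        x = env.transform.xllcorner + (c + rng.random(len(c))) * env.transform.cellsize
        y = env.transform.yllcorner + (ny - r - rng.random(len(r))) * env.transform.cellsize
        frames.append(pd.DataFrame({"x": x, "y": y, "species": sp}))
    return pd.concat(frames, ignore_index=True)
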