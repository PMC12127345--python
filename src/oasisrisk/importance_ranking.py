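"""Importance-value ranking of alien species and quartile risk classification.

The importance value (IV) of a species is the unweighted mean of its
relative density, relative frequency and relative cover, each expressed in
percent:

    IV = (RD + RF + RC) / 3
    RD = 100 * (individuals of the species / all individuals)
    RF = 100 * (sampling units where the species occurs / all units)
    RC = 100 * (summed cover of the species / summed cover of all species)

Ranked species are partitioned into four quartile risk levels
(High / Medium / Low / No): the first two classes take floor(n/4) species
each and the remainder is split between Low and No (Low receiving the
larger half when the remainder is odd), so n = 62 yields 15/15/16/16.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UndefinedStatisticError, ValidationError
from .survey_io import SurveyTable, TraitTable

RISK_LEVELS = ("High", "Medium", "Low", "No")

FREQUENCY_UNITS = {
    "quadrat": ["site", "plot", "quadrat"],
    "plot": ["site", "plot"],
}


def _unit_keys(unit: str) -> list[str]:
    try:
        return FREQUENCY_UNITS[unit]
    except KeyError:
        raise ConfigurationError(
            f"unknown frequency unit {unit!r}; expected one of {sorted(FREQUENCY_UNITS)}"
        ) from None


def relative_density(species: str, survey: SurveyTable) -> float:
    """Percent of all recorded individuals belonging to ``species``."""
    total = survey.records["count"].sum()
    if total <= 0:
        raise UndefinedStatisticError("survey has no individuals; relative density undefined")
    mine = survey.records.loc[survey.records["species"] == species, "count"].sum()
    return 100.0 * mine / total


def relative_frequency(species: str, survey: SurveyTable, unit: str = "quadrat") -> float:
    """Percent of sampling units in which ``species`` occurs (count > 0)."""
    keys = _unit_keys(unit)
    if unit == "quadrat" and survey.design is not None:
        n_units = survey.n_units
    else:
        n_units = survey.records.groupby(keys).ngroups
        if survey.design is not None and unit == "plot":
            n_units = survey.design[0] * survey.design[1]
    if n_units == 0:
        raise UndefinedStatisticError("survey has no sampling units")
    present = survey.records[(survey.records["species"] == species) & (survey.records["count"] > 0)]
    occupied = present.groupby(keys).ngroups
    return 100.0 * occupied / n_units


def relative_cover(species: str, survey: SurveyTable) -> float:
    """Percent of total plant cover contributed by ``species``."""
    total = survey.records["cover"].sum()
    if total <= 0:
        raise UndefinedStatisticError("survey has zero total cover; relative cover undefined")
    mine = survey.records.loc[survey.records["species"] == species, "cover"].sum()
    return 100.0 * mine / total


def importance_values(survey: SurveyTable, unit: str = "quadrat") -> pd.DataFrame:
    """Per-species RD/RF/RC and importance value, ranked descending.

    Ties in importance value are broken by species id (lexicographic), so
    ranks form a strict permutation of 1..n.
    """
    if survey.records.empty:
        raise UndefinedStatisticError("empty survey")
    keys = _unit_keys(unit)
    rec = survey.records
    total_count = rec["count"].sum()
    total_cover = rec["cover"].sum()
    if total_count <= 0:
        raise UndefinedStatisticError("survey has no individuals")
    if total_cover <= 0:
        raise UndefinedStatisticError("survey has zero total cover")
    if unit == "quadrat" and survey.design is not None:
        n_units = survey.n_units
    elif unit == "plot" and survey.design is not None:
        n_units = survey.design[0] * survey.design[1]
    else:
        n_units = rec.groupby(keys).ngroups

    by_sp = rec.groupby("species")
    rd = 100.0 * by_sp["count"].sum() / total_count
    rc = 100.0 * by_sp["cover"].sum() / total_cover
    present = rec[rec["count"] > 0]
    occ = present.groupby("species").apply(
        lambda g: g.groupby(keys).ngroups, include_groups=False
    )
    rf = 100.0 * occ.reindex(rd.index, fill_value=0) / n_units

    out = pd.DataFrame(
        {
            "species": rd.index,
            "rel_density": rd.to_numpy(),
            "rel_frequency": rf.to_numpy(),
            "rel_cover": rc.to_numpy(),
        }
    )
    out["importance_value"] = (
        out["rel_density"] + out["rel_frequency"] + out["rel_cover"]
    ) / 3.0
    out = out.sort_values(
        ["importance_value", "species"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def risk_class_sizes(n: int) -> tuple[int, int, int, int]:
    """Sizes of the High/Medium/Low/No classes for n ranked species."""
    if n < 4:
        raise ValidationError(f"need at least 4 species to form quartile classes, got {n}")
    q = n // 4
    rem = n - 2 * q
    low = math.ceil(rem / 2)
    return q, q, low, rem - low


def classify_risk(ranking: pd.DataFrame) -> pd.DataFrame:
    """Assign quartile risk levels to a ranked importance-value table."""
    n = len(ranking)
    sizes = risk_class_sizes(n)
    levels: list[str] = []
    for lvl, k in zip(RISK_LEVELS, sizes):
        levels.extend([lvl] * k)
    out = ranking.sort_values("rank").reset_index(drop=True).copy()
    out["risk_level"] = pd.Categorical(levels, categories=RISK_LEVELS, ordered=True)
    return out


def rank_and_classify(survey: SurveyTable, unit: str = "quadrat") -> pd.DataFrame:
    """Full ranking: importance values plus quartile risk levels."""
    return classify_risk(importance_values(survey, unit=unit))


def class_summary(ranking: pd.DataFrame) -> pd.DataFrame:
    """Within-class arithmetic means of RD/RF/RC and importance value."""
    if "risk_level" not in ranking.columns:
        raise ValidationError("risk levels not assigned; run classify_risk first")
    cols = ["rel_density", "rel_frequency", "rel_cover", "importance_value"]
    summary = (
        ranking.groupby("risk_level", observed=False)[cols]
        .mean()
        .reindex(list(RISK_LEVELS))
    )
    summary.insert(0, "n_species", ranking.groupby("risk_level", observed=False).size())
    return summary


def taxon_tally(traits: TraitTable) -> dict[str, pd.DataFrame | int | float]:
    """Counts and percentages of species per family and genus.

    Percentages are reported to one decimal; also counts monotypic
    (single-species) families and genera.
    """
    df = traits.data
    total = len(df)
    fam = df.groupby("family").size().sort_values(ascending=False)
    gen = df.groupby("genus").size().sort_values(ascending=False)

    def _table(counts: pd.Series, label: str) -> pd.DataFrame:
        return pd.DataFrame(
            {
                label: counts.index,
                "n_species": counts.to_numpy(),
                "percent": np.round(100.0 * counts.to_numpy() / total, 1),
            }
        )

    mono_gen = int((gen == 1).sum())
    mono_fam = int((fam == 1).sum())
    return {
        "families": _table(fam, "family"),
        "genera": _table(gen, "genus"),
        "n_species": total,
        "n_families": len(fam),
        "n_genera": len(gen),
        "monotypic_families": mono_fam,
        "monotypic_genera": mono_gen,
        "monotypic_family_percent": round(100.0 * mono_fam / total, 1),
        "monotypic_genus_percent": round(100.0 * mono_gen / total, 1),
    }
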