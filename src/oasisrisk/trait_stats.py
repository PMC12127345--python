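"""Comparison of continuous traits across risk levels.

Cascade: per-group Shapiro-Wilk normality and Levene variance-homogeneity
checks choose between one-way ANOVA (with Tukey HSD post hoc) and
Kruskal-Wallis (with pairwise Wilcoxon rank-sum tests, Holm-corrected).
Group differences are summarised as a compact letter display: groups that
share a letter are not significantly different at alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError


@dataclass
class GroupComparison:
    trait: str
    groups: pd.DataFrame  # n, mean, sd per group
    normality_p: dict[str, float]
    homogeneity_p: float
    test_used: str  # "anova" | "kruskal_wallis"
    test_statistic: float
    p_value: float
    pairwise_p: pd.DataFrame  # symmetric matrix of adjusted pairwise p-values
    letters: dict[str, str]


def compact_letter_display(
    group_names: list[str], pairwise_p: pd.DataFrame, alpha: float = 0.05
) -> dict[str, str]:
    """Insert-absorb compact letter display.

    Builds letter columns so that two groups share a letter iff their
    pairwise comparison is NOT significant at alpha.  Groups are processed
    in the given order, which fixes the lettering deterministically.
    """
    # start with one column containing all groups
    columns: list[set[str]] = [set(group_names)]
    for i, g1 in enumerate(group_names):
        for g2 in group_names[i + 1 :]:
            p = pairwise_p.loc[g1, g2]
            if np.isnan(p) or p > alpha:
                continue
            # significant pair: no column may contain both
            for col in list(columns):
                if g1 in col and g2 in col:
                    columns.remove(col)
                    c1 = col - {g2}
                    c2 = col - {g1}
                    # absorb: drop new columns that are subsets of existing ones
                    for c in (c1, c2):
                        if not any(c <= other for other in columns):
                            columns.append(c)
    # assign letters in group order for stable output
    columns.sort(key=lambda c: min(group_names.index(g) for g in c))
    letters = {g: "" for g in group_names}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter, col in zip(alphabet, columns):
        for g in group_names:
            if g in col:
                letters[g] += letter
    return letters


def compare_trait_by_risk(
    values: pd.Series,
    risk: pd.Series,
    alpha: float = 0.05,
    trait_name: str | None = None,
) -> GroupComparison:
    """Run the assumption-checking cascade for one trait across risk groups."""
    trait_name = trait_name or (values.name or "trait")
    df = pd.DataFrame({"value": values.to_numpy(dtype=float), "group": risk.to_numpy()})
    group_names = [g for g in pd.unique(df["group"])]
    samples = {g: df.loc[df["group"] == g, "value"].to_numpy() for g in group_names}
    small = [g for g, v in samples.items() if len(v) < 2]
    if small:
        raise AnalysisError(f"group(s) with fewer than 2 values: {small}")
    if len(group_names) < 2:
        raise AnalysisError("need at least 2 groups")

    normality_p = {g: float(stats.shapiro(v).pvalue) for g, v in samples.items()}
    homogeneity_p = float(stats.levene(*samples.values()).pvalue)
    parametric = all(p > alpha for p in normality_p.values()) and homogeneity_p > alpha

    names = list(group_names)
    pmat = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    if parametric:
        stat, p = stats.f_oneway(*samples.values())
        test_used = "anova"
        tk = stats.tukey_hsd(*[samples[g] for g in names])
        for i in range(len(names)):
            for j in range(len(names)):
                if i != j:
                    pmat.iloc[i, j] = tk.pvalue[i, j]
    else:
        stat, p = stats.kruskal(*samples.values())
        test_used = "kruskal_wallis"
        pairs = [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))]
        raw = [
            stats.mannwhitneyu(
                samples[names[i]], samples[names[j]], alternative="two-sided"
            ).pvalue
            for i, j in pairs
        ]
        adj = multipletests(raw, method="holm")[1]
        for (i, j), padj in zip(pairs, adj):
            pmat.iloc[i, j] = padj
            pmat.iloc[j, i] = padj

    # letters only meaningful when the omnibus test rejects; otherwise all share "a"
    if p > alpha:
        letters = {g: "a" for g in names}
    else:
        letters = compact_letter_display(names, pmat, alpha=alpha)

    groups = pd.DataFrame(
        {
            "n": {g: len(v) for g, v in samples.items()},
            "mean": {g: float(np.mean(v)) for g, v in samples.items()},
            "sd": {g: float(np.std(v, ddof=1)) for g, v in samples.items()},
        }
    )
    return GroupComparison(
        trait=trait_name,
        groups=groups,
        normality_p=normality_p,
        homogeneity_p=homogeneity_p,
        test_used=test_used,
        test_statistic=float(stat),
        p_value=float(p),
        pairwise_p=pmat,
        letters=letters,
    )


def comparisons_table(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Flatten GroupComparison results into one tidy table (one row per
    trait x group)."""
    rows = []
    for c in comparisons:
        for g in c.groups.index:
            rows.append(
                {
                    "trait": c.trait,
                    "group": g,
                    "n": c.groups.loc[g, "n"],
                    "mean": c.groups.loc[g, "mean"],
                    "sd": c.groups.loc[g, "sd"],
                    "test_used": c.test_used,
                    "test_statistic": c.test_statistic,
                    "p_value": c.p_value,
                    "letters": c.letters[g],
                }
            )
    return pd.DataFrame(rows)
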