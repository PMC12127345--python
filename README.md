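# oasisrisk

Trait-based invasion-risk analysis for alien plants in oasis
agroecosystems. The package is aimed at invasion ecologists and
agricultural land managers who survey alien plant communities with nested
quadrat designs and want to (1) rank species by how dominant they already
are, (2) learn which functional traits predict that dominance, and
(3) project where the riskiest species could spread.

## What it computes

**Importance-value risk ranking.** For each alien species the importance
value is the unweighted mean of three percentages computed over the whole
survey:

```
IV = (RD + RF + RC) / 3
RD = 100 · (individuals of the species / all individuals)
RF = 100 · (sampling units occupied / all sampling units)
RC = 100 · (cover of the species / total cover)
```

Ranked species are partitioned into four quartile risk levels
(High / Medium / Low / No): floor(n/4) species in each of the top two
classes, the remainder split between Low and No. At n = 62 this yields
classes of 15/15/16/16 species.

**Trait → risk classification.** Random-forest and gradient-boosting
classifiers are fitted to a one-hot-encoded matrix of functional traits
(SLA, plant height, seed hundred-grain weight, flowering duration, plus
categorical life form, mating system, pollination mode, fruit type,
dispersal mode) against the four risk levels, with accuracy, Cohen's κ,
per-class precision/recall/F1 and confusion matrices on a stratified 70/30
split. Feature importance is model-agnostic: the mean drop in accuracy
when one feature is permuted across rows.

**Trait statistics.** Each key trait is compared across risk levels with
an assumption-checking cascade (Shapiro–Wilk + Levene → one-way ANOVA +
Tukey HSD, otherwise Kruskal–Wallis + Holm-corrected pairwise rank tests),
summarised as a compact letter display.

**RLQ ordination.** A three-table ordination links environment (R),
site × species composition (L) and traits (Q) through the SVD of the
weighted fourth-corner cross matrix `Z = R̃ᵀ P Q̃`; traits scoring high and
positive on axis 1 are the ones tracking the main environmental gradient.

**Trait-weighted MaxEnt-style SDM.** Presence points of high-risk species
are weighted by a min–max-normalised composite TraitScore (default: SLA)
and fitted against 10× uniformly sampled background points by an
L1-penalized weighted logistic regression — the infinitely-weighted
logistic approximation of the presence/background point-process model —
yielding a cloglog suitability surface and held-out ROC/AUC.

**Synthetic communities.** A generator plants known ground truth — a
611-site (scaled to 120 by default) × 3-plot × 5-quadrat survey whose
latent invasiveness is driven by SLA and seed mass, and a landscape where
high-SLA species track the main gradient — so every stage is testable
end-to-end without field data.

## Worked example

```python
from oasisrisk import synthetic_data as syn, importance_ranking as ir

gc = syn.GeneratorConfig(seed=1)            # 62 species, 120 sites
traits, truth = syn.gen_traits(gc)
survey = syn.gen_survey(traits, truth, gc)
ranking = ir.rank_and_classify(survey)
print(ir.class_summary(ranking).round(3))
```

```
            n_species  rel_density  rel_frequency  rel_cover  importance_value
risk_level
High               15        5.132         40.737      5.063            16.977
Medium             15        1.155         15.496      1.172             5.941
Low                16        0.315          5.608      0.354             2.092
No                 16        0.040          1.069      0.051             0.387
```

Fifteen species land in the High class and dominate the community: on
average they occupy 41% of quadrats and carry a mean importance value of
17.0, versus 0.4 for the No-risk class. Continuing with the same
realisation, the RLQ step puts SLA far ahead of the other traits on the
main environmental axis (axis-1 canonical scores 0.79 vs |≤ 0.12| for
height, seed weight and flowering duration), and the SLA-weighted
distribution model for the 15 high-risk species reaches a held-out AUC of
0.942 — the model separates presences from background strongly, as
expected when the planted niche is trait-mediated.

The same analyses are available from the shell:

```
oasisrisk simulate --seed 1 --outdir demo/
oasisrisk rank --survey demo/survey.csv --traits demo/traits.csv --out ranking.csv
oasisrisk run --config pipeline.yaml --outdir out/   # full pipeline
```

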