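# Methods

This note documents the models implemented in `oasisrisk`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not demonstrate.

## Importance-value ranking

Relative density and relative cover are survey-wide shares (they sum to
100% over species by construction); relative frequency is the share of
sampling units occupied and does not sum to anything in particular. The
sampling unit for frequency defaults to the quadrat — the survey design's
atomic unit (e.g. 611 sites × 3 plots × 5 quadrats = 9,165 units) — with a
plot-level option. Surveys spanning multiple years are pooled before the
computation.

Ties in importance value are broken by species id so ranks are a strict
permutation; this only matters for degenerate (usually synthetic) tables.

**Quartile partition.** "Top 25% = High risk" is ambiguous when n is not
divisible by 4. The rule used: High = Medium = floor(n/4); the remainder
goes to Low and No, Low taking the larger half when odd. At n = 62 this
gives 15/15/16/16. Class summaries are unweighted arithmetic means within
class; because the importance value is itself the unweighted mean of its
three components, the class-mean IV equals the mean of the class-mean
components (an identity the tests exercise).

## Trait → risk classifiers

Continuous traits enter as-is; categorical traits are one-hot encoded
against a closed vocabulary, continuous columns first and indicator
columns in alphabetical order so the schema is reproducible. Learners are
scikit-learn's random forest and XGBoost's gradient boosting behind a
common predictor contract; when no hyperparameters are supplied a small
fixed grid is searched by 5-fold CV (forest: 200/500 trees, √p or p/3
features per split; boosting: learning rate 0.1/0.3, depth 3/6).

The 70/30 split is stratified by risk level: with ~62 species and four
classes an unstratified split can lose a class entirely. Two observation
designs are supported: species-level (one row per species, n = 62) and
observation-level (one row per species × occupied site, the default for
evaluation). Observation-level designs put rows of the same species in
both train and test, which leaks species identity and inflates test
metrics — near-perfect accuracies under this design measure memorisation
of the species→class map, not generalisation to unseen species.

**Permutation importance** is computed from scratch (metric: accuracy;
default 50 repeats): the baseline accuracy is measured once, each feature
is shuffled across rows with independent draws, and the mean and sd of
the accuracy drop are reported. Default granularity is per column (each
one-hot indicator separately); `grouping="variable"` permutes a
categorical variable's indicators jointly. Drops are not additive across
features — permuting two jointly is not the sum of permuting each (the
XOR fixture in the tests makes this concrete).

## Trait statistics cascade

Per group, Shapiro–Wilk tests normality; Levene tests homogeneity of
variance. Only if every group passes both at α does one-way ANOVA with
Tukey HSD run; otherwise Kruskal–Wallis with pairwise Wilcoxon rank-sum
tests under Holm correction (the standard non-parametric analogue; the
parametric branch's post hoc does not transfer). Note the cascade's
pre-testing means the parametric branch is taken only ~77% of the time
even for perfectly normal data (five α=0.05 gates); the overall type-I
error of the omnibus decision stays calibrated at 0.05 ± 0.02 in both
regimes (verified at 1000 null replicates each).

Compact letters are assigned by insert–absorb: start with one column
holding all groups, split any column containing a significantly different
pair, absorb subset columns, and letter columns in group order — a
deterministic labelling where groups sharing a letter are not
significantly different at α. When the omnibus test does not reject, all
groups share "a" regardless of pairwise results.

## RLQ ordination

With P = L / grand total, row weights r = P·1 and column weights
c = 1ᵀ·P, the R and Q columns are centred **and scaled to unit variance**
under their respective weights (the normed-PCA variant; centring-only is
available via `scale=False`). The fourth-corner matrix Z = R̃ᵀ P Q̃ is
decomposed by SVD; total co-inertia is ‖Z‖²_F (= Σ over *all* singular
values squared; reported axes default to 2). Axis signs are fixed so the
env variable with the largest |loading| on each axis is positive, making
quadrant placement deterministic. Empty rows/columns of L are dropped
with a warning. Categorical traits should be pre-expanded to indicators;
the trait tables used here are continuous (log-transformed, since trait
distributions are right-skewed).

Significance uses a site-permutation test of total co-inertia (rows of R
shuffled against L, +1 p-value convention). `select_traits` returns traits
positive on axis 1 with |score| in the top quartile, ordered by |score| —
the "first quadrant" reading of a trait tracking the main gradient.

Because the survey module has no site coordinates, the pipeline builds
the three tables from presence points: each occupied grid cell is a site,
L counts points per cell × species, R takes the cell's environmental
values.

## Trait-weighted SDM

TraitScore: per-trait min–max to [0,1], composite = mean over the selected
traits (default SLA alone, the trait selected by the RLQ step). Presences
get their species' score as case weight, floored at ε = 10⁻³ (a zero
weight would silently delete the minimum-score species). Background:
uniform over unmasked cells, 10× the presence count, without replacement
when the grid allows.

The fit is the infinitely-weighted logistic approximation of the
presence/background point-process model: a weighted L1-penalized logistic
regression with presence weights w_i and a fixed background weight of
100 per point. Features default to linear + quadratic per layer (a convex,
low-dimensional set; hinge features are deliberately omitted). Features
are standardised by their weighted mean/SD before fitting, so the uniform
L1 penalty acts per feature scaled by its weighted SD; coefficients are
mapped back to the raw scale. Two exact degeneracies anchor correctness:
unit weights reproduce the unweighted fit, and integer weights reproduce
the fit on the row-replicated data (to 1e-6; both tested). Evaluation
splits presences and background 70/30 separately (keeping the evaluation
class balance stable) and reports the held-out ROC/AUC; AUC uses the
Mann–Whitney rank formulation with ties counted ½, which equals
trapezoidal integration of the threshold-swept curve exactly.

The default mode pools all high-risk species' presences into one model
with per-species weights (one combined risk surface); fitting species
separately is possible by filtering the presence table. The cloglog
transform maps the linear predictor to [0,1] (logistic and raw outputs
selectable).

## Synthetic data: what it emulates, and not

The generator plants three causal links so each pipeline stage has a
recoverable ground truth:

1. **Traits → invasiveness.** SLA ~ LogNormal(5.0, 0.4) cm²/g,
   hundred-grain weight ~ LogNormal(−1, 1) g; latent invasiveness
   η = 1.0·z(log SLA) + 0.8·z(log HGW) + small categorical effects
   (capsule/utricle fruit, gravity dispersal: +0.2) + N(0, 0.3).
2. **Invasiveness → survey.** Per quadrat, occupancy ~
   Bernoulli(logistic(−2.5 + 1.5·η)); counts 1 + NegBin(mean
   exp(0.5 + 0.6η), dispersion 1); cover ∝ count × per-species leafiness,
   rescaled so quadrat totals stay ≤ 1.
3. **Traits → distribution.** Cell intensity per species ∝
   exp((2.0 + 2.0·z(log SLA))·env1 − ½·env2²): all aliens share a baseline
   affinity for the resource-rich (high-env1, oasis) end of the gradient,
   and SLA modulates its strength. The shared baseline is what makes a
   *pooled* high-risk model able to separate presences from background
   (held-out AUC ≥ 0.9); with purely species-specific responses the pooled
   single-coefficient model faces an irreducible heterogeneity ceiling
   near AUC ≈ 0.85.

Default scale is 62 species × 120 sites (×3 plots ×5 quadrats); the
full 611-site profile is one config key away and is used in the tests
only for the sampling-unit arithmetic. Environmental layers are a west–
east gradient plus smoothed Gaussian random fields on a 60 × 40 grid, all
standardised. Every generator is a pure function of (config, seed).

What the synthetic data does **not** emulate: spatial autocorrelation of
the survey sites (quadrats are exchangeable), observation error in cover
estimation, interannual dynamics, dispersal limitation, and sampling bias
in presence points. Passing recovery tests therefore show the estimators
work when their assumptions hold — not that field data meet those
assumptions.

## Numerical conventions

- Cover is stored as a fraction in [0,1]; a survey file with any cover
  value > 1 is treated as percent and divided by 100 (warned).
- Rasters are ESRI ASCII grids, row 0 = north, cell-center point
  extraction, nodata −9999; a stack's mask is the union of layer masks,
  and mismatched grids are an error (no resampling).
- Logistic fits use liblinear with tol 1e-8 and fixed random_state; all
  stochastic steps take explicit integer seeds, and two pipeline runs
  with the same config are byte-identical.
- Test-suite problem sizes (e.g. 50-site surveys for the 20-seed trait
  recovery check, 200 presences / 2000 background for SDM recovery) are
  chosen as the smallest scales at which the planted signals are reliably
  recoverable, keeping the default suite fast.

## Known limitations

- The quartile rule and the compact-letter algorithm are conventions;
  other defensible choices (e.g. rank-interpolated quartiles, letter
  ordering by group mean) would change labels at the margins.
- Observation-level classifier metrics are optimistic by design (species
  identity leaks across the split); use the species-level design for
  honest generalisation estimates.
- The RLQ implementation handles continuous (or pre-expanded indicator)
  traits; full Hill–Smith mixed-type scaling is not implemented.
- The SDM assumes background points characterise available environment;
  no bias correction or extrapolation (MESS-style) diagnostics.
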