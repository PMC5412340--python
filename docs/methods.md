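# Methods

`toxmark` identifies gene markers whose expression tracks the *severity*
of drug-induced histopathology symptoms — not merely their occurrence —
in large multi-compound toxicogenomics cohorts, and validates candidate
panels by how well they predict severity for compounds never seen during
selection.

## Data model

The pipeline consumes a genes × samples expression matrix (log-scale,
already summarised to gene level; probe summarisation is upstream and
out of scope) and a per-sample table carrying the dosing compound and,
per symptom, an ordinal pathology grade in {0, 1, 2, 3, 4} (none,
minimal, slight, moderate, severe) plus a flag marking findings judged
spontaneous rather than drug-induced. For one symptom the modelling
dataset keeps all samples except those with a *spontaneous positive*
finding (flagged and grade ≥ 1); a spontaneous flag on a grade-0 record
carries no finding and the sample is kept as a control. Occurrence is
derived as grade ≥ 1.

Genes are z-scored to mean 0, SD 1 using the population (denominator
*n*) standard deviation; the population form makes small worked
examples exact and the two forms are indistinguishable at cohort scale.
Zero-variance genes cannot be scaled; they are centred to zero and
reported in a warning, never imputed. By default standardisation is
*global* (over all samples of the dataset) before modelling — this
mirrors pipelines that normalise the cohort once, and leaks only the
per-gene location/scale statistics across CV folds; a `per-fold` mode
that standardises with training-fold statistics is available for
leakage-free evaluation. The difference was negligible in every
scenario we generate.

## Marker selection

Three selection methods share one interface and differ only in the
label information they use (severity groups, jointly / severity
groups, per gene / occurrence groups, per gene):

**Sparse LDA (primary).** Classical LDA is recast as *optimal scoring*:
find class scores θ (one value per severity grade) and a coefficient
vector β minimising ‖Yθ − Xβ‖², where Y is the n × K class indicator
matrix. Penalising the regression with an elastic net
(λ₂‖β‖² + λ₁‖β‖₁) makes β sparse while letting correlated genes share
or cancel weight — the property that distinguishes joint from per-gene
selection. Directions are extracted sequentially for j = 1..K−1, each
score vector kept D-orthonormal (D = YᵀY/n) to the previous ones and
to the trivial constant score, alternating:

1. β_j ← argmin ‖Yθ_j − Xβ‖² + λ₂‖β‖² with at most *m* non-zero
   coefficients;
2. θ_j ← normalise(P D⁻¹ Yᵀ X β_j), P the D-orthogonal projector.

The cardinality constraint is enforced directly: the ℓ₁ path is
computed by LARS-EN (on the ridge-augmented Gram matrix) and the
least-penalised solution whose active set fits the budget is taken, so
the requested marker count *m* is an input parameter rather than an
implicit function of λ₁. With m ≥ p and λ₁ → 0 the solve reproduces
the ridge/OLS solution exactly, and the fitted subspace coincides with
classical LDA's discriminant subspace (principal angles < 1e-6 on
full-rank problems) — both are asserted in the tests.

*Ranking across directions.* A gene's selection score is the largest
absolute loading it attains across directions, **after weighting each
direction by its canonical fit quality R²** (the squared correlation
between Yθ_j and Xβ_j). Coefficients from separate regressions live on
incomparable scales; when the between-class structure is low-rank
(e.g. effects linear in grade), trailing directions fit mostly noise,
and without the weighting their loadings can displace genuinely weak
markers from the panel. The R² weight is the optimal-scoring analogue
of weighting discriminant coordinates by canonical correlation. The
top *m* genes with non-zero weighted loading form the marker set; ties
break lexicographically by gene id for determinism.

Defaults: λ₂ = 1e-3 (stabilises p ≫ n solves; configurable, 0 allowed
on full-rank designs), K−1 directions for K grades present, alternating
updates capped at 20 iterations at tolerance 1e-4 for screening (the
selected support stabilises long before the coefficients; precision
work uses tighter settings explicitly).

**One-way ANOVA.** Per-gene F across severity groups; groups with
fewer than two members are excluded. A gene with zero within-group
variance but non-zero between-group variance is maximally
discriminative: F = ∞, p = 0, ranked first. Ranking is by ascending
p-value.

**Two-sample t.** Per-gene t between occurrence groups. Default is the
Welch unequal-variance form with Satterthwaite df, because case and
control variances differ by construction whenever effects scale with
grade; the pooled classical form is available via `variant="pooled"`.
Ranking is by ascending p with ties broken by descending |t| then gene
id (Welch df varies per gene, so p-order and |t|-order can differ).

## Severity prediction model

Cohorts are control-heavy (most samples never show a given symptom),
so a single regressor would be dominated by grade-0 samples. The model
is an ensemble of `n_models` (default 100) small regression forests;
each member trains on *all* case samples plus an equal-size control
subset drawn uniformly without replacement, independently per member
(with replacement, with a warning, in the degenerate case of fewer
controls than cases). The regression target is the raw integer grade —
severity is treated numerically, without an ordinal link — and the
ensemble prediction is the plain arithmetic mean of member outputs,
continuous and unclipped. Member forests default to 10 trees of
unlimited depth with bootstrap resampling; feature subsampling at
splits is disabled (`max_features = 1.0`) so that every marker is a
split candidate in every tree, the closest standard-forest reading of
"each marker participates in tree construction". Training subsample
composition is logged per member, and the case/control balance is
asserted from that log in the tests.

## Evaluation

Cross-validation folds partition *drugs*, never samples: drugs are
shuffled and dealt round-robin into k = 10 folds, and every sample
inherits its drug's fold, so held-out compounds are entirely unseen.
Marker selection runs inside each training split; selecting once on
the full cohort would leak compound identity through the panel. A hook
exposes exactly the sample ids visible to selection per fold, and the
tests assert they never intersect the held-out fold.

Severity read-out: Spearman's correlation (Pearson on midranks)
between actual and predicted severity, reported per fold and pooled
over concatenated out-of-fold predictions. Pooled is primary; a fold
whose actual severities are constant (e.g. no cases) has no defined
rank correlation and is excluded from the per-fold mean with a
warning. Occurrence read-out: a sample is called positive when its
predicted severity is ≥ a threshold; sweeping the threshold over the
distinct predicted values yields the ROC, and the trapezoidal AUC
equals the Mann–Whitney statistic with ties credited ½ (asserted
against an exhaustive pair-counting oracle).

## Enrichment

Marker panels are screened against user-supplied gene sets (GMT) with
the upper-tail hypergeometric test, p = Σ_{i≥k} C(K,i)C(N−K,n−i)/C(N,n),
after intersecting both the panel and each term with the background
universe (default: all genes of the expression matrix — a
species-level background is not reproducible offline). Significance is
flagged at raw p < 0.01 by default, matching screening practice for
small panels; Benjamini–Hochberg correction is available behind a
flag. `mode="ease"` scores k−1 successes instead of k, the
conservative EASE convention used by DAVID-style tools; the plain test
is the default and the mode is recorded in CLI output metadata.

## Synthetic cohorts

The generator (`toxmark.simulate`) produces cohorts with the structure
the analysis assumes, plus ground truth for scoring recovery:

* each drug is toxic with probability `frac_toxic_drugs`; a toxic
  drug's maximum induced grade is drawn uniformly from 1..`max_grade`,
  and its samples receive grades monotone in a within-drug dose index
  (equal contiguous chunks per grade), so every grade 0..max appears
  for every toxic drug — a deterministic stand-in for dose/time
  structure. Non-toxic drugs contribute only controls, producing the
  control-heavy imbalance of real pathology data;
* expression is unit-variance Gaussian with correlated gene blocks
  (`block_size` genes sharing a latent factor at correlation
  `block_rho`, default 10 genes at 0.3); marker genes add
  direction · `effect_size` · grade to their mean, so `effect_size`
  reads directly in SD units per grade;
* one marker pair is *correlated-but-individually-weak*: both members
  load ~0.9 on a shared latent factor and carry half the effect with
  opposite signs. Each member is marginally weak, but the pair
  difference cancels the shared factor and carries the full effect at
  ~⅕ of the noise SD — constructed deliberately as the test bed for
  the claim that exploiting gene–gene relationships finds markers
  per-gene screens miss;
* ~3% of positive findings are flagged spontaneous, exercising the
  drug-induced-only filter;
* the matching annotation generator plants one term containing 70% of
  the marker genes padded to `term_size` with random genes, among
  uniformly random terms.

What the generator does **not** emulate: probe-level noise, batch
effects, saturating or otherwise nonlinear dose–response, multiple
correlated symptoms, and drug-specific expression signatures unrelated
to toxicity. Passing tests therefore certify the statistical machinery
and its guarantees (recovery, leakage-freedom, calibration of the
metrics), not performance on any real cohort.

Two frozen scenarios are exported: `benchmark_scenario` (40 drugs × 20
samples, 2,000 genes, 24 markers at 0.8 SD/grade, 30% toxic drugs) for
marker-recovery and signal-detection checks, and `weak_pair_scenario`
(30 drugs × 15 samples, 400 genes, 8 markers at 0.4 SD/grade, 40%
toxic) for the three-way method comparison — sized so the pair carries
a material share of the severity signal and per-gene effects sit near
the univariate detection margin, the regime where joint and per-gene
selection genuinely part ways.

## Known limitations and expected behaviour of the method comparison

On the weak-pair scenario, sparse-LDA panels consistently achieve the
highest cross-validated severity correlation. The ANOVA-vs-t-test
comparison, by contrast, is a statistical tie here: because planted
effects are *linear in grade*, the genes separating occurrence groups
are exactly the genes tracking severity, and the single-df
case-vs-control contrast has equal or better per-gene power than the
(K−1)-df F. A real advantage for severity-aware univariate screening
requires nonlinear (e.g. saturating) dose–response, which this
generator intentionally does not model; on synthetic data the
severity-grouping-vs-occurrence-grouping ordering should therefore not
be expected to reproduce, and the acceptance test that asserts it
documents this boundary of the synthetic design.

Other numerical choices: all randomness flows through explicit integer
seeds (NumPy `default_rng`; per-stage seeds in the CLI are split from
the master seed by a counter scheme so stage reordering never shifts
streams); CV at the benchmark scale uses 20 ensemble members instead
of 100 and the method comparison uses 10 — the read-outs stabilise
well below that, and the member count scales results, not conclusions;
ties are broken lexicographically everywhere a ranking is emitted;
missing expression values are rejected rather than imputed.
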