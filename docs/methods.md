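# Methods

This note documents the statistical procedures implemented in `access5a`,
the modelling assumptions behind them, the defaults and why they were
chosen, and what the synthetic-data tests do and do not demonstrate.

## The evaluation model

A service system is evaluated through a three-level indicator hierarchy:
L1 primary dimensions (here 5: availability, accessibility,
affordability, acceptability, adaptability), split into L2 secondary and
L3 tertiary indicators (here 14 and 37). Each tertiary indicator maps to
one Likert survey item with the evaluation set
V = {V1, …, V5}, V1 = very satisfied … V5 = very dissatisfied, carrying
grade values (5, 4, 3, 2, 1). Internally all responses are stored on the
grade-value scale (5 = best); `ResponseTable.from_frame` also accepts
`V1`…`V5` labels.

Weights are fractions of a total of 1 with the additive constraint that
every parent's weight equals the sum of its children's. `validate_weight_rollup`
checks each parent against both its direct children's sum and its
leaf-descendant sum, so a perturbed leaf flags the entire ancestor chain,
not just its immediate parent.

## Delphi statistics

* **Authority**: Cr = (Ca + Cs)/2 with both components pre-quantified on
  [0, 1]; the rubric mapping questionnaire answers to Ca/Cs is outside
  scope. Cr ≥ 0.70 is the conventional acceptability bar.
* **Concordance**: Kendall's W from within-expert ranks of the
  importance ratings, with average ranks for ties. Because 1–5 Likert
  ratings are heavily tied, the tie-corrected denominator
  m²(n³−n) − m·ΣT_i (T_i = Σ(t³−t) over tie groups in expert i's row) is
  the default; without correction a fully constant row is rejected as an
  undefined ranking. Significance uses the asymptotic χ² = m(n−1)W test
  with n−1 degrees of freedom (an exact test is not provided; published
  consultation tables of this size are deep in the asymptotic regime).
  Note that a χ² printed next to a 3-d.p. W will generally not equal
  m(n−1)·W_rounded exactly; consistency is asserted at rounding
  tolerance only.
* **Screening**: an indicator is retained iff its mean importance is
  ≥ 3.5 and its coefficient of variation (SD/mean, SD with ddof = 1) is
  ≤ 0.25. These are common Delphi conventions; the reference study
  reports a 39 → 37 reduction without stating its rule, so both
  thresholds are explicit parameters everywhere they are used.

## Entropy weighting

For n evaluation objects × m indicators, columns are min–max normalised
(direction-aware: negative-direction columns are reflected), then
p_ij = x_ij/Σ_i x_ij, e_j = −k Σ_i p_ij ln p_ij with k = 1/ln n (the
standard choice bounding e_j in [0, 1]), d_j = 1 − e_j and
w_j = d_j/Σ d_j.

Numerical choices:

* 0·ln 0 := 0, keeping the one-hot minimum-entropy case exact. A
  `shift` option (add ε, e.g. 1e-4, to all normalised values and
  recompute proportions) is available for users who prefer strictly
  positive proportions; it is off by default.
* A constant column has no discriminating information: the default
  policy assigns e_j = 1, w_j = 0 with a warning ("zero-weight");
  an "error" policy is available. Redundancies below 1e-12 are snapped
  to zero so that float error in ln cannot manufacture weight out of a
  constant column; if *all* columns are constant, weights are undefined
  and an error is raised.
* The evaluation objects are individual respondents by default (each
  respondent's 37 Likert scores form a row); any other aggregation
  (e.g. district means) can be passed as the data matrix instead. The
  reference study does not state which unit it used, which is why its
  printed weights ship as a fixture rather than being recomputed.

Leaf weights are then aggregated bottom-up (`assign_and_rollup`); the
result always passes the roll-up validator.

## Fuzzy comprehensive evaluation

* **Membership**: for indicator r and grade g, the membership degree is
  the relative frequency of grade g among respondents; rows sum to 1.
* **Composition**: the weighted-average operator M(·,⊕) — renormalise
  the sibling weights within the block, then take the weighted sum of
  membership rows. It conserves total membership (every composite vector
  sums to 1), uses all weight information, and makes every parent score
  the exact weighted mean of its children's scores, which in turn makes
  hierarchical composition path-independent: composing
  tertiary → secondary → primary → overall equals a single flat pass
  with global leaf weights. This operator also reproduces the published
  parent scores from the published child scores within rounding
  (±0.002 at every node), which is the empirical evidence for the
  choice. The classical max–min operator M(∧,∨) is available behind a
  flag for comparison (its output is renormalised to sum 1); it is not
  the default because it discards most weight information at 37-leaf
  scale.
* **Defuzzification**: dot product of the membership vector with the
  grade values, no renormalisation. The input must sum to 1 within a
  tolerance of 0.005 by default — loose enough to accept externally
  reported vectors whose printed entries sum to 0.9999. Renormalising
  such a vector before the dot product would change the fourth decimal
  (3.3333 instead of 3.3330 for the reference vector), so
  renormalisation is opt-in.

## Survey design

* **Sample size**: n = ⌊k²·p(1−p)/ε²⌋ with defaults k = 1.96 (95%
  confidence), p = 0.5 (conservative), ε = 0.05, giving 384. The floor
  rather than the ceiling matches how the bound is conventionally quoted
  for these round inputs.
* **Multiple imputation**: each missing Likert cell is drawn from the
  observed marginal grade distribution of its own column, independently
  in each of m (default 5) completed tables; analyses run per table and
  pool by averaging. A model-based (chained-equations) imputer is
  deliberately not used: the downstream quantity — frequency-based
  membership — depends only on marginal grade frequencies, for which
  marginal hot-deck draws are a sufficient and transparent model.
  Tables with more than 5% missing cells are refused with per-column
  diagnostics. Deterministic under a fixed seed.
* **Demographics**: `respondent_summary` produces percentage tables per
  category (gender, age band, income band, health, residence) at 2
  decimals; per-category totals are allowed 0.2 points of rounding
  slack, matching how such tables are printed.

## Synthetic data generator

`generate_survey` draws, per respondent and indicator, a latent
continuous satisfaction value with the indicator's latent mean and a
shared dispersion, and discretises it onto grades 1–5 at cut-points
1.5/2.5/3.5/4.5 with clamping. The latent family is a symmetric normal
by default; a left-skewed skew-normal (shape −4, re-parameterised so the
requested mean and dispersion are the distribution's actual moments) is
provided because real satisfaction data are typically left-skewed.
Demographics are multinomial draws at configurable stratum proportions;
the bundled defaults are the published respondent profile (e.g. 51.85%
male, 41.90% in the 2000–3999 Yuan income band). Missing cells are
Bernoulli at a configurable rate capped at 5%. The bundled profile sets
the latent means to the published tertiary scores, the dispersion to
0.8 and n to 430 — the analysed sample size of the reference survey.

What this emulates and what it does not: the generator reproduces the
*marginal* structure the pipeline consumes (per-indicator grade
frequencies, stratum proportions, sparse missingness) with known ground
truth. It does not model correlation between indicators, respondent
heterogeneity (random effects), differential item functioning across
strata, or informative missingness. Passing recovery tests therefore
demonstrate the pipeline's correctness and stability under the stated
response model, not robustness to those real-data features.

Recovery behaviour: rounding a latent normal is approximately unbiased
in the interior of the scale but clamping compresses means near the
endpoints; at dispersion 0.8 and latent means in [2.9, 3.9] the
discretisation bias stays ≈0.03, and with n = 5000 recovered indicator
means land within ±0.06 of the latent means (the tolerance asserted in
the tests).

## Pipeline and problem sizes

`run_pipeline` chains the stages (Delphi summary/screening → imputation
→ per-table entropy weights, averaged across imputations → roll-up →
FCE per table, scores pooled by averaging) and persists every
intermediate as CSV with a `# key=value` metadata header (tool version,
config hash, seed); stripped of headers, outputs are byte-identical
across reruns with the same config and seed. Entropy weights are
averaged across imputed tables before roll-up so that one common
weighted hierarchy scores all tables.

Test and example problem sizes were chosen so the full suite runs in
seconds on a laptop: unit tests use panels of ≤ 20 experts × ≤ 58 items
and surveys of ≤ 430 respondents; the recovery checks use one n = 5000
survey and one n = 10000 demographics draw.

## Known limitations

* Only 3-level hierarchies are supported (no deeper trees, no
  multi-parent DAGs) and no subjective or hybrid weighting (AHP etc.).
* The Delphi screening rule is a convention, not the reference study's
  (unpublished) rule; with other data it may trim a different set.
* No survey weighting/post-stratification or design effects; the
  response rate is computed as valid/distributed questionnaires.
* Published weights and scores are internal-consistency fixtures; the
  package cannot re-derive them without the undeposited raw data.
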