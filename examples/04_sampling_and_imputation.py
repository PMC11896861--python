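"""Survey design utilities: sample size, response rate, multiple imputation.

Computes the minimum sample size for a proportion at 95% confidence,
then generates a survey with 2% missing cells and repairs it by marginal
multiple imputation, pooling the evaluation across completed tables.
"""

from access5a import (
    PopulationProfile,
    evaluate_hierarchy,
    generate_survey,
    impute_missing,
    load_xian_hierarchy,
    load_xian_profile_dict,
    min_sample_size,
    pool_scores,
    respondent_summary,
    response_rate,
)

n_min = min_sample_size(k=1.96, p=0.5, eps=0.05)
print(f"minimum sample size at 95% confidence, +-5% error: n >= {n_min}")
print(f"response rate for 430 valid of 438 distributed: {response_rate(430, 438):.2f}%")
# 430 analysed responses comfortably exceed the computed floor of 384.

hierarchy = load_xian_hierarchy()
profile = PopulationProfile.from_dict(
    load_xian_profile_dict(), seed=11, missing_rate=0.02
)
survey = generate_survey(profile)
print(f"\nsimulated {survey.n_respondents} respondents, "
      f"{survey.missing_fraction:.1%} of cells missing")

imputation = impute_missing(survey, m_imputations=5, seed=11)
print(f"imputed {len(imputation.log)} cells in each of {imputation.m} completed tables")

results = [evaluate_hierarchy(t, hierarchy) for t in imputation.tables]
pooled = pool_scores([r.scores for r in results])
print("pooled overall score:", round(pooled.loc["overall", "score"], 4),
      "+- between-imputation SD", round(pooled.loc["overall", "between_imputation_sd"], 5))
# the tiny between-imputation SD shows 2% missingness barely moves the index.

print("\nrespondent profile (top rows):")
print(respondent_summary(survey).head(6).to_string(index=False))
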