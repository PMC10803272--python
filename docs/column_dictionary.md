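# Extraction-table column dictionary

Comma-separated UTF-8 with a fixed header row; one row per reported
effect size. Unicode minus signs are normalized to ASCII on read.

| column | type | meaning |
|---|---|---|
| `obs_id` | token | unique identifier of the reported effect size |
| `study_id` | token | identifier of the source study; all observations of a study share its random effect |
| `outcome_id` | token | health outcome the effect size refers to |
| `rr` | positive real | relative measure of association (RR, odds ratio or hazard ratio, pooled as one relative measure) |
| `ci_lower`, `ci_upper` | positive reals, optional | reported 95% CI; must bracket `rr`. Converted to a log-scale SE via `ln(ci_upper/ci_lower) / (2 * 1.96)` when `se_log_rr` is absent |
| `se_log_rr` | positive real, optional | standard error of ln(RR) when reported directly; exactly one of the CI pair or this field must resolve |
| `design` | enum | `prospective_cohort`, `case_control`, `nested_case_control`, `retrospective_cohort`, `case_cohort`, `case_crossover` |
| `smoking_status` | enum | smoking status of the exposed population: `never`, `former`, `nonsmoker`, `any_unspecified`, `adjusted_never` (children-only samples with originally unspecified status, treated as never smokers) |
| `exposure_location` | enum | `home_or_work`, `home`, `work`, `any_unspecified` |
| `exposure_source` | enum | `family`, `parental`, `maternal`, `paternal`, `spouse`, `any_unspecified` |
| `exposure_timing` | enum | `current` or `ever` exposure |
| `sex_scope` | enum | `both`, `female`, `male` |
| `children_only` | bool | sample restricted to children (≤16 years) |
| `subgroup_level` | enum | `whole_population`, `sex_specific`, `age_specific`, `other_subgroup` |
| `endpoint_type` | enum | `incidence`, `mortality`, `combined` |
| `adjustment_rank` | integer | ordinal degree of confounder adjustment; higher = more adjusted |
| `group_key` | token | age–sex–smoking-status group the observation belongs to, used for repeat-measurement SE inflation |
| `mutually_exclusive` | bool | whether the observation's exposure group is mutually exclusive of the other observations in its `group_key` |
| `bias_<name>` | 0/1 | one column per bias covariate; 0 is the gold-standard level |
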