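# Default configuration: screening thresholds, advice rules, health-space
# options, reference-group moments and the observed study tables used by the
# synthetic cohort generator. Everything here is data, editable without
# touching code. Units follow the column dictionary in the README.

screening:
  waist_cm: {M: 102.0, F: 88.0}          # excessive waist, >= threshold
  triglycerides_mmol_l: 1.7              # elevated, >=
  hdl_mmol_l: {M: 1.03, F: 1.29}         # reduced, strict <
  sbp_mm_hg: 130.0                       # elevated, >=
  dbp_mm_hg: 85.0                        # elevated, >=
  glucose_mmol_l: 5.6                    # elevated, strict >
  at_risk_min_secondary: 1               # central obesity + >=1 secondary factor
  mets_min_secondary: 2                  # IDF-style: central obesity + >=2 factors
  motivation_min_mean: 5.0               # 3-item 7-point Likert inclusion rule

homa_ir:
  # glucose [mmol/L] x (C-peptide [nmol/L] x insulin_equiv [uU/mL per nmol/L]) / denominator
  insulin_equiv: 6.0
  denominator: 22.5

health_space:
  features: [triglycerides, ldl, hdl, glucose, c_peptide]
  # direction used when ranking the healthy pool: which extreme is healthiest
  higher_is_healthier: {triglycerides: false, ldl: false, hdl: true,
                        glucose: false, c_peptide: false}
  healthy_bmi_range: [18.0, 25.0]
  n_top_healthy: 10
  class_codes: {mets: 1.0, healthy: 2.0}
  threshold: 1.5
  random_structure: intercept_slopes      # intercept_slopes | intercept | none

advice:
  # per-category DHDI sufficiency cut-off (score units, 1-10): advise if score < cutoff
  dhdi_cutoffs:
    vegetables: 8.0
    fruit: 8.0
    oils_and_fats: 8.0
    fish: 8.0
    wholegrain: 8.0
    dairy: 8.0
    nuts: 8.0
    sugar_beverages: 8.0
  carotenoid_cutoff_umol_l: 1.0           # applies to fruit and vegetables
  flag_map:
    tg_high: [fish, sugar_beverages, oils_and_fats]
    hdl_low: [fish, nuts, oils_and_fats]
    glucose_high: [wholegrain, sugar_beverages]
    bp_high: [vegetables, dairy]
    waist_excessive: [sugar_beverages, oils_and_fats, nuts]
  max_categories: null

schedule:
  measurement_weeks: [0, 8, 16]
  likert_weeks: [0, 16]
  advice_weeks: [0, 8]
  health_score_weeks: [0, 16]

# Reference-group moments (mean, sd) for the two health-space training pools
# and the intervention cohort baseline. Truncation bounds are physiological.
reference_groups:
  healthy:
    male_fraction: 0.50
    features:
      age:               {mean: 57.6, sd: 16.2}
      bmi:               {mean: 21.3, sd: 1.88}
      waist:             {mean: 83.2, sd: 4.68}
      total_cholesterol: {mean: 5.32, sd: 1.10}
      hdl:               {mean: 1.49, sd: 0.37}
      ldl:               {mean: 3.12, sd: 1.02}
      triglycerides:     {mean: 1.57, sd: 0.52}
      glucose:           {mean: 5.33, sd: 0.70}
      c_peptide:         {mean: 0.75, sd: 0.40}
      sbp:               {mean: 138.0, sd: 18.5}
      dbp:               {mean: 77.7, sd: 14.0}
  mets:
    male_fraction: 0.46
    features:
      age:               {mean: 54.0, sd: 21.0}
      bmi:               {mean: 31.1, sd: 5.68}
      waist:             {mean: 105.0, sd: 10.8}
      total_cholesterol: {mean: 4.77, sd: 1.02}
      hdl:               {mean: 1.01, sd: 0.13}
      ldl:               {mean: 2.73, sd: 0.99}
      triglycerides:     {mean: 2.25, sd: 0.95}
      glucose:           {mean: 7.07, sd: 3.08}
      c_peptide:         {mean: 1.46, sd: 0.90}
      sbp:               {mean: 128.0, sd: 21.5}
      dbp:               {mean: 67.4, sd: 18.6}
  intervention:
    male_fraction: 0.26
    features:
      age:               {mean: 61.0, sd: 8.2}
      bmi:               {mean: 29.9, sd: 4.18}
      waist:             {mean: 102.0, sd: 11.4}
      total_cholesterol: {mean: 6.23, sd: 0.78}
      hdl:               {mean: 1.14, sd: 0.27}
      ldl:               {mean: 4.34, sd: 0.74}
      triglycerides:     {mean: 1.67, sd: 0.85}
      glucose:           {mean: 5.61, sd: 0.65}
      c_peptide:         {mean: 0.52, sd: 0.33}
      sbp:               {mean: 135.0, sd: 18.0}
      dbp:               {mean: 78.6, sd: 9.54}

truncation_bounds:
  age:               [18.0, 95.0]
  bmi:               [14.0, 60.0]
  waist:             [50.0, 180.0]
  total_cholesterol: [2.0, 12.0]
  hdl:               [0.4, 4.0]
  ldl:               [0.5, 9.0]
  triglycerides:     [0.2, 12.0]
  glucose:           [3.0, 22.0]
  c_peptide:         [0.05, 6.0]
  sbp:               [80.0, 230.0]
  dbp:               [40.0, 140.0]

# Default feature correlations for the Gaussian copula; identity elsewhere.
feature_correlations:
  - {a: hdl, b: triglycerides, r: -0.3}

# Observed study tables: per-outcome means at each measured week and the
# week-0 SD. `kind: category` outcomes change only for participants whose
# behavior-change strategy includes the category (the printed means are
# conditional on inclusion). `health_score` and `homa_ir` are derived
# quantities in the pipeline; their printed rows are kept for the
# printed-change arithmetic, not for generation.
study_tables:
  vegetables:            {kind: category, weeks: [0, 8, 16], means: [6.6, 7.5, 7.1],   sd: 2.9}
  fruit:                 {kind: category, weeks: [0, 8, 16], means: [5.8, 8.2, 8.4],   sd: 3.3}
  oils_and_fats:         {kind: category, weeks: [0, 8, 16], means: [3.7, 3.6, 3.5],   sd: 3.9}
  fish:                  {kind: category, weeks: [0, 8, 16], means: [6.6, 7.5, 8.6],   sd: 3.2}
  wholegrain:            {kind: category, weeks: [0, 8, 16], means: [6.3, 7.7, 7.9],   sd: 2.5}
  dairy:                 {kind: category, weeks: [0, 8, 16], means: [3.1, 3.8, 4.1],   sd: 2.6}
  nuts:                  {kind: category, weeks: [0, 8, 16], means: [6.2, 7.0, 8.4],   sd: 3.3}
  sugar_beverages:       {kind: category, weeks: [0, 8, 16], means: [1.9, 5.5, 6.6],   sd: 1.8}
  dhdi_total:            {kind: continuous, weeks: [0, 8, 16], means: [52.9, 56.5, 57.2], sd: 13.1}
  carotenoids:           {kind: continuous, weeks: [0, 8, 16], means: [1.21, 1.39, 1.42], sd: 0.43}
  glucose:               {kind: continuous, weeks: [0, 8, 16], means: [5.61, 5.63, 5.84], sd: 0.67}
  c_peptide:             {kind: continuous, weeks: [0, 8, 16], means: [0.52, 0.52, 0.43], sd: 0.32}
  triglycerides:         {kind: continuous, weeks: [0, 8, 16], means: [1.67, 1.43, 1.39], sd: 0.86}
  total_cholesterol:     {kind: continuous, weeks: [0, 8, 16], means: [6.23, 5.91, 5.90], sd: 0.78}
  hdl:                   {kind: continuous, weeks: [0, 8, 16], means: [1.14, 1.09, 1.44], sd: 0.28}
  ldl:                   {kind: continuous, weeks: [0, 8, 16], means: [4.34, 4.18, 3.87], sd: 0.74}
  sbp:                   {kind: continuous, weeks: [0, 8, 16], means: [135.0, 133.0, 132.0], sd: 18.2}
  dbp:                   {kind: continuous, weeks: [0, 8, 16], means: [78.6, 80.3, 79.6], sd: 9.60}
  bmi:                   {kind: continuous, weeks: [0, 8, 16], means: [29.9, 29.4, 29.2], sd: 3.94}
  waist:                 {kind: continuous, weeks: [0, 8, 16], means: [102.0, 100.0, 99.4], sd: 11.5}
  self_perceived_health: {kind: likert, weeks: [0, 16], means: [4.68, 5.35], sd: 1.07}
  diet_healthiness:      {kind: likert, weeks: [0, 16], means: [4.50, 5.56], sd: 1.05}
  diet_satisfaction:     {kind: likert, weeks: [0, 16], means: [4.35, 5.29], sd: 1.39}
  health_score:          {kind: derived, weeks: [0, 8, 16], means: [1.30, 1.23, 1.57], sd: 0.31}
  homa_ir:               {kind: derived, weeks: [0, 8, 16], means: [7.45, 7.42, 6.31], sd: 5.27}

# Fraction of participants whose behavior-change strategy includes each
# category (advice frequencies reported by the study).
strategy_probabilities:
  vegetables: 0.91
  oils_and_fats: 0.62
  nuts: 0.59
  wholegrain: 0.56
  dairy: 0.41
  fish: 0.35
  fruit: 0.27
  sugar_beverages: 0.09

trajectory_options:
  within_subject_corr: 0.7
  dropout: 0
  n_participants: 34
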