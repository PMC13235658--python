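# Reference statistical description of a prospective Korean GI-cancer
# screening cohort: 7,652 participants, 156 incident gastrointestinal cancer
# cases (2.0%) over 14 years of follow-up.  Per-class marginal moments of the
# published baseline-characteristics table; nutrient intakes are the
# energy-adjusted values.  Units: age years; BMI kg/m2; SBP/DBP mmHg; glucose,
# HDL, LDL, triglyceride mg/dL; AST U/L; GGT IU/L; energy kcal/d; nutrients
# per day.  Only marginals are published: joint structure is unknown and the
# generator defaults to per-class independence.
n: 7652
incidence: 0.02
n_cases: 156
# Bernoulli rates per class: [case, control]
covariate_prevalence:
  sex_male: [0.571, 0.359]
  drinker: [0.647, 0.628]
  smoker: [0.494, 0.333]
  married: [0.878, 0.880]
  unemployed: [0.410, 0.425]
  higher_education: [0.410, 0.467]
  lower_income: [0.308, 0.198]
# Per-class normal moments: [case_mean, case_sd, control_mean, control_sd]
predictor_moments:
  age: [57.51, 7.83, 52.33, 8.20]
  ast: [28.58, 15.06, 22.97, 11.11]
  bmi: [24.97, 2.98, 23.59, 2.97]
  calcium: [474.73, 199.97, 486.88, 211.73]
  carbohydrate: [315.48, 33.92, 314.08, 33.71]
  beta_carotene: [1976.90, 1024.43, 2127.04, 1221.98]
  dietary_cholesterol: [121.09, 74.57, 131.70, 77.08]
  dbp: [81.81, 10.82, 76.03, 10.48]
  glucose: [102.44, 33.66, 92.99, 14.18]
  fat: [29.18, 11.78, 30.46, 11.53]
  fiber: [15.13, 6.61, 16.69, 7.47]
  ggt: [44.47, 68.35, 28.79, 33.74]
  hdl: [55.51, 13.01, 59.76, 14.59]
  iron: [10.34, 2.60, 10.34, 2.88]
  ldl: [114.15, 36.13, 116.95, 32.64]
  magnesium: [168.12, 65.97, 177.43, 67.89]
  mufa: [7.48, 3.74, 8.04, 3.93]
  niacin: [9.80, 2.42, 10.31, 2.59]
  phosphorus: [874.99, 206.04, 899.72, 221.95]
  potassium: [2319.55, 727.02, 2460.60, 800.13]
  protein: [61.88, 10.73, 62.49, 11.41]
  pufa: [4.60, 2.04, 4.84, 2.06]
  sbp: [131.74, 15.07, 124.72, 14.46]
  sfa: [8.45, 4.04, 9.04, 4.27]
  sodium: [1990.97, 814.69, 1981.94, 778.54]
  sugar: [44.68, 25.30, 51.35, 28.39]
  thiamin: [0.90, 0.23, 0.92, 0.23]
  energy: [1778.40, 597.48, 1732.69, 577.23]
  triglyceride: [120.69, 65.40, 117.50, 75.34]
  vitamin_a: [419.72, 201.31, 449.03, 224.47]
  vitamin_c: [60.98, 34.46, 68.47, 39.26]
  vitamin_d: [4.37, 4.19, 4.79, 4.07]
  vitamin_e: [6.34, 3.32, 6.65, 3.11]
  zinc: [4.93, 1.77, 5.16, 1.88]
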