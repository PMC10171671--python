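# Dose-response parameters for the salt -> SBP -> CVD-mortality pathway.
#
# beta: change in systolic blood pressure (mmHg) per g/day of salt, by age.
#   Transcribed from the age-specific blood-pressure response to a
#   100 mmol/day sodium change (= 5.844 g/day salt) estimated in the
#   Law, Frost & Wald (1991, BMJ 302:811-824) cross-population and
#   intervention analyses, evaluated at the population-average blood
#   pressure; slopes rise with age.
#
# rr20: relative risk of cause-specific CVD death per 20 mmHg higher usual
#   systolic blood pressure, by age at risk.  Ischaemic heart disease and
#   stroke entries are transcribed from the Prospective Studies
#   Collaboration age-specific hazard ratios (Lewington et al. 2002,
#   Lancet 360:1903-1913), inverting the published "per 20 mmHg lower"
#   estimates.  The remaining pressure-mediated causes (heart failure,
#   hypertensive disease, aortic aneurysm, pulmonary embolism, rheumatic
#   heart disease) are not tabulated cause-by-cause in that report; their
#   entries are approximate transcriptions anchored to the Collaboration's
#   "other vascular" gradient and cohort studies of hypertension and each
#   outcome, and are flagged "approximate" in their source strings.
version: 1
beta:
  - {age_min: 15, age_max: 29, slope: 0.513, se: 0.062,
     source: "Law/Frost/Wald 1991: ~3.0 mmHg SBP per 100 mmol/d Na at ages 15-29"}
  - {age_min: 30, age_max: 39, slope: 0.684, se: 0.082,
     source: "Law/Frost/Wald 1991: ~4.0 mmHg SBP per 100 mmol/d Na at ages 30-39"}
  - {age_min: 40, age_max: 49, slope: 0.856, se: 0.103,
     source: "Law/Frost/Wald 1991: ~5.0 mmHg SBP per 100 mmol/d Na at ages 40-49"}
  - {age_min: 50, age_max: 59, slope: 1.027, se: 0.123,
     source: "Law/Frost/Wald 1991: ~6.0 mmHg SBP per 100 mmol/d Na at ages 50-59"}
  - {age_min: 60, age_max: 69, slope: 1.198, se: 0.144,
     source: "Law/Frost/Wald 1991: ~7.0 mmHg SBP per 100 mmol/d Na at ages 60-69"}
  - {age_min: 70, age_max: 120, slope: 1.369, se: 0.164,
     source: "Law/Frost/Wald 1991: ~8.0 mmHg SBP per 100 mmol/d Na at ages 70+"}
rr20:
  # Ischaemic heart disease (I20-25)
  - {cause: I20-25, age_min: 20, age_max: 49, rr: 2.04, ci_low: 1.82, ci_high: 2.29,
     source: "Lewington 2002 PSC, IHD mortality, age 40-49 (1/0.49 per 20 mmHg)"}
  - {cause: I20-25, age_min: 50, age_max: 59, rr: 2.00, ci_low: 1.85, ci_high: 2.16,
     source: "Lewington 2002 PSC, IHD mortality, age 50-59"}
  - {cause: I20-25, age_min: 60, age_max: 69, rr: 1.85, ci_low: 1.75, ci_high: 1.96,
     source: "Lewington 2002 PSC, IHD mortality, age 60-69"}
  - {cause: I20-25, age_min: 70, age_max: 79, rr: 1.67, ci_low: 1.59, ci_high: 1.75,
     source: "Lewington 2002 PSC, IHD mortality, age 70-79"}
  - {cause: I20-25, age_min: 80, age_max: 120, rr: 1.49, ci_low: 1.39, ci_high: 1.60,
     source: "Lewington 2002 PSC, IHD mortality, age 80-89"}
  # Cerebrovascular disease / stroke (I60-69)
  - {cause: I60-69, age_min: 20, age_max: 49, rr: 2.78, ci_low: 2.27, ci_high: 3.40,
     source: "Lewington 2002 PSC, stroke mortality, age 40-49 (1/0.36 per 20 mmHg)"}
  - {cause: I60-69, age_min: 50, age_max: 59, rr: 2.63, ci_low: 2.38, ci_high: 2.91,
     source: "Lewington 2002 PSC, stroke mortality, age 50-59"}
  - {cause: I60-69, age_min: 60, age_max: 69, rr: 2.33, ci_low: 2.17, ci_high: 2.50,
     source: "Lewington 2002 PSC, stroke mortality, age 60-69"}
  - {cause: I60-69, age_min: 70, age_max: 79, rr: 2.00, ci_low: 1.89, ci_high: 2.12,
     source: "Lewington 2002 PSC, stroke mortality, age 70-79"}
  - {cause: I60-69, age_min: 80, age_max: 120, rr: 1.49, ci_low: 1.37, ci_high: 1.62,
     source: "Lewington 2002 PSC, stroke mortality, age 80-89"}
  # Heart failure (I50) - approximate
  - {cause: I50, age_min: 20, age_max: 59, rr: 2.00, ci_low: 1.60, ci_high: 2.50,
     source: "approximate: hypertension-to-HF cohort gradients scaled per 20 mmHg"}
  - {cause: I50, age_min: 60, age_max: 69, rr: 1.85, ci_low: 1.50, ci_high: 2.28,
     source: "approximate: hypertension-to-HF cohort gradients scaled per 20 mmHg"}
  - {cause: I50, age_min: 70, age_max: 79, rr: 1.65, ci_low: 1.36, ci_high: 2.00,
     source: "approximate: hypertension-to-HF cohort gradients scaled per 20 mmHg"}
  - {cause: I50, age_min: 80, age_max: 120, rr: 1.45, ci_low: 1.21, ci_high: 1.74,
     source: "approximate: hypertension-to-HF cohort gradients scaled per 20 mmHg"}
  # Hypertensive disease (I10-15) - approximate, steepest gradient
  - {cause: I10-15, age_min: 20, age_max: 59, rr: 3.20, ci_low: 2.30, ci_high: 4.45,
     source: "approximate: usual-SBP gradient for deaths coded to hypertensive disease"}
  - {cause: I10-15, age_min: 60, age_max: 69, rr: 2.80, ci_low: 2.06, ci_high: 3.81,
     source: "approximate: usual-SBP gradient for deaths coded to hypertensive disease"}
  - {cause: I10-15, age_min: 70, age_max: 79, rr: 2.40, ci_low: 1.80, ci_high: 3.20,
     source: "approximate: usual-SBP gradient for deaths coded to hypertensive disease"}
  - {cause: I10-15, age_min: 80, age_max: 120, rr: 2.00, ci_low: 1.52, ci_high: 2.63,
     source: "approximate: usual-SBP gradient for deaths coded to hypertensive disease"}
  # Aortic aneurysm (I71) - approximate
  - {cause: I71, age_min: 20, age_max: 59, rr: 2.30, ci_low: 1.67, ci_high: 3.17,
     source: "approximate: PSC other-vascular gradient, aneurysm cohorts"}
  - {cause: I71, age_min: 60, age_max: 69, rr: 2.10, ci_low: 1.55, ci_high: 2.85,
     source: "approximate: PSC other-vascular gradient, aneurysm cohorts"}
  - {cause: I71, age_min: 70, age_max: 79, rr: 1.80, ci_low: 1.37, ci_high: 2.37,
     source: "approximate: PSC other-vascular gradient, aneurysm cohorts"}
  - {cause: I71, age_min: 80, age_max: 120, rr: 1.55, ci_low: 1.21, ci_high: 1.99,
     source: "approximate: PSC other-vascular gradient, aneurysm cohorts"}
  # Pulmonary embolism (I26) - approximate, weak association
  - {cause: I26, age_min: 20, age_max: 120, rr: 1.30, ci_low: 1.05, ci_high: 1.61,
     source: "approximate: weak BP association for venous thromboembolic death"}
  # Rheumatic heart disease (I05-09) - approximate, weak association
  - {cause: I05-09, age_min: 20, age_max: 120, rr: 1.30, ci_low: 1.02, ci_high: 1.66,
     source: "approximate: weak BP association for rheumatic heart disease death"}
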