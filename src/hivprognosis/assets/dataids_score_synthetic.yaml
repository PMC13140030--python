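# Dat'AIDS score definition (categorical points -> four risk groups).
#
# PARTLY SYNTHETIC RECONSTRUCTION.  The published facts pinned here are:
# the component list (age, CD4, non-HIV cancer, CVD, eGFR, cirrhosis,
# low BMI, anaemia, HCV co-infection); the age-band points (1 for 65-74,
# 8 for >=75); the theoretical total range 0-73; the risk-group cut-points
# 0-3 / 4-13 / 14-19 / >=20; and the group-level predicted 5-year survival
# 0.95 / 0.90 / 0.80 / 0.53.  The remaining per-category point values are
# synthetic: plausible values consistent with the pinned facts (per-component
# maxima sum to 73).  Do not use this file for clinical scoring.
#
# Interval convention: [min, max), half-open on the right.
name: dataids
kind: categorical_points
components:
  - covariate: age
    type: interval
    intervals:
      - {min: 0, max: 65, points: 0}
      - {min: 65, max: 75, points: 1}
      - {min: 75, max: .inf, points: 8}
  - covariate: cd4
    type: interval
    intervals:
      - {min: 0, max: 200, points: 12}
      - {min: 200, max: 350, points: 5}
      - {min: 350, max: 500, points: 2}
      - {min: 500, max: .inf, points: 0}
  - covariate: non_hiv_cancer
    type: boolean
    points_if_true: 9
  - covariate: cvd
    type: boolean
    points_if_true: 8
  - covariate: egfr
    type: interval
    intervals:
      - {min: 0, max: 30, points: 16}
      - {min: 30, max: 60, points: 5}
      - {min: 60, max: .inf, points: 0}
  - covariate: cirrhosis
    type: boolean
    points_if_true: 9
  - covariate: low_bmi
    type: boolean
    points_if_true: 5
  - covariate: anemia
    type: boolean
    points_if_true: 4
  - covariate: hcv
    type: boolean
    points_if_true: 2
risk_groups:
  - {name: low, min_score: 0, max_score: 3, predicted_survival_5y: 0.95}
  - {name: moderate, min_score: 4, max_score: 13, predicted_survival_5y: 0.90}
  - {name: high, min_score: 14, max_score: 19, predicted_survival_5y: 0.80}
  - {name: very_high, min_score: 20, max_score: .inf, predicted_survival_5y: 0.53}
# Optional continuous-prediction block (derivation baseline survival at 5 years
# and log-hazard per point).  The derivation study's baseline survival function
# is not reprinted in accessible form; the slot is left empty so the engine
# falls back to the group-level mapping with a constant-hazard bridge.
continuous: null
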