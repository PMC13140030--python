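# VACS index 2.0: continuous score.  The published version (Tate et al.,
# AIDS 2019;33:903-912) scores age, CD4, HIV-1 RNA, haemoglobin, FIB-4,
# eGFR and HCV continuously and adds BMI, albumin, white-blood-cell count
# and platelet count.
#
# SYNTHETIC RECONSTRUCTION.  The published restricted-cubic-spline
# coefficients are not reproduced here; this asset keeps the correct
# variable list, risk directions and approximate magnitudes using
# piecewise-linear component functions (points interpolated between knots,
# clamped outside the knot range — the clamping is the stated input-domain
# restriction).  Totals are real-valued.  Suitable for computability
# accounting and rank-based (concordance) analyses; do not use for
# clinical scoring.
name: vacs2
kind: continuous
offset: 18.0
components:
  - covariate: age
    type: piecewise_linear
    knots: [[50.0, 0.0], [85.0, 30.0]]
  - covariate: cd4
    type: piecewise_linear
    knots: [[0.0, 30.0], [700.0, 0.0]]
  - covariate: hiv_rna
    type: piecewise_linear
    log10_x: true
    knots: [[1.7, 0.0], [5.0, 12.0]]
  - covariate: hemoglobin
    type: piecewise_linear
    knots: [[10.0, 24.0], [16.0, 0.0]]
  - covariate: fib4
    type: piecewise_linear
    knots: [[1.0, 0.0], [7.25, 25.0]]
  - covariate: egfr
    type: piecewise_linear
    knots: [[0.0, 30.0], [90.0, 0.0]]
  - covariate: hcv
    type: boolean
    points_if_true: 4
  - covariate: albumin_gdl
    type: piecewise_linear
    knots: [[2.5, 18.0], [4.5, 0.0]]
  - covariate: wbc
    type: piecewise_linear
    knots: [[2.5, 10.0], [5.5, 0.0], [10.0, 0.0], [14.0, 9.0]]
  - covariate: bmi
    type: piecewise_linear
    knots: [[15.0, 12.0], [25.0, 0.0]]
  - covariate: platelets
    type: piecewise_linear
    knots: [[50.0, 12.0], [180.0, 0.0]]
risk_groups: null
continuous: null
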