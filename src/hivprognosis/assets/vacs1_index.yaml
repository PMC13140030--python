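# VACS index 1.0: categorical points over age, CD4, HIV-1 RNA, haemoglobin,
# FIB-4, eGFR and HCV co-infection.  Transcribed from the published index
# (Justice et al., J Acquir Immune Defic Syndr 2013;62:149-163; the point
# table is reproduced widely, e.g. in the VACS online calculator).
#
# Interval convention: [min, max), half-open on the right; published band
# edges like "12-13.9" are encoded as [12, 14).
name: vacs1
kind: categorical_points
components:
  - covariate: age
    type: interval
    intervals:
      - {min: 0, max: 50, points: 0}
      - {min: 50, max: 65, points: 12}
      - {min: 65, max: .inf, points: 27}
  - covariate: cd4
    type: interval
    intervals:
      - {min: 0, max: 50, points: 29}
      - {min: 50, max: 100, points: 28}
      - {min: 100, max: 200, points: 10}
      - {min: 200, max: 350, points: 6}
      - {min: 350, max: 500, points: 6}
      - {min: 500, max: .inf, points: 0}
  - covariate: hiv_rna
    type: interval
    intervals:
      - {min: 0, max: 500, points: 0}
      - {min: 500, max: 100000, points: 7}
      - {min: 100000, max: .inf, points: 14}
  - covariate: hemoglobin
    type: interval
    intervals:
      - {min: 0, max: 10, points: 38}
      - {min: 10, max: 12, points: 22}
      - {min: 12, max: 14, points: 10}
      - {min: 14, max: .inf, points: 0}
  - covariate: fib4
    type: interval
    intervals:
      - {min: 0, max: 1.45, points: 0}
      - {min: 1.45, max: 3.25, points: 6}
      - {min: 3.25, max: .inf, points: 25}
  - covariate: egfr
    type: interval
    intervals:
      - {min: 0, max: 30, points: 25}
      - {min: 30, max: 45, points: 8}
      - {min: 45, max: 60, points: 6}
      - {min: 60, max: .inf, points: 0}
  - covariate: hcv
    type: boolean
    points_if_true: 5
risk_groups: null
continuous: null
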