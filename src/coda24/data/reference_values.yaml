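# Reference estimates bundled for the executable worked example.
#
# geometric_means: compositional centres (per-behaviour geometric means,
#   linearly adjusted to sum to 1440 min/day) of a published school cohort
#   of 359 UK children and adolescents, overall and by stratum.
# beta1: first-pivot ILR regression coefficients (with standard errors)
#   from the corresponding mixed models, reported only for outcomes whose
#   omnibus composition test was significant.  Each quadruple is in
#   canonical behaviour order (sleep, st, lpa, mvpa) and should sum to ~0
#   up to 2-dp rounding.
# Outcomes are motor-competence circuit scores: overall (0-54), process,
# product and time (each 0-18).
part_order: [sleep, st, lpa, mvpa]
total_minutes: 1440
geometric_means:
  all_schools:      [543.2, 635.8, 210.1, 50.9]
  primary_all:      [588.1, 580.6, 211.2, 60.1]
  secondary_all:    [499.3, 693.6, 205.6, 41.6]
  all_girls:        [544.6, 639.6, 210.8, 44.9]
  primary_girls:    [581.7, 592.8, 212.8, 52.6]
  secondary_girls:  [495.9, 701.0, 206.8, 36.3]
  all_boys:         [541.9, 632.7, 208.4, 57.0]
  primary_boys:     [567.3, 598.9, 210.5, 63.3]
  secondary_boys:   [502.8, 684.8, 204.1, 48.4]
beta1:
  all_schools:
    overall: {coef: [-2.45, -0.60, -1.76, 4.81], se: [2.25, 1.80, 2.64, 1.37]}
    process: {coef: [-1.00, -0.52, -0.86, 2.40], se: [0.96, 0.77, 1.13, 0.59]}
    time:    {coef: [-0.43, -0.03, -0.58, 1.04], se: [0.64, 0.51, 0.75, 0.39]}
  primary_all:
    time:    {coef: [1.52, -1.54, -1.72, 1.74], se: [1.22, 1.05, 1.04, 0.64]}
  secondary_all:
    overall: {coef: [-7.34, -0.26, 3.06, 4.54], se: [2.92, 2.22, 4.21, 1.87]}
    process: {coef: [-2.63, -0.50, 0.45, 2.68], se: [1.29, 0.98, 1.86, 0.83]}
    product: {coef: [-3.17, 0.11, 1.48, 1.58], se: [1.52, 1.15, 2.19, 0.97]}
  all_girls:
    overall: {coef: [-8.33, -0.05, 5.78, 2.60], se: [4.29, 3.92, 3.69, 1.89]}
    process: {coef: [-3.48, 0.09, 1.67, 1.73], se: [1.87, 1.70, 1.62, 0.83]}
    product: {coef: [-4.72, 0.75, 3.39, 0.57], se: [2.23, 2.04, 1.92, 0.98]}
  primary_girls:
    product: {coef: [-6.07, 1.70, 7.71, -3.34], se: [3.43, 2.82, 2.53, 1.60]}
  secondary_girls:
    overall: {coef: [-14.33, 3.76, 5.86, 4.72], se: [6.16, 6.43, 7.03, 2.82]}
    process: {coef: [-5.64, 0.94, 1.79, 2.90], se: [2.75, 2.87, 3.14, 1.26]}
    product: {coef: [-7.69, 3.11, 2.71, 1.86], se: [3.18, 3.31, 3.62, 1.45]}
  all_boys:
    overall: {coef: [0.56, -0.26, -7.28, 6.98], se: [2.88, 2.08, 3.72, 2.02]}
    process: {coef: [0.20, -0.34, -2.86, 3.00], se: [1.19, 0.86, 1.54, 0.83]}
    time:    {coef: [-0.55, 0.08, -1.19, 1.67], se: [0.88, 0.64, 1.14, 0.62]}
  primary_boys:
    overall: {coef: [9.97, -4.65, -12.67, 7.34], se: [5.52, 4.86, 5.01, 3.11]}
    process: {coef: [2.82, -0.94, -4.81, 2.93], se: [2.29, 2.00, 2.08, 1.29]}
    product: {coef: [5.59, -2.34, -5.13, 1.88], se: [2.63, 2.31, 2.38, 1.48]}
    time:    {coef: [1.99, -1.63, -2.95, 2.59], se: [1.75, 1.50, 1.58, 0.99]}
  secondary_boys:
    process: {coef: [-1.81, -0.63, 0.23, 2.20], se: [1.50, 0.97, 2.37, 1.15]}
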