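# Seven-trait seedling salt-tolerance model published for a 318-genotype
# Miscanthus sacchariflorus / M. lutarioriparius panel (fit on 303 genotypes).
# Units: SNC/RNC/RKC in mg/g dry mass, RWC in %, RNIL/RGR dimensionless, Sen 1-9.
intercept: 0.6895
predictors: [SNC, RNIL, RWC, RGR, RKC, Sen, RNC]
coefficients: [-0.0012, 0.1242, 0.0057, 0.0516, -0.0023, -0.0202, -0.0010]
diagnostics:
  r_squared: 0.962
  intercept_stderr: 0.0108
  stderr: [0.0000, 0.0062, 0.0002, 0.0033, 0.0002, 0.0013, 0.0001]
  t: [-25.48, 20.17, 23.82, 15.63, -14.90, -16.06, -12.39]
  standardized_beta: [-0.4140, 0.2689, 0.2912, 0.1884, -0.1793, -0.2791, -0.1601]
  n: 303
  mode: published
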