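# Baseline coefficients for the comparison RBE models.
#
# wedenberg / mcnamara: values from the original publications.
# mairani: package-chosen default coefficients for the documented
#   nonlinear-in-LET, (alpha/beta)_x-dependent parameterization; they are
#   NOT transcribed from the original publication and exist only so that
#   retraining starts from an explicit, versioned baseline.
version: 1
wedenberg:
  q: 0.434        # Gy * um / keV
mcnamara:
  p0: 0.99064     # dimensionless
  p1: 0.35605     # Gy * um / keV
  p2: 1.1012      # dimensionless
  p3: -0.0038703  # Gy^-0.5 * um / keV
mairani:
  k1: 0.40        # Gy * um / keV
  k2: 0.015       # um / keV
  k3: 0.003       # um / keV
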