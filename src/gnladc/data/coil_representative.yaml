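# Representative whole-body 3T gradient coil model.
#
# Real solid-harmonic expansion, Schmidt semi-normalized associated
# Legendre functions without the Condon-Shortley phase; each term is
# scaled by R0^(n-1) so the coefficients are dimensionless.  Rows are
# [order n, degree m, cos|sin, coefficient].
#
# The true spherical-harmonic coefficients of clinical systems are
# proprietary; this model is calibrated so the trace b-value bias spans
# about -10% (at 200 mm S-I) to +8.5% (at 200 mm R-L), the regime
# reported for torso-size fields of view, with bias decreasing along
# S-I and increasing along R-L away from the isocenter.
name: representative-3T-wholebody
R0_mm: 250.0
coils:
  x:
  - [1, 1, cos, 1.0]
  - [3, 1, cos, -0.05]
  - [5, 1, cos, 0.015]
  y:
  - [1, 1, sin, 1.0]
  - [3, 1, sin, -0.05]
  - [5, 1, sin, 0.015]
  z:
  - [1, 0, cos, 1.0]
  - [3, 0, cos, -0.027]
  - [5, 0, cos, 0.002]
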