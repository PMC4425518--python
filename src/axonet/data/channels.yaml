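# Voltage-gated channel kinetics and base densities for the model dIN.
#
# Rate functions have the form  rate(V) = (A + B*V) / (C + exp((D + V)/E))
# with V in mV and rates in 1/ms.  The calcium beta_m rate is piecewise,
# switching parameter sets at -25 mV.
#
# Note: the sodium alpha_m E parameter is stored as -12.56.  The positive
# value sometimes quoted for this kinetic set makes the activation gate
# open at hyperpolarised potentials (m_inf ~ 0.7 at rest), which is
# inconsistent with every reported property of the cell; the negative sign
# gives the standard sigmoidal activation curve.
channels:
  lk:
    kind: lk
    reversal_potential: -52.0       # mV
    base_density: 0.25              # mS/cm^2 (uniform-leak passive value)
    gates: []
  na:
    kind: na
    reversal_potential: 50.0        # mV
    base_density: 10.0              # mS/cm^2
    gates:
      - name: m_na
        exponent: 3
        alpha: {A: 8.67, B: 0.0, C: 1.0, D: -1.01, E: -12.56}
        beta:  {A: 3.82, B: 0.0, C: 1.0, D: 9.01, E: 9.69}
      - name: h_na
        exponent: 1
        alpha: {A: 0.08, B: 0.0, C: 0.0, D: 38.88, E: 26.0}
        beta:  {A: 4.08, B: 0.0, C: 1.0, D: -5.09, E: -10.21}
  kf:
    kind: kf
    reversal_potential: -81.5       # mV
    base_density: 2.5               # mS/cm^2
    gates:
      - name: n_kf
        exponent: 4
        alpha: {A: 5.06, B: 0.0666, C: 5.12, D: -18.396, E: -25.42}
        beta:  {A: 0.505, B: 0.0, C: 0.0, D: 28.7, E: 34.6}
  ks:
    kind: ks
    reversal_potential: -81.5       # mV
    base_density: 2.0               # mS/cm^2
    gates:
      - name: n_ks
        exponent: 2
        alpha: {A: 0.462, B: 8.204e-3, C: 4.59, D: -4.21, E: -11.97}
        beta:  {A: 0.0924, B: -1.353e-3, C: 1.615, D: 2.1e+5, E: 3.33e+5}
  ca:
    kind: ca
    permeability: 0.016             # cm/s (GHK)
    base_density: 1.0               # dimensionless multiplier on permeability
    gates:
      - name: m_ca
        exponent: 2
        alpha: {A: 4.05, B: 0.0, C: 1.0, D: -15.32, E: -13.57}
        beta:  {A: 1.24, B: 0.093, C: -1.0, D: 10.63, E: 1.0}       # V < -25 mV
        beta_high: {A: 1.28, B: 0.0, C: 1.0, D: 5.39, E: 12.11}     # V > -25 mV

# Density multipliers swept in the channel-density study, and the values
# chosen for the final model.
multipliers:
  ca: {tested: [0.0, 0.5, 1.0, 1.5], chosen: 1.0}
  kf: {tested: [0.5, 1.0, 1.5], chosen: 1.0}
  ks: {tested: [0.5, 1.0, 1.5], chosen: 1.0}
  na: {tested: [0.0, 0.5, 1.0, 1.5, 2.0, 3.0], chosen: 3.0}
  lk: {tested: [0.5, 1.0, 1.5], chosen: 1.0}
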