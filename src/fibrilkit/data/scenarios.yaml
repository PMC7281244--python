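# Fibrillation scenario table: logistic parameters of the bound-dye fraction
# trajectory f(t) for every protein / trehalose / NaCl combination studied.
#
# Encoded qualitative orderings:
#   * NaCl shortens the lag and speeds nucleation for both proteins;
#   * trehalose without salt blocks lysozyme fibrillation (plateau ~0),
#     and with salt only mildly slows the elongation phase;
#   * trehalose extends the insulin lag from 80 to about 240 min and lowers
#     its final plateau by about 10%; 100 mM NaCl erases both effects.
#
# lag_min: tangent-intercept lag time (minutes); rate_per_min: logistic rate;
# plateau: final bound fraction in [0, 1].  t_half = lag + 2/rate.
lysozyme:
  trehalose_0:
    nacl_0: {lag_min: 60.0, rate_per_min: 0.040, plateau: 0.80}
    nacl_25: {lag_min: 25.0, rate_per_min: 0.060, plateau: 0.85}
    nacl_50: {lag_min: 10.0, rate_per_min: 0.080, plateau: 0.90}
  trehalose_150:
    nacl_0: {lag_min: 0.0, rate_per_min: 0.001, plateau: 0.02, blocked: true}
    nacl_25: {lag_min: 35.0, rate_per_min: 0.050, plateau: 0.80}
    nacl_50: {lag_min: 18.0, rate_per_min: 0.070, plateau: 0.88}
  trehalose_300:
    nacl_0: {lag_min: 0.0, rate_per_min: 0.001, plateau: 0.02, blocked: true}
    nacl_25: {lag_min: 45.0, rate_per_min: 0.045, plateau: 0.78}
    nacl_50: {lag_min: 18.0, rate_per_min: 0.070, plateau: 0.87}
insulin:
  trehalose_0:
    nacl_0: {lag_min: 80.0, rate_per_min: 0.050, plateau: 0.80}
    nacl_100: {lag_min: 20.0, rate_per_min: 0.080, plateau: 0.85}
  trehalose_300:
    nacl_0: {lag_min: 240.0, rate_per_min: 0.040, plateau: 0.72}
    nacl_100: {lag_min: 25.0, rate_per_min: 0.075, plateau: 0.84}
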