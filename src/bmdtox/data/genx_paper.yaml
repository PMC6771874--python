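# Pipeline configuration reproducing the GenX (HFPO-DA) chronic-bioassay
# reference-dose chain: cystic focal degeneration incidence in male rats
# from the 2-year study -> frequentist and Bayesian-model-average BMD10 ->
# deterministic RfD (allometric HED / composite UFs) and probabilistic RfD
# -> drinking-water MCLG.
#
# The rat body weight (0.29 kg) is the value back-calculated from the
# published HED of 1.6 mg/kg/day for a BMDL10 of 6.3 mg/kg/day under
# BW^(3/4) scaling; the study itself does not print a reference weight, so
# any reproduction must state the weight used (this file is that statement).
seed: 0
dataset:
  fixture: cystic_focal_degeneration
bmr:
  kind: extra_risk
  level: 0.10
confidence: 0.95
frequentist:
  restricted: true
bayesian:
  draws: 100000
hed:
  animal_bw: 0.29
  human_bw: 70.0
  species: rat (chronic bioassay)
uncertainty_factors:
  uf_a: 3    # residual interspecies, after allometric scaling
  uf_h: 10   # human variability
  uf_s: 1    # chronic study: no subchronic-to-chronic extrapolation
  uf_d: 3    # database: key studies unpublished though publicly available
probabilistic:
  target_incidence: 0.01
  uf_d: 3
  draws: 1000000
guideline:
  rfd_basis: probabilistic
  body_weight: 70.0
  drinking_water_intake: 2.0
  rsc: 0.2
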