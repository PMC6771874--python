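# Default lognormal adjustment-factor parameters for probabilistic
# reference-dose derivation, version 1.
#
# These follow the approximate probabilistic hazard-characterization
# framework (WHO/IPCS-style) in which each adjustment factor is a lognormal
# stated as a median and a P95/P50 ratio:
#
#   af_bw   — allometric body-weight scaling.  Daily dose is assumed to
#             scale as BW^(1 - exponent) per animal, i.e. the per-kg dose
#             divisor is (BW_human/BW_animal)^exponent.  The framework's
#             central allometric exponent for dose is 0.7 (divisor exponent
#             0.3), with sampling uncertainty on the exponent
#             (exponent_sd, one SD) propagated into the factor:
#             P95/P50 = ratio^(1.6449 * exponent_sd).
#   af_tktd — residual interspecies toxicokinetic/toxicodynamic
#             differences after allometric scaling; median 1 (allometry is
#             unbiased on average) with a threefold P95/P50.
#   af_h    — human variability: the ratio between the median-human
#             equipotent dose and that of the most-sensitive I% of the
#             population, keyed by target incidence I.
#
# The 1%-incidence human-variability entry and the overall chain were
# validated against the published 5th percentile of HD_10^1% (0.040
# mg/kg/day) for the 2-year rat bioassay liver-lesion BMA pair (14.2, 6.4).
version: 1
af_bw:
  exponent: 0.3        # divisor exponent: 1 - 0.7 allometric dose exponent
  exponent_sd: 0.033   # SD of the allometric exponent
af_tktd:
  p50: 1.0
  p95_over_p50: 3.0
af_h:
  by_incidence:
    "0.01":
      p50: 9.7
      p95_over_p50: 4.3
    "0.05":
      p50: 4.3
      p95_over_p50: 2.9
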