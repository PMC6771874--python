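# Default priors for the Bayesian dichotomous suite, version 1.
#
# Each entry is a Normal prior on the stated scale ("logit" for probability
# parameters, "log" for slopes/powers -> lognormal, "identity" for
# intercepts), listed in the model's parameter order.  The settings follow
# the weakly-informative convention of the standard benchmark-dose software
# family: a diffuse logistic-normal background, lognormal shape priors with
# medians near 1.5-2 that softly discourage supralinear low-dose curvature,
# and diffuse slope priors.  The shape-prior width (sigma 0.35) was
# validated against the published Bayesian model-average BMD10/BMDL10 for
# the 2-year rat bioassay liver-lesion incidence data.
#
# The four-parameter dichotomous Hill model is omitted from the default
# averaging table: with the common four-dose-group design it is saturated
# and its Laplace evidence is unreliable.  Add it explicitly in a custom
# config if the design has five or more groups.
version: 1
priors:
  quantal_linear:
    - {param: background, scale: logit, mu: 0.0, sigma: 2.0}
    - {param: slope, scale: log, mu: 0.0, sigma: 2.0}
  multistage_k:  # degree 2
    - {param: background, scale: logit, mu: 0.0, sigma: 2.0}
    - {param: beta1, scale: log, mu: 0.0, sigma: 2.0}
    - {param: beta2, scale: log, mu: 0.0, sigma: 2.0}
  log_logistic:
    - {param: background, scale: logit, mu: 0.0, sigma: 2.0}
    - {param: intercept, scale: identity, mu: 0.0, sigma: 2.0}
    - {param: slope, scale: log, mu: 0.693147, sigma: 0.35}
  log_probit:
    - {param: background, scale: logit, mu: 0.0, sigma: 2.0}
    - {param: intercept, scale: identity, mu: 0.0, sigma: 2.0}
    - {param: slope, scale: log, mu: 0.693147, sigma: 0.35}
  weibull:
    - {param: background, scale: logit, mu: 0.0, sigma: 2.0}
    - {param: power, scale: log, mu: 0.424264, sigma: 0.35}
    - {param: slope, scale: log, mu: 0.0, sigma: 1.5}
  gamma:
    - {param: background, scale: logit, mu: 0.0, sigma: 2.0}
    - {param: power, scale: log, mu: 0.693147, sigma: 0.35}
    - {param: slope, scale: log, mu: 0.0, sigma: 1.5}
  logistic:
    - {param: intercept, scale: identity, mu: 0.0, sigma: 2.0}
    - {param: slope, scale: log, mu: 0.0, sigma: 2.0}
  probit:
    - {param: intercept, scale: identity, mu: 0.0, sigma: 2.0}
    - {param: slope, scale: log, mu: 0.0, sigma: 2.0}
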