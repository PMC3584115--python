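{
  "terms": [
    {"name": "Intercept", "coef": 10.20, "se": 2.05},
    {"name": "gating", "coef": 1.00, "se": 0.48},
    {"name": "cpt_d", "coef": -0.37, "se": 0.22},
    {"name": "arithmetic", "coef": -0.32, "se": 0.10},
    {"name": "block_design", "coef": 0.28, "se": 0.14},
    {"name": "piq", "coef": -0.19, "se": 0.03},
    {"name": "smoker", "coef": 1.58, "se": 0.80}
  ],
  "outcome": "schizophrenia",
  "gating_cutoff": 0.4,
  "notes": {
    "piq_coefficient_discrepancy": "The published source prints the Performance IQ coefficient as -0.19 (SE 0.03) but its odds ratio as 0.90 (0.86-0.95); exp(-0.19) = 0.83, which is inconsistent with the printed odds ratio (0.90 corresponds to a coefficient of about -0.105). Scoring group-mean covariates with -0.19 yields near-zero predicted probabilities. The printed -0.19 is stored verbatim; no correction is applied.",
    "smoker_or_rounding": "The printed smoking odds ratio 4.87 differs slightly from exp(1.58) = 4.85; presumed rounding in the source.",
    "term_mapping": "gating = 1 if the capped S2/S1 gating ratio exceeds gating_cutoff; cpt_d is the undegraded CPT sensitivity z-score; arithmetic and block_design are WAIS-III scaled scores; piq is WAIS-III Performance IQ; smoker = 1 for current smokers."
  }
}
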