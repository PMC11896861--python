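# Synthetic population profile emulating the Xi'an field survey: latent
# satisfaction means per tertiary indicator set to the published defuzzified
# tertiary scores, demographic strata at the published respondent proportions.
# The response-generating model itself is a stand-in (the study did not
# publish one); see docs/methods.md.
version: 1
n: 430
dispersion: 0.8
missing_rate: 0.0
family: normal
latent_means:
  A11: 3.1442
  A12: 3.1651
  A21: 2.9790
  A22: 3.2372
  A31: 3.2071
  A32: 3.2234
  A33: 3.2114
  B11: 3.8815
  B12: 3.8116
  B21: 3.4767
  B22: 3.6022
  C11: 3.6675
  C12: 3.3744
  C13: 3.3099
  C21: 3.2303
  C22: 3.2976
  C23: 3.1347
  C31: 3.0837
  C32: 3.0742
  C41: 3.7348
  C42: 3.2930
  D11: 3.6536
  D12: 3.7349
  D13: 3.2931
  D14: 3.5650
  D21: 3.5697
  D22: 3.6511
  E11: 3.3838
  E12: 3.3652
  E13: 3.4115
  E21: 3.3045
  E22: 3.3257
  E23: 3.0862
  E24: 3.4722
  E25: 3.5255
  E31: 3.5347
  E32: 3.4535
demographics:
  gender:
    Male: 51.85
    Female: 48.15
  age:
    60-64 years: 23.84
    65-69 years: 27.08
    70-74 years: 24.31
    75 and above: 24.77
  income:
    0-999 Yuan: 16.67
    1000-1999 Yuan: 29.63
    2000-3999 Yuan: 41.90
    4000 Yuan and above: 11.81
  health:
    Health: 23.84
    Good: 40.05
    Fair: 27.78
    Unhealthy: 8.33
  residence:
    Living with spouse: 42.13
    Living with children: 21.53
    Living alone: 19.68
    Living with spouse and children: 14.35
    Other: 2.31
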