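# Point-value exposure parameterization for the deterministic risk engine.
#
# US EPA RAGS residential soil-exposure defaults; receptor durations follow
# the study-design age bands (children 1-17 y, adults 18-65 y).  Units:
# IngR mg day^-1, InhR m^3 day^-1, SA cm^2, AF mg cm^-2 day^-1, EF days
# year^-1, ED years, BW kg, AT_ca days, PEF m^3 kg^-1.  The averaging time
# for non-carcinogens is ED*365 days and is derived, not configured.

child:
  IngR: 200.0
  InhR: 7.6
  SA: 2800.0
  AF: 0.2
  EF: 350.0
  ED: 17.0
  BW: 15.0
  AT_ca: 25550.0
  PEF: 1.36e+9
adult:
  IngR: 100.0
  InhR: 20.0
  SA: 5700.0
  AF: 0.07
  EF: 350.0
  ED: 47.0
  BW: 70.0
  AT_ca: 25550.0
  PEF: 1.36e+9
unit_conv: 1.0e-6
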