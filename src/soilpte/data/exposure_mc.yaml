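# Probabilistic exposure parameterization for the Monte-Carlo risk engine.
#
# Distributions follow common practice in probabilistic soil health-risk
# assessment: soil ingestion rate log-normal (arithmetic mean at the RAGS
# point value), exposure frequency uniform between a half-year outdoor
# scenario and near-daily contact, body weight normal.  Parameters without
# an established distribution are held at their point values.  Exposure
# durations use the EPA default receptor bands (child 6 y, adult 24 y).

child:
  IngR: {dist: lognormal, mean: 200.0, sd: 60.0}
  InhR: 7.6
  SA: 2800.0
  AF: 0.2
  EF: {dist: uniform, low: 180.0, high: 365.0}
  ED: 6.0
  BW: {dist: normal, mean: 15.0, sd: 2.0}
  AT_ca: 25550.0
  PEF: 1.36e+9
adult:
  IngR: {dist: lognormal, mean: 100.0, sd: 30.0}
  InhR: 20.0
  SA: 5700.0
  AF: 0.07
  EF: {dist: uniform, low: 180.0, high: 365.0}
  ED: 24.0
  BW: {dist: normal, mean: 70.0, sd: 7.0}
  AT_ca: 25550.0
  PEF: 1.36e+9
unit_conv: 1.0e-6
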