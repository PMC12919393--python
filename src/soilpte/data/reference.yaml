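# Reference tables for the pollution and ecological-risk indices.
#
# background: local geochemical background values Bn (mg kg^-1).
# toxic_response: Hakanson toxic-response coefficients Tr (unitless).
# guidelines: soil-quality guideline values (mg kg^-1); absent entries mean
#   the guideline does not define a value for that element.
# mdl: method detection limits (mg kg^-1) of the emulated analytical method.

background:
  Hg: 0.5
  As: 3.4
  Zn: 56.9
  Pb: 66.6
  Co: 23.2
  Cd: 0.95
  Ni: 67.8
  Cr: 169.9
  Cu: 73.6

toxic_response:
  Hg: 40
  Cd: 30
  As: 10
  Pb: 5
  Cu: 5
  Ni: 5
  Co: 5
  Cr: 2
  Zn: 1

guidelines:
  INBV:  # Indian natural background values
    Zn: 22.1
    Pb: 13.1
    Co: 15.2
    Ni: 27.7
    Cr: 114
    Cu: 56.5
  ILS:  # Indian limits for soil
    Hg: 0.2
    As: 5
    Zn: 250
    Pb: 5
    Cd: 1
    Ni: 20
    Cr: 5
    Cu: 25
  WHO:
    Zn: 50
    Pb: 85
    Cd: 0.8
    Ni: 35
    Cr: 100
    Cu: 36
  CCME:
    Hg: 6.6
    As: 12
    Zn: 200
    Pb: 70
    Cd: 1.4
    Ni: 50
    Cr: 64
    Cu: 91

mdl:
  Hg: 0.005
  As: 0.003
  Zn: 0.01
  Pb: 0.021
  Co: 0.0027
  Cd: 0.015
  Ni: 0.002
  Cr: 0.002
  Cu: 0.002
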