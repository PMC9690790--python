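# Indicator registry: 16 indicators of the stabilization-effect evaluation
# system, with response-curve thresholds in the units the curve consumes.
#
# Groups: I  = national-standard indicators (hard compliance limit),
#         II = farmland classification-management indicators,
#         III = dynamic indicators scored via derived quantities.
#
# Entries flagged `assumption: true` are back-computed values, not published
# facts: the biomass local reference (1.27 g) and its unit-capped curve
# (H = 1.0 on the ratio scale) are the values consistent with the published
# worked-example scores.
#
# Heavy-metal thresholds default to cadmium; `by_metal` blocks may override
# L/H (and the compliance limit) per metal for other contaminants — such
# values are user input, none are shipped here beyond Cd.

indicators:
  pH:
    group: II
    curve: parabolic
    transform: raw
    units: ""
    L1: 3.0
    L: 5.0
    H: 7.0
    H1: 9.0
  SOM:
    group: II
    curve: s_type
    transform: raw
    units: g/kg
    L: 6.0
    H: 40.0
  CEC:
    group: II
    curve: s_type
    transform: raw
    units: cmol(+)/kg
    L: 10.0
    H: 20.0
  A-N:
    group: II
    curve: s_type
    transform: raw
    units: mg/kg
    L: 30.0
    H: 150.0
  A-P:
    group: II
    curve: s_type
    transform: raw
    units: mg/kg
    L: 3.0
    H: 40.0
  A-K:
    group: II
    curve: s_type
    transform: raw
    units: mg/kg
    L: 30.0
    H: 200.0
  AHM:
    # available heavy metal, scored on the reduction rate alpha (percent);
    # rising ramp: the bigger the reduction, the better
    group: III
    curve: s_type
    transform: reduction_rate
    units: "%"
    L: 0.0
    H: 75.0
  THM:
    # total heavy metal in soil; Cd screening/control values
    group: I
    curve: inverse_s
    transform: raw
    units: mg/kg
    L: 0.6
    H: 3.0
    compliance_limit: 0.6
    by_metal:
      Cd: {L: 0.6, H: 3.0, compliance_limit: 0.6}
  biomass:
    group: II
    curve: s_type
    transform: ratio_to_reference
    units: ratio
    L: 0.0
    H: 1.0
    reference_value: 1.27
    assumption: true
  production:
    group: II
    curve: s_type
    transform: ratio_to_reference
    units: ratio
    L: 0.0
    H: 0.9
  hm_edible:
    # heavy metal in the edible part; Cd food-safety limit
    group: I
    curve: inverse_s
    transform: raw
    units: mg/kg
    L: 0.0
    H: 0.2
    compliance_limit: 0.2
    by_metal:
      Cd: {L: 0.0, H: 0.2, compliance_limit: 0.2}
  hm_above_ground:
    # scored on the bio-accumulation factor (percent)
    group: III
    curve: inverse_s
    transform: baf
    units: "%"
    L: 10.0
    H: 100.0
  hm_roots:
    group: III
    curve: inverse_s
    transform: baf
    units: "%"
    L: 10.0
    H: 100.0
  hm_amendment:
    # heavy metal in the amendment; fertilizer toxic-substance limit
    group: I
    curve: inverse_s
    transform: raw
    units: mg/kg
    L: 0.0
    H: 10.0
    compliance_limit: 10.0
  cost:
    # cost over crop revenue
    group: II
    curve: inverse_s
    transform: ratio_to_reference
    units: ratio
    L: 0.5
    H: 0.7
  stability:
    group: III
    curve: s_type
    transform: raw
    units: years
    L: 0.0
    H: 3.0
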