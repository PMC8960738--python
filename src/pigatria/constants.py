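"""Physical constants (units chosen so that voltages come out in mV)."""

#: Gas constant, J mol^-1 K^-1
R_GAS = 8.3143

#: Faraday constant, C mmol^-1
FARADAY = 96.4867

#: Body temperature, K (37 degrees C)
BODY_TEMPERATURE = 310.15
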