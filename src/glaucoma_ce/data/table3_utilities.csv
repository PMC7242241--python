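# Health-state utility weights (Health Utilities Index 3, German POAG sample).
# The blindness utility is not stored: it is derived at load time by ordinary
# least-squares extrapolation of the three POAG stage utilities, following the
# decreasing trend (reported rounded to 2 decimals). Its SD is stored for
# probabilistic analysis.
state,utility,utility_sd
early,0.85,0.15
moderate,0.75,0.23
advanced,0.58,0.32
blind,,0.40
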