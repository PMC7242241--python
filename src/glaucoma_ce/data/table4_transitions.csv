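# Yearly POAG stage transition probabilities (percent) for standard of care,
# derived from 5-year German observational percentages converted to annual
# probabilities. Stay and progress percentages sum to 100 before mortality.
stage,stay_pct,progress_pct
early,91.5,8.5
moderate,87.6,12.4
advanced,81.4,18.6
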