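# Stage-dependent annual direct medical costs, 2019 EUR (mean and SD), by
# component. Totals are recomputed by the loader from the components; the
# published moderate-stage total prints 356.12 while these components sum to
# 356.13 (a 1-cent rounding discrepancy in the source).
stage,component,mean,sd
early,medications,230.22,145.40
early,ocular_examinations,34.54,21.23
early,ophthalmologist_visits,58.43,29.21
moderate,medications,266.58,145.40
moderate,ocular_examinations,32.74,16.91
moderate,ophthalmologist_visits,56.81,21.10
advanced,medications,411.98,230.22
advanced,ocular_examinations,34.90,22.30
advanced,ophthalmologist_visits,66.54,38.95
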