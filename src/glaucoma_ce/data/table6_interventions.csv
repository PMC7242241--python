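# One-off intervention costs, 2019 EUR (German statutory fee schedule).
# Totals (MIGS procedure + cataract surgery) are recomputed by the loader.
strategy,migs_procedure,cataract_surgery
cataract_alone,0,224.84
one_device,413.58,224.84
two_devices,712.50,224.84
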