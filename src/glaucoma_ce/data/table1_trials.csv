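# One-year IOP summaries (mmHg, mean and SD) per arm of the randomized trials
# comparing a MIGS device combined with cataract surgery (intervention) against
# cataract surgery alone (control). Arm sizes were not published alongside the
# summaries and are left blank.
# Provenance note: the Craven control follow-up mean was printed as "17. (3.1)"
# in the source table; it is encoded here as 17.0 mmHg.
study_id,strategy,arm,n,mean_baseline,sd_baseline,mean_followup,sd_followup
craven2012,one_tmbs,intervention,,18.6,3.4,17.0,2.8
craven2012,one_tmbs,control,,17.9,3.0,17.0,3.1
fea2010,one_tmbs,intervention,,17.8,2.7,14.7,1.3
fea2010,one_tmbs,control,,16.7,3.0,15.6,1.1
fernandez2010,two_tmbs,intervention,,24.2,1.6,17.6,2.8
fernandez2010,two_tmbs,control,,23.6,1.5,19.8,2.3
pfeiffer2015,is,intervention,,18.9,3.3,16.1,3.0
pfeiffer2015,is,control,,18.6,3.8,16.0,2.8
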