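# Published 1-year mean IOP change from baseline (mmHg) per strategy, as
# estimated by the source analysis (anchored indirect comparison). The
# cataract-alone row is the common-comparator anchor used by the default
# pipeline configuration; the remaining rows are expected outputs kept for
# cross-checking, never fed back into the computation.
strategy,mean,ci_low,ci_high,k,i2
cataract_alone,-2.05,-3.38,-0.72,4,81
one_tmbs,-3.15,-5.66,-0.64,2,39
two_tmbs,-4.85,-7.71,-1.99,1,
is,-2.25,-4.87,0.37,1,
one_or_two_tmbs,-3.87,-6.66,-1.08,3,97
migs,-3.49,-5.52,-1.46,4,97
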