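# label: glycerol_this_study
# substrate: glycerol
# uptake_rate: 2.42
# units: mmol.min-1.L-1
# note: the aco entry is recorded with weight 0; the carbon identity
# note: aco = uptake - acl of this network puts it at 0.98.
reaction	flux	weight	note
glyc_up	2.42	1	measured
aco	0.90	0	measured; identity value 0.98, recorded not fitted
acl	1.44	1	measured
cs	2.42	0.5	synthetic (carbon identity cs = uptake)
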