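# label: ethanol_this_study
# substrate: ethanol
# uptake_rate: 7.76
# units: mmol.min-1.L-1
reaction	flux	weight	note
etoh_up	7.76	1	measured
aco	3.00	1	measured (consistent with carbon identity aco = uptake - acl)
acl	4.76	1	measured
cs	7.76	0.5	synthetic (carbon identity cs = uptake)
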