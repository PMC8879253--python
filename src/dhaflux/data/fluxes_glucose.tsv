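# label: glucose_13C
# substrate: glucose
# uptake_rate: 3.58
# units: mmol.min-1.L-1
# note: uptake and ACL are measured anchors; the TCA (aco) entry is recorded
# note: with weight 0 because the carbon identity aco = 2*uptake - acl of this
# note: PPP-free network forbids it (docs/methods.md); cs follows from that
# note: identity and is synthetic.
reaction	flux	weight	note
glc_up	3.58	1	measured
aco	2.43	0	measured; carbon-infeasible here, recorded not fitted
acl	3.87	1	measured
cs	7.16	0.5	synthetic (carbon identity cs = 2*uptake)
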