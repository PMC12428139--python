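# Example binding-constants configuration (all Kd in mM).
#
# Representative 1:1 metal-ADP dissociation constants near 0.1-0.2 M ionic
# strength and neutral pH; edit to match the conditions of your assay.  The
# PEP dianion/trianion pK of 6.3 sets the ionized-substrate fraction.
kd_mg_adp: 0.25
kd_mn_adp: 0.10
pk_pep: 6.3
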