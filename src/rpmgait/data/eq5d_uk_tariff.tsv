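# UK EQ-5D-3L time-trade-off value set (MVH study): decrements from the
# full-health anchor of 1.0. "constant" applies once for any move away
# from state 11111; "N3" applies once if any dimension is at level 3.
# Dimensions: MO mobility, SC self-care, UA usual activities,
# PD pain/discomfort, AD anxiety/depression.
term	decrement
constant	0.081
MO2	0.069
MO3	0.314
SC2	0.104
SC3	0.214
UA2	0.036
UA3	0.094
PD2	0.123
PD3	0.386
AD2	0.071
AD3	0.236
N3	0.269
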