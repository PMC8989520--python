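a1	0	12
msr	12	42
msd	42	92
a2	92	104
term_site	52	53
branch_g	91	92
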