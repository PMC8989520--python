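length	count	frequency
37	1	0.0333333
38	2	0.0666667
39	9	0.3
40	6	0.2
41	7	0.233333
42	4	0.133333
43	1	0.0333333
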