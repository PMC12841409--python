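inversion	on	left_junction	right_junction	result
X2	X1	edge:5	pair:-2,7	X2
X0	X1	edge:3	edge:7	X0
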