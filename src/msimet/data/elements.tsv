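symbol	monoisotopic_mass
e-	0.0005485799091
H	1.0078250319
C	12.0
N	14.0030740042
O	15.9949146193
F	18.9984031621
Na	22.9897692820
Mg	23.9850416970
P	30.9737619984
S	31.9720711735
Cl	34.9688526940
K	38.9637064848
Ca	39.9625908560
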