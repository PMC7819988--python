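name	added	removed	charge	mode
[M+H]+	H	-	1	positive
[M+Na]+	Na	-	1	positive
[M+K]+	K	-	1	positive
[M-H]-	-	H	-1	negative
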