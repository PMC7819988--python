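name	formula	adduct	mode	mz
DHB [M+H]+	C7H6O4	[M+H]+	positive	155.033885
Carnitine	C7H15NO3	[M+H]+	positive	162.112470
DHB [M+Na]+	C7H6O4	[M+Na]+	positive	177.015829
Phosphocholine	C5H14NO4P	[M+H]+	positive	184.073321
Acetylcarnitine	C9H17NO4	[M+H]+	positive	204.123034
DHB cluster 273	C14H8O6	[M+H]+	positive	273.039364
DHB cluster 409	C21H12O9	[M+H]+	positive	409.055408
PC(32:0)	C40H80NO8P	[M+H]+	positive	734.569432
PC(34:1)	C42H82NO8P	[M+K]+	positive	798.540963
9-Aminoacridine	C13H10N2	[M-H]-	negative	193.077122
Peptide 409	C17H26N6O6	[M-H]-	negative	409.184106
ADP	C10H15N5O10P2	[M-H]-	negative	426.022139
ATP	C10H16N5O13P3	[M-H]-	negative	505.988470
Peptide 524	C23H39N7O7	[M-H]-	negative	524.283820
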