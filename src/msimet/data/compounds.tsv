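id	name	formula	class	adducts_pos	adducts_neg	is_matrix
gpc	Glycerophosphocholine	C8H20NO6P	GPC	[M+H]+;[M+Na]+	-	0
lpc_16_0	LysoPC(16:0)	C24H50NO7P	LPC	[M+H]+;[M+Na]+;[M+K]+	-	0
lpc_18_0	LysoPC(18:0)	C26H54NO7P	LPC	[M+H]+;[M+Na]+;[M+K]+	-	0
lpc_18_1	LysoPC(18:1)	C26H52NO7P	LPC	[M+H]+;[M+Na]+;[M+K]+	-	0
lpc_20_4	LysoPC(20:4)	C28H50NO7P	LPC	[M+Na]+;[M+H]+;[M+K]+	-	0
pc_30_0	PC(30:0)	C38H76NO8P	PC	[M+H]+;[M+Na]+;[M+K]+	-	0
pc_32_0	PC(32:0)	C40H80NO8P	PC	[M+H]+;[M+Na]+;[M+K]+	-	0
pc_34_1	PC(34:1)	C42H82NO8P	PC	[M+K]+;[M+H]+;[M+Na]+	-	0
pc_34_2	PC(34:2)	C42H80NO8P	PC	[M+H]+;[M+Na]+;[M+K]+	-	0
pc_36_2	PC(36:2)	C44H84NO8P	PC	[M+H]+;[M+Na]+;[M+K]+	-	0
pc_36_3	PC(36:3)	C44H82NO8P	PC	[M+H]+;[M+Na]+;[M+K]+	-	0
pc_36_4	PC(36:4)	C44H80NO8P	PC	[M+H]+;[M+Na]+;[M+K]+	-	0
pc_38_4	PC(38:4)	C46H84NO8P	PC	[M+H]+;[M+Na]+;[M+K]+	-	0
pc_38_6	PC(38:6)	C46H80NO8P	PC	[M+H]+;[M+Na]+;[M+K]+	-	0
pc_40_6	PC(40:6)	C48H84NO8P	PC	[M+H]+;[M+Na]+;[M+K]+	-	0
sm_d34_1	SM(d34:1)	C39H79N2O6P	SM	[M+H]+;[M+Na]+;[M+K]+	-	0
sm_d36_1	SM(d36:1)	C41H83N2O6P	SM	[M+H]+;[M+Na]+;[M+K]+	-	0
sm_d38_1	SM(d38:1)	C43H87N2O6P	SM	[M+H]+;[M+Na]+;[M+K]+	-	0
sm_d42_2	SM(d42:2)	C47H93N2O6P	SM	[M+H]+;[M+Na]+;[M+K]+	-	0
tg_52_2	TG(52:2)	C55H102O6	TG	[M+Na]+;[M+K]+	-	0
tg_54_3	TG(54:3)	C57H104O6	TG	[M+Na]+;[M+K]+	-	0
pa_34_1	PA(34:1)	C37H71O8P	PA	-	[M-H]-	0
pa_36_2	PA(36:2)	C39H73O8P	PA	-	[M-H]-	0
pa_38_4	PA(38:4)	C41H73O8P	PA	-	[M-H]-	0
ps_36_1	PS(36:1)	C42H80NO10P	PS	-	[M-H]-	0
ps_38_4	PS(38:4)	C44H78NO10P	PS	-	[M-H]-	0
ps_40_6	PS(40:6)	C46H78NO10P	PS	-	[M-H]-	0
adp	Adenosine diphosphate	C10H15N5O10P2	nucleotide	-	[M-H]-	0
atp	Adenosine triphosphate	C10H16N5O13P3	nucleotide	-	[M-H]-	0
a4p	Adenosine tetraphosphate	C10H17N5O16P4	nucleotide	-	[M-H]-	0
cmp	Cytidine monophosphate	C9H14N3O8P	nucleotide	-	[M-H]-	0
ip4	Inositol tetrakisphosphate	C6H16O18P4	other	-	[M-H]-	0
ip5	Inositol pentakisphosphate	C6H17O21P5	other	-	[M-H]-	0
prpp	Phosphoribosyl pyrophosphate	C5H13O14P3	other	-	[M-H]-	0
carnitine	Carnitine	C7H15NO3	other	[M+H]+	-	0
acetylcarnitine	Acetylcarnitine	C9H17NO4	other	[M+H]+	-	0
phosphocholine	Phosphocholine	C5H14NO4P	other	[M+H]+	-	0
dhb	2,5-Dihydroxybenzoic acid (matrix)	C7H6O4	other	[M+H]+;[M+Na]+	-	1
dhb_dimer	DHB matrix cluster (2M-2H2O)	C14H8O6	other	[M+H]+	-	1
dhb_trimer	DHB matrix cluster (3M-3H2O)	C21H12O9	other	[M+H]+	-	1
aa_9	9-Aminoacridine (matrix)	C13H10N2	other	-	[M-H]-	1
pep_409	Calibrant peptide 409	C17H26N6O6	other	-	[M-H]-	0
pep_524	Calibrant peptide 524	C23H39N7O7	other	-	[M-H]-	0
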