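rule_id	kind	formula	adduct	tolerance_ppb	classes	description
tma_loss	neutral_loss	C3H9N	-	500	PC;LPC;SM	Loss of trimethylamine, diagnostic of the phosphocholine head group
pcho_loss	neutral_loss	C5H14NO4P	-	500	PC;LPC;SM	Loss of phosphocholine, diagnostic of PC/SM lipids
adenine_loss	fragment	C5H8O9P2	[M-H]-	500	nucleotide	Triphosphate backbone fragment after adenine loss (ATP diagnostic)
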