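# Default histone PTM / derivatization registry.
# targets: comma-separated residue codes; "N-term" = peptide N-terminus.
# formula: elemental composition of the monoisotopic mass shift.
name	targets	formula	description
ac	K,N-term	C2H2O	acetyl
me1	K,R	CH2	monomethyl
me2	K,R	C2H4	dimethyl
me3	K	C3H6	trimethyl
prop	K,N-term	C3H4O	propionyl (derivatization)
ph	S,T,Y	HPO3	phospho
acme	K	C3H4O	methyl-acetyl (Kacme)
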