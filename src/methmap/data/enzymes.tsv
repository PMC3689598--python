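# Default enzyme registry: name, recognition (IUPAC), cut offset from the
# 5' edge of a top-strand occurrence, marks blocking cleavage ('-' = none),
# double-stranded scan for non-palindromic recognitions.
# MspI cuts through 5mC but is blocked by an internal 5hmC; HpaII is the
# fully methyl-sensitive isoschizomer. BfaI (sensitive to 5hmC) / FspBI
# (insensitive) are the CTAG pair. TasI is the frequent cutter /AATT.
# AciI and HinP1I sensitivity to 5hmC defaults to HpaII-like (blocked by
# both marks). HinP1I is stored with the standard G^CGC offset.
MspI	CCGG	1	5hmC	true
HpaII	CCGG	1	5mC,5hmC	true
FspBI	CTAG	1	-	true
BfaI	CTAG	1	5hmC	true
TasI	AATT	0	-	true
AciI	CCGC	1	5mC,5hmC	true
HinP1I	GCGC	1	5mC,5hmC	true
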