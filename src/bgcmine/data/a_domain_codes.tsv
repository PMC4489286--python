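# Adenylation-domain binding-pocket specificity codes (8 residues, read at
# the configured consensus columns of the A profile). Illustrative default
# payload in the style of the classical pocket-code tables; edit or replace
# for production use.
DLLFGIAV	ala
ILGGGLIA	gly
DAFWIGGT	val
DAWFLGNV	leu
DGFFLGVV	ile
DVWHLSLV	ser
DFWNIGMV	thr
DLYNLSLI	cys
DAWTIAAI	phe
DALWLGGT	tyr
DVWHFSLV	trp
DLTKIGEV	asp
DAWHFGGV	glu
DLQFGAGV	lys
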