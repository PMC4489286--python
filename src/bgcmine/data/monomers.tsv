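# Amino-acid monomer -> SMILES alpha-carbon fragment (alpha carbon plus
# side chain, written so that N precedes and the acyl carbon follows).
gly	C
ala	C(C)
val	C(C(C)C)
leu	C(CC(C)C)
ile	C(C(C)CC)
ser	C(CO)
thr	C(C(C)O)
cys	C(CS)
met	C(CCSC)
phe	C(Cc1ccccc1)
tyr	C(Cc1ccc(O)cc1)
trp	C(Cc1c[nH]c2ccccc12)
asp	C(CC(O)=O)
glu	C(CCC(O)=O)
asn	C(CC(N)=O)
gln	C(CCC(N)=O)
lys	C(CCCCN)
arg	C(CCCNC(N)=N)
his	C(Cc1cnc[nH]1)
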