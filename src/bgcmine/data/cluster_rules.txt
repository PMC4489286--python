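# Default cluster detection rules over the bundled toy profile set.
# One stanza per compound class: RULE <type>, CUTOFF <kb>, EXTENSION <kb>,
# CONDITION <boolean expression over profile names>.
# The production rule collection is payload; users supply their own file for
# full class parity. Distances are kilobases.

RULE t1pks
CUTOFF 20
EXTENSION 20
CONDITION KS and AT

RULE transatpks
CUTOFF 20
EXTENSION 20
CONDITION KS and ATd and not AT

RULE t2pks
CUTOFF 20
EXTENSION 20
CONDITION t2ks and t2clf

RULE t3pks
CUTOFF 20
EXTENSION 20
CONDITION CHS

RULE nrps
CUTOFF 20
EXTENSION 20
CONDITION C and A

RULE terpene
CUTOFF 20
EXTENSION 10
CONDITION Terpene

RULE lantipeptide
CUTOFF 20
EXTENSION 10
CONDITION (LanB and LanC) or LanM

RULE bacteriocin
CUTOFF 20
EXTENSION 5
CONDITION Bacteriocin

RULE siderophore
CUTOFF 20
EXTENSION 5
CONDITION Siderophore

RULE ectoine
CUTOFF 20
EXTENSION 5
CONDITION EctC

RULE arylpolyene
CUTOFF 20
EXTENSION 10
CONDITION APE_KS

RULE resorcinol
CUTOFF 20
EXTENSION 10
CONDITION DarB

RULE ladderane
CUTOFF 20
EXTENSION 10
CONDITION Ladderane

RULE PUFA
CUTOFF 20
EXTENSION 10
CONDITION PUFA_KS
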