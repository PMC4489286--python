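# Prioritized leader-peptide cleavage motifs for lanthipeptide precursors.
# Format: name<TAB>regex; cleavage occurs immediately after the match.
# File order is priority order. Editable payload: class-specific proteolysis
# rules vary and should be tuned per dataset.
double_glycine	GG
gly_ala	GA
class_I_FNLD	F[DN]LD
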