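"""Lanthipeptide precursor analysis: cleavage, modifications, mass.

The precursor is split after the double-glycine motif; every core Ser/Thr
is assumed dehydrated (Dha/Dhb, -18.010565 Da each) and each Cys pairs
with one dehydrated residue into a lanthionine bridge (mass-neutral).
"""

from bgcmine.lanthipeptide import analyze_precursor
from bgcmine.records import Gene

precursor = Gene("lanA", "rec", [(0, 300)], 1, "MKTAGGSCTVA")
prediction = analyze_precursor(precursor)

p = prediction.precursor
print(f"precursor {p.sequence}")
print(f"  leader {p.leader!r} | core {p.core!r} "
      f"(motif: {p.cleavage_motif_used})")
print(f"  dehydrations {prediction.dehydrations}, "
      f"bridges {prediction.bridges}")
print(f"  modifications: {', '.join(prediction.modifications)}")
print(f"  finished monoisotopic mass {prediction.monoisotopic_mass:.6f} Da")
# Core SCTVA: Ser and Thr dehydrate (2 x 18.010565 Da lost), the single
# Cys closes one bridge; the mass is the residue-table sum plus one water
# minus the dehydration losses.
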