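"""Active-site and stereochemistry calls on planted domains.

Plants a ketosynthase (intact catalytic Cys), a ketoreductase carrying the
LDD motif (B-type, D-configured product) and an enoylreductase with the
tyrosine that marks 2S methyl branches, then runs the bundled motif set.
"""

from bgcmine import data as bundled
from bgcmine.active_sites import run_default_set
from bgcmine.hmm import filter_hits, scan_protein
from bgcmine.synthetic import consensus_protein

seq = "M" + consensus_protein(
    ["KS", "KR", "ER"],
    overrides={("KR", 12): "L", ("KR", 13): "D", ("KR", 14): "D",
               ("ER", 13): "Y"})
profiles = bundled.toy_profiles()
hits = []
for name in ("KS", "KR", "ER"):
    hits.extend(scan_protein(seq, profiles[name], gene_id="orf1"))
hits = filter_hits(hits, profiles)

for result in run_default_set(hits, {"orf1": seq}):
    call = result.label or ("site present" if result.matched
                            else "SITE ABSENT")
    print(f"{result.motif_id:<22} extracted {result.extracted!r:<8} -> "
          f"{call}")
# The extracted strings are the residues at the motif's consensus columns,
# read through the profile alignment; '-' marks a deleted column.
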