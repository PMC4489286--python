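"""Core polyketide scaffold from a domain architecture.

A CoA-ligase loading didomain (acetyl starter) plus one malonyl extension
module whose reductive loop is complete (KR+DH+ER, fully reduced methylene
beta-carbon) yields butyric acid; dropping the loop back to nothing gives
the beta-keto product, acetoacetic acid.
"""

from bgcmine import data as bundled
from bgcmine.hmm import filter_hits, scan_protein
from bgcmine.records import Gene
from bgcmine.structure import predict_cluster_structure
from bgcmine.synthetic import consensus_protein


def analyze(reductive_domains):
    loading = "M" + consensus_protein(["CAL", "ACP"])
    extension = "M" + consensus_protein(
        ["KS", "AT", *reductive_domains, "ACP", "TE"])
    genes = [Gene("load", "rec", [(0, 3000)], 1, loading),
             Gene("ext", "rec", [(4000, 9000)], 1, extension)]
    profiles = bundled.toy_profiles()
    hits = []
    for gene in genes:
        for profile in profiles.values():
            hits.extend(scan_protein(gene.translation, profile,
                                     gene_id=gene.gene_id))
    hits = filter_hits(hits, profiles)
    modules, scaffold = predict_cluster_structure(genes, hits, ["t1pks"])
    desc = " + ".join(f"{m.kind}[{m.monomer.call},{m.reduction}]"
                      for m in modules)
    print(f"{desc:<65} -> {scaffold.smiles}")


analyze(["KR", "DH", "ER"])   # fully reduced: butyric acid CCCC(=O)O
analyze([])                   # no reduction: acetoacetic acid CC(=O)CC(=O)O
analyze(["KR"])               # ketoreduction only: 3-hydroxybutyric acid
# Each extension contributes two backbone carbons; the printed reduction
# state describes the beta-carbon inherited from the previous module.
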