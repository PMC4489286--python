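"""Compare a detected cluster against a reference collection.

The query's own gene set, inserted as a reference, must rank first with
100% of query genes hit and maximal synteny (n-1 conserved adjacencies);
a same-content reference with permuted gene order keeps the gene hits but
loses all synteny.
"""

from bgcmine.compare import (ReferenceCluster, compare_cluster,
                             reference_from_genes)
from bgcmine.records import Gene

seqs = ["MKLVINSGSSSIKYQLIDAETGEEL", "MTEYKLVVVGAGGVGKSALTIQLIQ",
        "MSDNELKQRLAAYLDGELSAEEQAE", "MGSSHHHHHHSSGLVPRGSHMASMT"]
query = [Gene(f"q{i}", "rec", [(i * 2000, i * 2000 + 1000)], 1, s)
         for i, s in enumerate(seqs)]

references = [
    reference_from_genes("self", "the query cluster itself", query),
    ReferenceCluster("permuted", "same proteins, shuffled order", "known",
                     [(f"p{i}", query[j].translation, 1)
                      for i, j in enumerate([0, 2, 1, 3])]),
    reference_from_genes("partial", "two of four proteins", query[:2]),
]

ranked = compare_cluster(query, references,
                         core_query_genes=frozenset({"q0"}),
                         base_url="https://mibig.secondarymetabolites.org"
                                  "/repository/")
print("rank  reference  total  genes  synteny  %query-genes  link")
for i, comp in enumerate(ranked, 1):
    print(f"{i:>4}  {comp.ref_id:<9} {comp.total_score:>5.0f}  "
          f"{comp.hit_gene_count:>5}  {comp.synteny_score:>7}  "
          f"{comp.percent_query_genes_hit:>11.1f}  {comp.hyperlink}")
# total = genes-with-hits + conserved adjacencies + core-gene bonus; the
# self reference is maximal by construction.
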