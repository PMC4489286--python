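"""Synthetic genomes with planted, ground-truthed gene clusters.

The generator emits bacterial-style records in which most genes are random
proteins (codon-encoded, no profile content) and designated genes embed the
consensus peptides of chosen toy profiles, so the scanner recovers them far
above cutoff while background genes stay silent.  Every planted cluster is
described in a truth manifest (type, member genes, expected core span),
which end-to-end tests and the acceptance analysis compare against the
pipeline's calls.

What this emulates: gene density, strandedness, modular multi-domain
proteins, cluster-scale gene grouping.  What it does not: real codon usage,
homology between families, pseudogenes, or profile hits of marginal score —
detection operates in a high-signal regime by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .records import AMINO_ACIDS, Feature, Gene, SequenceRecord
from . import data as bundled

#: fixed reverse-translation codon per amino acid (deterministic output)
CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCG", "Q": "CAG", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class PlantedGene:
    """One gene of a planted cluster.

    Either ``domains`` (profile names whose consensus is embedded, in
    order) or ``protein`` (a literal translation, e.g. a precursor
    peptide).  ``overrides`` replaces consensus residues: keys are
    (profile name, 1-based consensus column).
    """

    domains: tuple = ()
    protein: Optional[str] = None
    overrides: dict = field(default_factory=dict)


@dataclass
class PlantedCluster:
    type_name: str
    record_index: int
    start_gene: int
    genes: list  # of PlantedGene


@dataclass
class SyntheticGenomeSpec:
    n_records: int = 1
    genes_per_record: int = 12
    planted: list = field(default_factory=list)  # of PlantedCluster
    intergenic_mean: int = 150
    background_gene_len: tuple = (50, 90)
    seed: int = 0

    def __post_init__(self):
        profiles = bundled.toy_profiles()
        occupied: dict[int, set] = {}
        for cluster in self.planted:
            if not (0 <= cluster.record_index < self.n_records):
                raise ValueError(
                    f"planted cluster record index {cluster.record_index} "
                    f"out of range")
            span = range(cluster.start_gene,
                         cluster.start_gene + len(cluster.genes))
            if span.stop > self.genes_per_record:
                raise ValueError("planted cluster exceeds genes_per_record")
            used = occupied.setdefault(cluster.record_index, set())
            if used & set(span):
                raise ValueError("planted cluster gene ranges overlap")
            used |= set(span)
            for gene in cluster.genes:
                for name in gene.domains:
                    if name not in profiles:
                        raise ValueError(
                            f"planted domain {name!r} is not a bundled "
                            "profile")


def consensus_protein(domains: Sequence[str], overrides: Optional[dict] = None,
                      linker: str = "GSG") -> str:
    """Concatenate profile consensus peptides with short linkers.

    ``overrides`` maps (profile name, 1-based column) to a residue, used to
    plant specificity codes, stereochemistry residues or broken active
    sites.
    """
    overrides = overrides or {}
    profiles = bundled.toy_profiles()
    chunks = []
    for name in domains:
        consensus = list(profiles[name].consensus)
        for (pname, col), residue in overrides.items():
            if pname == name:
                consensus[col - 1] = residue
        chunks.append("".join(consensus))
    return linker.join(chunks)


def _random_protein(rng, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=n))


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def generate_synthetic_genome(spec: SyntheticGenomeSpec
                              ) -> tuple[list, dict]:
    """Build records and the ground-truth manifest for a spec.

    Returns ``(records, manifest)``; the manifest lists every planted
    cluster with its expected type and core gene span.  Different seeds give
    different sequences but the same manifest structure.
    """
    rng = np.random.default_rng(spec.seed)
    planted_at: dict[tuple, tuple] = {}
    for cluster in spec.planted:
        for offset, pgene in enumerate(cluster.genes):
            planted_at[(cluster.record_index,
                        cluster.start_gene + offset)] = (cluster, pgene)
    records = []
    manifest: dict = {"seed": spec.seed, "clusters": []}
    for r in range(spec.n_records):
        record_id = f"synrec{r + 1:02d}"
        seq_parts: list[str] = []
        features: list[Feature] = []
        gene_spans: dict[int, tuple] = {}
        pos = 0
        for g in range(spec.genes_per_record):
            gap = max(20, int(rng.poisson(spec.intergenic_mean)))
            seq_parts.append("".join(
                "ACGT"[i] for i in rng.integers(0, 4, size=gap)))
            pos += gap
            key = (r, g)
            if key in planted_at:
                _, pgene = planted_at[key]
                if pgene.protein is not None:
                    body = pgene.protein
                else:
                    flank_l = _random_protein(rng, 4, 8)
                    flank_r = _random_protein(rng, 4, 8)
                    body = flank_l + consensus_protein(
                        pgene.domains, pgene.overrides) + flank_r
            else:
                body = _random_protein(rng, *spec.background_gene_len)
            translation = body if body.startswith("M") else "M" + body
            dna = "".join(CODON[aa] for aa in translation) + "TAA"
            strand = 1 if rng.random() < 0.7 else -1
            if strand == -1:
                dna = _revcomp(dna)
            start, end = pos, pos + len(dna)
            seq_parts.append(dna)
            pos = end
            gene_id = f"{record_id}_g{g + 1:03d}"
            features.append(Feature(
                kind="CDS", parts=[(start, end)], strand=strand,
                qualifiers={"locus_tag": [gene_id],
                            "translation": [translation]}))
            gene_spans[g] = (start, end, gene_id)
        tail = int(rng.poisson(spec.intergenic_mean))
        seq_parts.append("".join(
            "ACGT"[i] for i in rng.integers(0, 4, size=max(20, tail))))
        records.append(SequenceRecord(
            id=record_id,
            description="synthetic genome (bundled fixture generator)",
            seq="".join(seq_parts), features=features))
        for cluster in spec.planted:
            if cluster.record_index != r:
                continue
            # the expected detection core spans the domain-bearing genes;
            # literal-protein members (e.g. precursor peptides) carry no
            # domain and sit inside the extended span, not the core
            indices = [cluster.start_gene + k
                       for k, pg in enumerate(cluster.genes) if pg.domains]
            if not indices:
                indices = list(range(cluster.start_gene,
                                     cluster.start_gene + len(cluster.genes)))
            spans = [gene_spans[i] for i in indices]
            all_spans = [gene_spans[cluster.start_gene + k]
                         for k in range(len(cluster.genes))]
            manifest["clusters"].append({
                "record_id": record_id,
                "type": cluster.type_name,
                "first_gene": all_spans[0][2],
                "last_gene": all_spans[-1][2],
                "gene_ids": [s[2] for s in all_spans],
                "core_start": min(s[0] for s in spans),
                "core_end": max(s[1] for s in spans),
                "n_genes": len(cluster.genes),
            })
    return records, manifest


def write_fixture(spec: SyntheticGenomeSpec, genbank_path, manifest_path
                  ) -> tuple[list, dict]:
    """Generate and persist a fixture (GenBank + truth manifest JSON)."""
    from .genome_io import write_genbank
    records, manifest = generate_synthetic_genome(spec)
    write_genbank(records, genbank_path)
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return records, manifest


# ---------------------------------------------------------------------------
# stock cluster layouts used by tests, examples and the acceptance analysis
# ---------------------------------------------------------------------------

def stock_planted_cluster(type_name: str, record_index: int = 0,
                          start_gene: int = 3) -> PlantedCluster:
    """A representative planted layout satisfying the default rule for the
    given class."""
    layouts = {
        "t1pks": [PlantedGene(("KS", "AT", "KR", "ACP")),
                  PlantedGene(("KS", "AT", "DH", "KR", "ACP", "TE"))],
        "transatpks": [PlantedGene(("KS", "KR", "ACP")),
                       PlantedGene(("ATd",)),
                       PlantedGene(("KS", "ACP", "TE"))],
        "nrps": [PlantedGene(("A", "PCP")),
                 PlantedGene(("C", "A", "PCP", "TE"))],
        "terpene": [PlantedGene(("Terpene",))],
        "lantipeptide": [PlantedGene(("LanB",)),
                         PlantedGene(("LanC",)),
                         PlantedGene(protein="MKTAGGSCTVA")],
        "bacteriocin": [PlantedGene(("Bacteriocin",))],
        "siderophore": [PlantedGene(("Siderophore",))],
        "ectoine": [PlantedGene(("EctC",))],
        "arylpolyene": [PlantedGene(("APE_KS",))],
        "t2pks": [PlantedGene(("t2ks",)), PlantedGene(("t2clf",))],
        "t3pks": [PlantedGene(("CHS",))],
        "resorcinol": [PlantedGene(("DarB",))],
        "ladderane": [PlantedGene(("Ladderane",))],
        "PUFA": [PlantedGene(("PUFA_KS",))],
    }
    if type_name not in layouts:
        raise ValueError(f"no stock layout for type {type_name!r}")
    return PlantedCluster(type_name, record_index, start_gene,
                          layouts[type_name])
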