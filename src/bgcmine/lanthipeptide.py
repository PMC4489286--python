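"""Lanthipeptide precursor analysis: leader/core split, dehydration and
lanthionine bridge counting, and finished monoisotopic peptide mass.

Lanthipeptides are ribosomally synthesized peptides whose Ser/Thr residues
are dehydrated to dehydroalanine (Dha) / dehydrobutyrine (Dhb), each losing
one water (18.010565 Da monoisotopic), after which cysteine thiols add
across the dehydro residues to form lanthionine/methyllanthionine bridges.
The default model assumes every core Ser/Thr is dehydrated (an upper bound;
a flag exempts the N-terminal residue) and that each Cys forms a bridge with
one dehydrated partner.  Bridge formation itself is mass-neutral.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

from .records import BgcmineError, Gene

#: monoisotopic residue masses (peptide-bond residues), standard table
RESIDUE_MONOISOTOPIC = {
    "G": 57.021464, "A": 71.037114, "S": 87.032028, "P": 97.052764,
    "V": 99.068414, "T": 101.047678, "C": 103.009185, "L": 113.084064,
    "I": 113.084064, "N": 114.042927, "D": 115.026943, "Q": 128.058578,
    "K": 128.094963, "E": 129.042593, "M": 131.040485, "H": 137.058912,
    "F": 147.068414, "R": 156.101111, "Y": 163.063329, "W": 186.079313,
}

#: average residue masses, behind the ``average`` flag
RESIDUE_AVERAGE = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_MONOISOTOPIC = 18.010565
WATER_AVERAGE = 18.01528

DEFAULT_MAX_PRECURSOR_LEN = 120


@dataclass
class PrecursorPeptide:
    gene_id: str
    sequence: str
    leader: str
    core: str
    cleavage_motif_used: str

    def __post_init__(self):
        if self.leader + self.core != self.sequence:
            raise ValueError("leader + core must equal the full sequence")
        if not self.core:
            raise ValueError("core peptide is empty")


@dataclass
class LanthiPrediction:
    precursor: PrecursorPeptide
    dehydrations: int
    bridges: int
    monoisotopic_mass: float
    modifications: list = field(default_factory=list)
    assumptions: list = field(default_factory=lambda: [
        "all core Ser/Thr assumed dehydrated (upper-bound model)"])


def find_precursors(cluster_genes: Sequence[Gene],
                    max_len: int = DEFAULT_MAX_PRECURSOR_LEN) -> list[Gene]:
    """Candidate precursor genes within a lanthipeptide cluster.

    Short open reading frames (translation length <= ``max_len``) containing
    at least one Ser/Thr (dehydratable) and one Cys (bridge partner), in
    genomic order.
    """
    out = []
    for gene in sorted(cluster_genes, key=lambda g: (g.start, g.gene_id)):
        t = gene.translation
        if len(t) <= max_len and set(t) & set("ST") and "C" in t:
            out.append(gene)
    return out


def load_cleavage_motifs(path=None) -> list[tuple[str, str]]:
    """Prioritized (name, regex) cleavage motifs; file order is priority."""
    if path is None:
        path = resources.files("bgcmine.data") / "cleavage_motifs.tsv"
    motifs = []
    with open(str(path)) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            name, _, pattern = line.partition("\t")
            motifs.append((name, pattern))
    if not motifs:
        raise BgcmineError("cleavage motif list is empty")
    return motifs


def split_leader_core(
    gene_id: str,
    sequence: str,
    motif_list: Optional[Sequence[tuple[str, str]]] = None,
) -> Optional[PrecursorPeptide]:
    """Split a precursor at the first (highest-priority, leftmost) cleavage
    motif found within the N-terminal two thirds; cleavage is immediately
    after the motif.  Without any motif the peptide is halved and flagged
    ``fallback``.  Returns None when the resulting core would be empty.
    """
    if motif_list is None:
        motif_list = load_cleavage_motifs()
    limit = 2 * len(sequence) / 3
    for name, pattern in motif_list:
        best = None
        for m in re.finditer(pattern, sequence):
            if m.end() <= limit:
                best = m
                break  # leftmost occurrence of this motif
        if best is not None:
            leader, core = sequence[:best.end()], sequence[best.end():]
            if not core:
                return None
            return PrecursorPeptide(gene_id, sequence, leader, core, name)
    cut = len(sequence) // 2
    leader, core = sequence[:cut], sequence[cut:]
    if not core:
        return None
    return PrecursorPeptide(gene_id, sequence, leader, core, "fallback")


def count_modifications(core: str,
                        exempt_n_terminal: bool = False
                        ) -> tuple[int, int, list]:
    """(dehydrations, bridges, modification list) for a core peptide.

    Every Ser/Thr counts as dehydrated (Dha/Dhb); with
    ``exempt_n_terminal`` the first residue escapes dehydration.  Bridges
    need one Cys and one dehydrated partner each.
    """
    body = core[1:] if exempt_n_terminal else core
    n_ser = body.count("S")
    n_thr = body.count("T")
    dehydrations = n_ser + n_thr
    bridges = min(core.count("C"), dehydrations)
    modifications = (["Dha from Ser"] * n_ser + ["Dhb from Thr"] * n_thr
                     + ["lanthionine bridge"] * bridges)
    return dehydrations, bridges, modifications


def predicted_mass(core: str, dehydrations: int,
                   average: bool = False) -> float:
    """Finished peptide mass: residue masses + water - dehydration losses."""
    table = RESIDUE_AVERAGE if average else RESIDUE_MONOISOTOPIC
    water = WATER_AVERAGE if average else WATER_MONOISOTOPIC
    try:
        total = sum(table[aa] for aa in core)
    except KeyError as exc:
        raise BgcmineError(
            f"core contains non-standard residue {exc.args[0]!r}") from exc
    return total + water - dehydrations * water


def classify_lanthipeptide(cluster_profiles: set) -> Optional[str]:
    """Class assignment from which synthetase profiles fired (metadata only):
    dehydratase+cyclase (LanB+LanC) marks class I, the bifunctional LanM
    synthetase class II."""
    if {"LanB", "LanC"} <= cluster_profiles:
        return "class I"
    if "LanM" in cluster_profiles:
        return "class II"
    return None


def analyze_precursor(
    gene: Gene,
    motif_list: Optional[Sequence[tuple[str, str]]] = None,
    exempt_n_terminal: bool = False,
    average: bool = False,
) -> Optional[LanthiPrediction]:
    """Full single-precursor pipeline; None when no valid core exists."""
    precursor = split_leader_core(gene.gene_id, gene.translation, motif_list)
    if precursor is None:
        return None
    dehydrations, bridges, modifications = count_modifications(
        precursor.core, exempt_n_terminal)
    mass = predicted_mass(precursor.core, dehydrations, average)
    return LanthiPrediction(precursor, dehydrations, bridges, mass,
                            modifications)


def analyze_cluster(
    cluster_genes: Sequence[Gene],
    max_len: int = DEFAULT_MAX_PRECURSOR_LEN,
    motif_list: Optional[Sequence[tuple[str, str]]] = None,
) -> list[LanthiPrediction]:
    if motif_list is None:
        motif_list = load_cleavage_motifs()
    out = []
    for gene in find_precursors(cluster_genes, max_len):
        prediction = analyze_precursor(gene, motif_list)
        if prediction is not None:
            out.append(prediction)
    return out
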