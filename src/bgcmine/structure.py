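"""NRPS/PKS module parsing, monomer prediction and scaffold assembly.

Assembly-line biosynthesis is assumed co-linear: domains are walked gene by
gene in cluster order, each ketosynthase (PKS) or condensation domain (NRPS)
opens a new extension module, and a thioesterase/reductase closes the chain.
Per module the polyketide beta-carbon oxidation state follows from which
reductive domains are present and catalytically active (none: keto; KR:
hydroxyl; KR+DH: enoyl; KR+DH+ER: fully reduced methylene).  The resulting
monomer sequence is emitted as a SMILES core scaffold, released as the free
acid; cyclization, tailoring and stereochemistry are out of scope, and
stereochemistry calls (KR D-/L-, ER 2S/2R) remain annotations only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

from rdkit import Chem
from rdkit import RDLogger

from .active_sites import extract_residues
from .records import BgcmineError, DomainHit, Gene

RDLogger.DisableLog("rdApp.*")

#: canonical assembly-line domain names recognized in architectures
PKS_NRPS_DOMAINS = {
    "KS", "AT", "DH", "ER", "KR", "ACP", "CAL", "C", "A", "PCP", "E",
    "MT", "TE", "TD", "Branching", "Crotonase", "PyranSynthase", "ATd",
}

#: domains recognized and annotated but without effect on the scaffold
NEUTRAL_DOMAINS = {"E", "MT", "Branching", "Crotonase", "PyranSynthase",
                   "ATd"}

REDUCTIONS = ("keto", "hydroxyl", "enoyl", "methylene", "n/a")

COLINEARITY_NOTE = ("scaffold assumes assembly-line co-linearity; "
                    "cyclization and tailoring are not modeled")


@dataclass
class DomainArchitecture:
    """Ordered assembly-line domains of one gene."""

    gene_id: str
    domains: list  # of (domain_name, DomainHit)

    def names(self) -> list:
        return [d for d, _ in self.domains]


@dataclass
class MonomerPrediction:
    code: str
    call: str
    confidence: str  # exact | partial | none

    def __post_init__(self):
        if (self.call == "unknown") != (self.confidence == "none"):
            raise ValueError("call 'unknown' must pair with confidence 'none'")


UNKNOWN_MONOMER = MonomerPrediction("", "unknown", "none")


@dataclass
class BiosynModule:
    module_index: int
    kind: str  # pks_loading | pks_extension | nrps_loading | nrps_extension
    domains: list  # of (domain_name, DomainHit)
    gene_id: str = ""
    trans_at: bool = False
    terminal: bool = False
    monomer: MonomerPrediction = field(
        default_factory=lambda: UNKNOWN_MONOMER)
    reduction: str = "n/a"

    def domain_names(self) -> set:
        return {d for d, _ in self.domains}

    def hit_for(self, name: str) -> Optional[DomainHit]:
        for d, h in self.domains:
            if d == name:
                return h
        return None


@dataclass
class ScaffoldPrediction:
    units: list  # of (monomer call, reduction state)
    smiles: str
    assumptions: list


# ---------------------------------------------------------------------------
# architecture and module splitting
# ---------------------------------------------------------------------------

def build_architecture(gene: Gene, hits: Sequence[DomainHit],
                       domain_names: Optional[dict] = None
                       ) -> DomainArchitecture:
    """Collect the gene's assembly-line domain hits in protein order.

    ``domain_names`` maps profile names to canonical domain names (identity
    for names already canonical); other hits are ignored.
    """
    mapping = domain_names or {}
    domains = []
    for h in sorted((h for h in hits if h.gene_id == gene.gene_id),
                    key=lambda h: (h.env_start, h.env_end, h.profile)):
        name = mapping.get(h.profile, h.profile)
        if name in PKS_NRPS_DOMAINS:
            domains.append((name, h))
    return DomainArchitecture(gene.gene_id, domains)


def split_modules(architectures: Sequence[DomainArchitecture]
                  ) -> list[BiosynModule]:
    """Delineate modules across a cluster's genes in genomic order.

    Each KS (PKS) or C (NRPS) starts a new extension module; domains before
    the first KS/C form a loading module when they amount to AT/CAL(+ACP)
    or A(+PCP).  TE/TD marks the carrying module as terminal.  Modules are
    numbered from 1.
    """
    flat: list[tuple[str, DomainHit, str]] = []
    for arch in architectures:
        for name, hit in arch.domains:
            flat.append((name, hit, arch.gene_id))
    modules: list[BiosynModule] = []
    current: Optional[BiosynModule] = None
    leading: list[tuple[str, DomainHit, str]] = []
    for name, hit, gene_id in flat:
        if name in ("KS", "C"):
            if current is None and leading:
                loader = _loading_module(leading)
                if loader is not None:
                    modules.append(loader)
            kind = "pks_extension" if name == "KS" else "nrps_extension"
            current = BiosynModule(0, kind, [(name, hit)], gene_id=gene_id)
            modules.append(current)
        elif current is None:
            leading.append((name, hit, gene_id))
        else:
            current.domains.append((name, hit))
            if name in ("TE", "TD"):
                current.terminal = True
    if current is None and leading:
        loader = _loading_module(leading)
        if loader is not None:
            modules.append(loader)
    for index, module in enumerate(modules, 1):
        module.module_index = index
    return modules


def _loading_module(leading) -> Optional[BiosynModule]:
    names = {n for n, _, _ in leading}
    if "A" in names:
        kind = "nrps_loading"
    elif names & {"AT", "CAL"}:
        kind = "pks_loading"
    else:
        # carrier/tailoring domains alone do not select a starter unit
        return None
    return BiosynModule(0, kind, [(n, h) for n, h, _ in leading],
                        gene_id=leading[0][2])


def detect_trans_at(modules: Sequence[BiosynModule],
                    cluster_types: Sequence[str]) -> list[BiosynModule]:
    """Mark AT-less extension modules of a trans-AT cluster.

    When the cluster's detected types include ``transatpks``, every PKS
    extension module lacking an embedded AT acts in trans and defaults to a
    malonyl-CoA extender (partial confidence).  Modules with their own AT
    keep their cis call.
    """
    is_transat = "transatpks" in cluster_types
    for module in modules:
        if (is_transat and module.kind == "pks_extension"
                and "AT" not in module.domain_names()):
            module.trans_at = True
            module.monomer = MonomerPrediction("", "mal", "partial")
    return list(modules)


# ---------------------------------------------------------------------------
# monomer prediction
# ---------------------------------------------------------------------------

def load_code_table(path=None) -> dict:
    """Specificity-code table: 8-residue pocket code -> monomer name."""
    if path is None:
        path = resources.files("bgcmine.data") / "a_domain_codes.tsv"
    table = {}
    with open(str(path)) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            table[row[0].upper()] = row[1]
    return table


def predict_a_specificity(
    a_hit: DomainHit,
    translation: str,
    code_positions: Sequence[int],
    code_table: dict,
    min_partial: int = 6,
) -> MonomerPrediction:
    """Adenylation-domain substrate call from the binding-pocket code.

    The residues at the configured consensus columns are looked up in the
    code table: an exact string match is an exact call; otherwise the table
    entry with the most identical residues wins if it agrees at
    ``min_partial`` of the 8 positions; anything less is unknown.
    """
    code = extract_residues(a_hit, code_positions, translation).upper()
    if code in code_table:
        return MonomerPrediction(code, code_table[code], "exact")
    best_name, best_agree = None, -1
    for entry in sorted(code_table):
        agree = sum(1 for a, b in zip(code, entry) if a == b)
        if agree > best_agree:
            best_name, best_agree = code_table[entry], agree
    if best_name is not None and best_agree >= min_partial:
        return MonomerPrediction(code, best_name, "partial")
    return MonomerPrediction(code, "unknown", "none")


def predict_at_specificity(at_hit: DomainHit, translation: str,
                           motifs=None) -> MonomerPrediction:
    """Acyltransferase extender call: malonyl vs methylmalonyl.

    Uses the bundled AT-specificity motif (first-match outcomes); when the
    extraction matches nothing the call defaults to malonyl with partial
    confidence, the documented fallback.
    """
    from .active_sites import default_motifs, evaluate_motif
    if motifs is None:
        motifs = [m for m in default_motifs()
                  if m.motif_id == "AT_specificity"]
    for motif in motifs:
        if motif.target_profile != at_hit.profile:
            continue
        result = evaluate_motif(at_hit, translation, motif)
        if result.label in ("mal", "mmal"):
            confidence = "exact" if result.matched else "partial"
            return MonomerPrediction(result.extracted, result.label,
                                     confidence)
    return MonomerPrediction("", "mal", "partial")


# ---------------------------------------------------------------------------
# reduction state
# ---------------------------------------------------------------------------

def reduction_state(module: BiosynModule,
                    inactive_keys: frozenset = frozenset()) -> str:
    """Beta-carbon oxidation state implied by the module's reductive loop.

    ``inactive_keys`` holds (gene_id, profile, env_start) identity keys of
    domains flagged scaffold-inactive by the active-site analysis; flagged
    domains count as absent.  An inactive KR downgrades the whole module to
    keto: DH/ER have no hydroxyl substrate to act on.
    """
    if module.kind != "pks_extension":
        return "n/a"

    def active(name: str) -> bool:
        hit = module.hit_for(name)
        if hit is None:
            return False
        return (hit.gene_id, hit.profile, hit.env_start) not in inactive_keys

    if not active("KR"):
        return "keto"
    if not active("DH"):
        return "hydroxyl"
    if not active("ER"):
        return "enoyl"
    return "methylene"


# ---------------------------------------------------------------------------
# scaffold assembly
# ---------------------------------------------------------------------------

def load_monomer_fragments(path=None) -> dict:
    """Amino-acid monomer -> SMILES alpha-carbon fragment (with side chain)."""
    if path is None:
        path = resources.files("bgcmine.data") / "monomers.tsv"
    table = {}
    with open(str(path)) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            table[row[0]] = row[1]
    return table


_BETA_FRAGMENT = {
    "keto": "C(=O)",
    "hydroxyl": "C(O)",
    "enoyl": "C",  # followed by '=' to the alpha carbon
    "methylene": "C",
}

_PKS_ALPHA = {"mal": "C", "mmal": "C(C)"}

_PKS_STARTERS = {"acetyl": "C", "mal": "C", "prop": "CC"}


def assemble_scaffold(modules: Sequence[BiosynModule],
                      monomer_fragments: Optional[dict] = None
                      ) -> Optional[ScaffoldPrediction]:
    """Concatenate module monomers N->C / start->end into a SMILES scaffold.

    Each PKS extension adds a two-carbon backbone unit whose beta carbon is
    rendered per the module's reduction state; methylmalonyl adds an
    alpha-methyl branch.  NRPS units add the amino-acid residue through an
    amide bond.  The chain is released as the free acid.  Unknown monomers
    become a documented wildcard unit so partial predictions still yield a
    parseable structure.  Returns None when there is nothing to assemble.
    """
    if monomer_fragments is None:
        monomer_fragments = load_monomer_fragments()
    units: list[tuple[str, str]] = []
    assumptions = [COLINEARITY_NOTE]
    smiles = ""
    have_carbonyl = False  # a pending acyl carbon awaits rendering
    for module in modules:
        if module.kind in ("pks_loading", "nrps_loading"):
            call = module.monomer.call
            if module.kind == "pks_loading":
                starter = call if call in _PKS_STARTERS else "acetyl"
                if call == "unknown":
                    assumptions.append(
                        "unknown loading monomer modeled as acetyl")
                smiles += _PKS_STARTERS[starter]
                units.append((starter, "n/a"))
                have_carbonyl = True
            else:
                frag = monomer_fragments.get(call)
                if frag is None:
                    frag = "C"
                    assumptions.append(
                        f"unknown loading amino acid {call!r} modeled as a "
                        "generic alpha carbon")
                smiles += "N" + frag
                units.append((call, "n/a"))
                have_carbonyl = True
        elif module.kind == "pks_extension":
            state = module.reduction if module.reduction in _BETA_FRAGMENT \
                else "keto"
            if have_carbonyl:
                smiles += _BETA_FRAGMENT[state]
                if state == "enoyl":
                    smiles += "="
            call = module.monomer.call
            alpha = _PKS_ALPHA.get(call)
            if alpha is None:
                alpha = "C"
                if call == "unknown":
                    assumptions.append(
                        f"module {module.module_index}: unknown extender "
                        "modeled as malonyl")
            smiles += alpha
            units.append((call if call in _PKS_ALPHA else "mal",
                          state if have_carbonyl else "n/a"))
            have_carbonyl = True
        elif module.kind == "nrps_extension":
            if have_carbonyl:
                smiles += "C(=O)N"
            else:
                smiles += "N"
            call = module.monomer.call
            frag = monomer_fragments.get(call)
            if frag is None:
                frag = "C"
                assumptions.append(
                    f"module {module.module_index}: unknown amino acid "
                    f"{call!r} modeled as a generic alpha carbon")
            smiles += frag
            units.append((call, "n/a"))
            have_carbonyl = True
    if not units:
        return None
    if have_carbonyl:
        smiles += "C(O)=O"
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pragma: no cover - assembly emits valid fragments
        raise BgcmineError(f"assembled SMILES does not parse: {smiles}")
    return ScaffoldPrediction(units=units,
                              smiles=Chem.MolToSmiles(mol),
                              assumptions=assumptions)


def canonical_smiles(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise BgcmineError(f"SMILES does not parse: {smiles}")
    return Chem.MolToSmiles(mol)


#: consensus columns of the bundled toy A profile holding the pocket code
DEFAULT_CODE_POSITIONS = (10, 11, 12, 13, 14, 15, 16, 17)


def predict_cluster_structure(
    cluster_genes: Sequence[Gene],
    hits: Sequence[DomainHit],
    cluster_types: Sequence[str],
    inactive_keys: frozenset = frozenset(),
    code_positions: Sequence[int] = DEFAULT_CODE_POSITIONS,
    code_table: Optional[dict] = None,
) -> tuple[list[BiosynModule], Optional[ScaffoldPrediction]]:
    """Per-cluster orchestration: architectures -> modules -> monomers ->
    reduction states -> scaffold."""
    if code_table is None:
        code_table = load_code_table()
    translations = {g.gene_id: g.translation for g in cluster_genes}
    ordered = sorted(cluster_genes, key=lambda g: (g.start, g.gene_id))
    architectures = [build_architecture(g, hits) for g in ordered]
    modules = split_modules([a for a in architectures if a.domains])
    modules = detect_trans_at(modules, cluster_types)
    for module in modules:
        if module.monomer.call == "unknown":  # trans-AT default already set
            a_hit = module.hit_for("A")
            at_hit = module.hit_for("AT")
            cal_hit = module.hit_for("CAL")
            if a_hit is not None:
                module.monomer = predict_a_specificity(
                    a_hit, translations[a_hit.gene_id], code_positions,
                    code_table)
            elif at_hit is not None:
                module.monomer = predict_at_specificity(
                    at_hit, translations[at_hit.gene_id])
            elif cal_hit is not None and module.kind == "pks_loading":
                module.monomer = MonomerPrediction("", "acetyl", "partial")
        module.reduction = reduction_state(module, inactive_keys)
    scaffold = assemble_scaffold(modules)
    return modules, scaffold
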