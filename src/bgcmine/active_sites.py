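"""Active-site and key-residue annotation of biosynthetic domains.

Motifs are defined in an XML file (validated against the shipped XSD): each
motif names a target profile, a list of consensus columns, and either a
single regular-expression pattern (presence/absence call) or an ordered list
of (pattern, label) outcomes for multi-class calls such as ketoreductase
D-/L- stereochemistry.  Residues are extracted through the profile-alignment
map carried by every domain hit, so positions are anchored to profile
consensus columns and stay correct across indels; deleted columns render as
``-``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

from lxml import etree

from .records import BgcmineError, DomainHit, Feature, SequenceRecord, GAP


class MotifError(BgcmineError):
    pass


@dataclass
class MotifDefinition:
    motif_id: str
    description: str
    target_profile: str
    positions: list
    pattern: Optional[str] = None
    outcomes: list = field(default_factory=list)  # of (pattern, label)
    annotation_key: str = "active_site"
    #: when True, a non-matching pattern flags the domain scaffold-inactive
    required_for_activity: bool = False

    def __post_init__(self):
        if self.pattern is None and not self.outcomes:
            raise MotifError(
                f"motif {self.motif_id}: needs a pattern or outcomes")
        if list(self.positions) != sorted(set(self.positions)):
            raise MotifError(
                f"motif {self.motif_id}: positions must be strictly "
                "increasing")
        if self.positions and self.positions[0] < 1:
            raise MotifError(f"motif {self.motif_id}: positions are 1-based")


@dataclass
class MotifResult:
    gene_id: str
    motif_id: str
    extracted: str
    matched: bool
    label: Optional[str] = None
    annotation_key: str = "active_site"
    description: str = ""
    scaffold_inactive: bool = False
    hit: Optional[DomainHit] = None


def _schema():
    text = (resources.files("bgcmine.data") / "motifs.xsd").read_text()
    return etree.XMLSchema(etree.fromstring(text.encode()))


def load_motifs(xml_path, profile_lengths: Optional[dict] = None
                ) -> list[MotifDefinition]:
    """Parse and validate a motif XML file.

    ``profile_lengths`` (profile name -> match column count) additionally
    checks every position against the target profile length.
    """
    tree = etree.parse(str(xml_path))
    schema = _schema()
    if not schema.validate(tree):
        raise MotifError(
            f"{xml_path}: schema validation failed: "
            f"{schema.error_log.last_error}")
    motifs: list[MotifDefinition] = []
    seen = set()
    for el in tree.getroot().iter("motif"):
        motif_id = el.get("id")
        if motif_id in seen:
            raise MotifError(f"{xml_path}: duplicate motif id {motif_id!r}")
        seen.add(motif_id)
        target = el.get("target")
        positions = [int(x) for x in el.findtext("positions").split(",")]
        pattern_el = el.find("pattern")
        outcomes = [(o.get("pattern"), o.get("label"))
                    for o in el.iter("outcome")]
        motif = MotifDefinition(
            motif_id=motif_id,
            description=el.findtext("description", default=""),
            target_profile=target,
            positions=positions,
            pattern=None if pattern_el is None else pattern_el.text.strip(),
            outcomes=outcomes,
            annotation_key=el.get("annotation_key", "active_site"),
            required_for_activity=el.get("required", "false") == "true",
        )
        if profile_lengths is not None and target in profile_lengths:
            if positions and positions[-1] > profile_lengths[target]:
                raise MotifError(
                    f"motif {motif_id}: position {positions[-1]} exceeds "
                    f"profile {target} length {profile_lengths[target]}")
        motifs.append(motif)
    return motifs


def save_motifs(motifs: Iterable[MotifDefinition], xml_path) -> None:
    root = etree.Element("motifs")
    for m in motifs:
        el = etree.SubElement(root, "motif", id=m.motif_id,
                              target=m.target_profile,
                              annotation_key=m.annotation_key)
        if m.required_for_activity:
            el.set("required", "true")
        etree.SubElement(el, "description").text = m.description
        etree.SubElement(el, "positions").text = ",".join(
            str(p) for p in m.positions)
        if m.pattern is not None:
            etree.SubElement(el, "pattern").text = m.pattern
        if m.outcomes:
            outs = etree.SubElement(el, "outcomes")
            for pattern, label in m.outcomes:
                etree.SubElement(outs, "outcome", pattern=pattern, label=label)
    etree.ElementTree(root).write(str(xml_path), pretty_print=True,
                                  xml_declaration=True, encoding="UTF-8")


def extract_residues(hit: DomainHit, positions: Sequence[int],
                     translation: str) -> str:
    """Aligned residue at each consensus column; ``-`` where the column is
    deleted or outside the aligned span.  Pure function of (alignment,
    positions)."""
    out = []
    for col in positions:
        residue_index = hit.alignment.get(col, GAP)
        out.append("-" if residue_index is GAP else translation[residue_index])
    return "".join(out)


def evaluate_motif(hit: DomainHit, translation: str,
                   motif: MotifDefinition) -> MotifResult:
    """Extract the motif residues from a hit and classify them.

    ``matched`` reflects the full-string pattern when one is given,
    otherwise whether any outcome matched.  The label is the first outcome
    whose pattern matches (first-match-wins), or None.
    """
    if hit.profile != motif.target_profile:
        raise MotifError(
            f"motif {motif.motif_id} targets {motif.target_profile}, "
            f"hit is against {hit.profile}")
    extracted = extract_residues(hit, motif.positions, translation)
    matched = True
    if motif.pattern is not None:
        matched = re.fullmatch(motif.pattern, extracted) is not None
    label = None
    for pattern, outcome_label in motif.outcomes:
        if re.search(pattern, extracted):
            label = outcome_label
            break
    if motif.pattern is None:
        matched = label is not None
    return MotifResult(
        gene_id=hit.gene_id,
        motif_id=motif.motif_id,
        extracted=extracted,
        matched=matched,
        label=label,
        annotation_key=motif.annotation_key,
        description=motif.description,
        scaffold_inactive=(motif.required_for_activity and not matched),
        hit=hit,
    )


def run_motifs(
    hits: Sequence[DomainHit],
    translations: dict,
    motifs: Sequence[MotifDefinition],
) -> list[MotifResult]:
    """Evaluate every motif against every hit on its target profile.

    ``translations`` maps gene_id to protein sequence.
    """
    by_target: dict[str, list[MotifDefinition]] = {}
    for m in motifs:
        by_target.setdefault(m.target_profile, []).append(m)
    results = []
    for hit in hits:
        for motif in by_target.get(hit.profile, []):
            results.append(
                evaluate_motif(hit, translations[hit.gene_id], motif))
    return results


def default_motifs(profile_lengths: Optional[dict] = None
                   ) -> list[MotifDefinition]:
    """The bundled default motif set (KS/AT/DH/KR/ACP/TE/P450 active sites,
    ACP branching, KR D-/L- and ER 2S/2R stereochemistry)."""
    with resources.as_file(resources.files("bgcmine.data") / "motifs.xml") as p:
        return load_motifs(p, profile_lengths)


def run_default_set(hits: Sequence[DomainHit], translations: dict,
                    profile_lengths: Optional[dict] = None
                    ) -> list[MotifResult]:
    return run_motifs(hits, translations, default_motifs(profile_lengths))


def scaffold_inactive_keys(results: Sequence[MotifResult]) -> set:
    """Identity keys of domains whose mandatory active site failed."""
    keys = set()
    for r in results:
        if r.scaffold_inactive and r.hit is not None:
            keys.add((r.gene_id, r.hit.profile, r.hit.env_start))
    return keys


def annotate_record(record: SequenceRecord,
                    results: Sequence[MotifResult]) -> SequenceRecord:
    """Add matched motif annotations as qualifiers on domain features.

    A result attaches to the ``aSDomain`` feature whose gene and profile
    qualifiers match its hit; records lacking such features are left
    untouched for that result.
    """
    for result in results:
        if not result.matched or result.hit is None:
            continue
        note = f"{result.motif_id}: {result.description} ({result.extracted})"
        if result.label:
            note += f" -> {result.label}"
        for feature in record.features:
            if feature.kind != "aSDomain":
                continue
            if (feature.qualifiers.get("gene", [None])[0] == result.gene_id
                    and feature.qualifiers.get("profile", [None])[0]
                    == result.hit.profile):
                feature.qualifiers.setdefault(
                    result.annotation_key, []).append(note)
                break
    return record
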