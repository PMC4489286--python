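"""Genome and annotation I/O.

Reading and writing of GenBank/EMBL/FASTA goes through Biopython; this
module owns the conversion between the 1-based inclusive coordinates of the
flat-file formats and the package's 0-based half-open internal convention,
CDS extraction/translation (bacterial translation table 11 by default,
overridable per CDS via ``/transl_table``), and the XML result document
("BiosynML-style") with its shipped schema.
"""

from __future__ import annotations

import logging
from importlib import resources
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import (CompoundLocation, SeqFeature, SimpleLocation)
from Bio.SeqRecord import SeqRecord as BioSeqRecord
from lxml import etree

from .records import (BgcmineError, Feature, Gene, NUCLEOTIDES,
                      SequenceRecord, AMINO_ACIDS)

logger = logging.getLogger(__name__)

PROTEIN_ALPHABET = set(AMINO_ACIDS) | {"X"}


class GenomeParseError(BgcmineError):
    pass


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _from_bio(rec: BioSeqRecord) -> SequenceRecord:
    features = []
    for f in rec.features:
        strand = f.location.strand if f.location.strand in (1, -1) else 1
        parts = [(int(p.start), int(p.end)) for p in f.location.parts]
        features.append(Feature(
            kind=f.type,
            parts=parts,
            strand=strand,
            qualifiers={k: list(v) for k, v in f.qualifiers.items()},
        ))
    topology = rec.annotations.get("topology", "linear")
    record = SequenceRecord(
        id=rec.id, description=rec.description or "",
        seq=str(rec.seq).upper(),
        topology=topology if topology in ("linear", "circular") else "linear",
        features=features,
    )
    for feature in record.features:
        if feature.end > len(record.seq):
            raise GenomeParseError(
                f"record {record.id}: feature {feature.kind} ends at "
                f"{feature.end}, beyond sequence length {len(record.seq)}")
    return record


def _read_flat(path, fmt: str) -> list[SequenceRecord]:
    try:
        bio_records = list(SeqIO.parse(str(path), fmt))
    except ValueError as exc:
        raise GenomeParseError(f"{path}: line unknown: {exc}") from exc
    if not bio_records:
        raise GenomeParseError(f"{path}: no records in {fmt} file")
    return [_from_bio(r) for r in bio_records]


def read_genbank(path) -> list[SequenceRecord]:
    """One record per LOCUS; GenBank 1-based inclusive coordinates become
    0-based half-open, ``complement`` becomes strand -1."""
    _check_flatfile_header(path, "LOCUS")
    return _read_flat(path, "genbank")


def read_embl(path) -> list[SequenceRecord]:
    """EMBL flat-file counterpart of :func:`read_genbank`."""
    _check_flatfile_header(path, "ID")
    return _read_flat(path, "embl")


def _check_flatfile_header(path, keyword: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            if not line.startswith(keyword):
                raise GenomeParseError(
                    f"{path}: line {lineno}: expected {keyword} header, "
                    f"got {line.split()[0] if line.split() else ''!r}")
            return
    raise GenomeParseError(f"{path}: no records (empty file)")


def read_fasta(path, alphabet: str) -> list[SequenceRecord]:
    """FASTA input, declared nucleotide or protein.

    Protein records are flagged so downstream skips gene calling and treats
    each entry as a single gene.
    """
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError(f"alphabet must be nucleotide/protein, "
                         f"got {alphabet!r}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        allowed = NUCLEOTIDES if alphabet == "nucleotide" else PROTEIN_ALPHABET
        bad = sorted(set(seq) - allowed)
        if bad:
            raise GenomeParseError(
                f"{path}: record {rec.id}: illegal {alphabet} "
                f"character(s) {', '.join(bad)}")
        records.append(SequenceRecord(
            id=rec.id, description=rec.description, seq=seq,
            is_protein=(alphabet == "protein"),
        ))
    # an entry-less FASTA is a valid, empty input (unlike flat files)
    return records


# ---------------------------------------------------------------------------
# gene extraction
# ---------------------------------------------------------------------------

def _coding_sequence(record: SequenceRecord, feature: Feature) -> str:
    chunks = [record.seq[s:e] for s, e in sorted(feature.parts)]
    seq = "".join(chunks)
    if feature.strand == -1:
        seq = str(Seq(seq).reverse_complement())
    return seq


def extract_genes(record: SequenceRecord) -> list[Gene]:
    """Translate the record's CDS features into genes.

    The ``/translation`` qualifier wins when present; otherwise the coding
    sequence is translated with the bacterial code (table 11, or the CDS's
    own ``/transl_table``), trimming the terminal stop.  CDS with frame
    problems or internal stops are skipped with a logged warning.
    Idempotent and ordered by start coordinate.
    """
    if record.is_protein:
        return [Gene(gene_id=record.id, record_id=record.id,
                     parts=[(0, max(1, len(record.seq)))], strand=1,
                     translation=record.seq)]
    genes = []
    counter = 0
    for feature in record.features_of_kind("CDS"):
        counter += 1
        quals = feature.qualifiers
        gene_id = (quals.get("locus_tag") or quals.get("gene")
                   or quals.get("protein_id") or [f"{record.id}_cds{counter}"])[0]
        if "translation" in quals:
            translation = quals["translation"][0]
        else:
            cds = _coding_sequence(record, feature)
            if len(cds) % 3 != 0:
                logger.warning(
                    "record %s: CDS %s length %d not divisible by 3; "
                    "gene skipped", record.id, gene_id, len(cds))
                continue
            table = int(quals.get("transl_table", ["11"])[0])
            translation = str(Seq(cds).translate(table=table))
            if translation.endswith("*"):
                translation = translation[:-1]
        if not translation or "*" in translation:
            logger.warning(
                "record %s: CDS %s has internal stop or empty translation; "
                "gene skipped", record.id, gene_id)
            continue
        genes.append(Gene(gene_id=gene_id, record_id=record.id,
                          parts=sorted(feature.parts),
                          strand=feature.strand,
                          translation=translation))
    genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
    return genes


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _to_bio(record: SequenceRecord) -> BioSeqRecord:
    rec = BioSeqRecord(
        Seq(record.seq), id=record.id,
        name=record.id[:16].replace(" ", "_"),
        description=record.description,
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = record.topology
    # a fixed date keeps re-runs byte-identical
    rec.annotations["date"] = "01-JAN-1980"
    for f in record.features:
        parts = [SimpleLocation(s, e, f.strand) for s, e in f.parts]
        if f.strand == -1 and len(parts) > 1:
            parts = parts[::-1]
        location = parts[0] if len(parts) == 1 else CompoundLocation(parts)
        rec.features.append(SeqFeature(
            location=location, type=f.kind,
            qualifiers={k: list(v) for k, v in f.qualifiers.items()}))
    return rec


def write_genbank(records: Iterable[SequenceRecord], path) -> None:
    SeqIO.write([_to_bio(r) for r in records], str(path), "genbank")


def write_embl(records: Iterable[SequenceRecord], path) -> None:
    SeqIO.write([_to_bio(r) for r in records], str(path), "embl")


def cluster_to_feature(cluster) -> Feature:
    """Serialize a cluster prediction as a ``cluster`` feature."""
    qualifiers = {
        "cluster_number": [str(cluster.cluster_number)],
        "type": [cluster.type_label],
        "detection": [cluster.detection],
        "core_location": [f"{cluster.core_start + 1}..{cluster.core_end}"],
    }
    if cluster.probability is not None:
        qualifiers["probability"] = [f"{cluster.probability:.4f}"]
    return Feature(kind="cluster", parts=[(cluster.start, cluster.end)],
                   strand=1, qualifiers=qualifiers)


def hit_to_feature(hit, gene) -> Feature:
    """Serialize a domain hit as an ``aSDomain`` feature (approximate
    genomic envelope from protein coordinates)."""
    if gene.strand == 1:
        start = gene.start + 3 * hit.env_start
        end = min(gene.end, gene.start + 3 * hit.env_end)
    else:
        end = gene.end - 3 * hit.env_start
        start = max(gene.start, gene.end - 3 * hit.env_end)
    return Feature(kind="aSDomain", parts=[(start, end)], strand=gene.strand,
                   qualifiers={
                       "gene": [hit.gene_id],
                       "profile": [hit.profile],
                       "score": [f"{hit.bitscore:.1f}"],
                       "env": [f"{hit.env_start}..{hit.env_end}"],
                   })


# ---------------------------------------------------------------------------
# XML result document
# ---------------------------------------------------------------------------

def _biosynml_schema() -> etree.XMLSchema:
    text = (resources.files("bgcmine.data") / "biosynml.xsd").read_text()
    return etree.XMLSchema(etree.fromstring(text.encode()))


def build_biosynml(results) -> etree._ElementTree:
    """Build the XML result tree for a result bundle.

    ``results`` is a :class:`bgcmine.pipeline.AnalysisResults`-like object:
    ``records`` (SequenceRecord list), ``genes`` per record id, ``clusters``
    (ClusterPrediction list with optional per-cluster extras).
    """
    root = etree.Element("biosynml", version="1.0")
    genomes = etree.SubElement(root, "genomes")
    for record in results.records:
        etree.SubElement(genomes, "genome", id=record.id,
                         length=str(len(record.seq)),
                         topology=record.topology,
                         description=record.description or "")
    clusters_el = etree.SubElement(root, "clusters")
    for cluster in results.clusters:
        cl = etree.SubElement(
            clusters_el, "cluster",
            record=cluster.record_id,
            number=str(cluster.cluster_number),
            type=cluster.type_label,
            start=str(cluster.start), end=str(cluster.end),
            core_start=str(cluster.core_start),
            core_end=str(cluster.core_end),
            detection=cluster.detection)
        if cluster.probability is not None:
            cl.set("probability", f"{cluster.probability:.6f}")
        genes_el = etree.SubElement(cl, "genes")
        for gene in cluster.genes:
            etree.SubElement(genes_el, "gene", id=gene.gene_id,
                             start=str(gene.start), end=str(gene.end),
                             strand="+" if gene.strand == 1 else "-")
        domains_el = etree.SubElement(cl, "domains")
        for hit in cluster.supporting_hits:
            etree.SubElement(domains_el, "domain", gene=hit.gene_id,
                             name=hit.profile,
                             env_start=str(hit.env_start),
                             env_end=str(hit.env_end),
                             score=f"{hit.bitscore:.2f}")
        for result in cluster.extras.get("motifs", []):
            motifs_el = cl.find("motifs")
            if motifs_el is None:
                motifs_el = etree.SubElement(cl, "motifs")
            el = etree.SubElement(motifs_el, "motif", gene=result.gene_id,
                                  id=result.motif_id,
                                  extracted=result.extracted,
                                  matched=str(result.matched).lower())
            if result.label:
                el.set("label", result.label)
        scaffold = cluster.extras.get("scaffold")
        if scaffold is not None:
            sc = etree.SubElement(cl, "scaffold", smiles=scaffold.smiles)
            for monomer, reduction in scaffold.units:
                etree.SubElement(sc, "unit", monomer=monomer,
                                 reduction=reduction)
        comparisons = cluster.extras.get("comparisons", [])
        if comparisons:
            comps = etree.SubElement(cl, "comparisons")
            for comp in comparisons:
                el = etree.SubElement(
                    comps, "hit", ref=comp.ref_id, label=comp.label,
                    score=f"{comp.total_score:.1f}",
                    percent=f"{comp.percent_query_genes_hit:.1f}")
                if comp.hyperlink:
                    el.set("hyperlink", comp.hyperlink)
        for lanthi in cluster.extras.get("lanthipeptides", []):
            el = etree.SubElement(
                cl, "lanthipeptide", gene=lanthi.precursor.gene_id,
                core=lanthi.precursor.core,
                dehydrations=str(lanthi.dehydrations),
                bridges=str(lanthi.bridges),
                mass=f"{lanthi.monoisotopic_mass:.6f}")
    return etree.ElementTree(root)


def write_biosynml(results, path) -> None:
    """Write and schema-validate the XML result document."""
    tree = build_biosynml(results)
    schema = _biosynml_schema()
    if not schema.validate(tree):
        raise BgcmineError(
            f"result document fails schema validation: "
            f"{schema.error_log.last_error}")
    tree.write(str(path), pretty_print=True, xml_declaration=True,
               encoding="UTF-8")


def read_biosynml(path) -> etree._ElementTree:
    """Parse and schema-validate a result document."""
    tree = etree.parse(str(path))
    schema = _biosynml_schema()
    if not schema.validate(tree):
        raise BgcmineError(
            f"{path}: fails schema validation: {schema.error_log.last_error}")
    return tree


def write_summary_tab(results, path) -> None:
    """Tab-delimited cluster summary: one row per cluster."""
    header = ["record_id", "cluster_number", "type", "start", "end",
              "best_known_hit"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for cluster in results.clusters:
            comparisons = cluster.extras.get("comparisons", [])
            best = comparisons[0].ref_id if comparisons else "-"
            fh.write("\t".join([
                cluster.record_id, str(cluster.cluster_number),
                cluster.type_label, str(cluster.start), str(cluster.end),
                best]) + "\n")
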