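"""End-to-end orchestration: scan, detect, analyze, report.

The pipeline is deterministic: the configured seed governs only synthetic
fixture generation, never the analysis itself, so identical inputs and
configuration produce byte-identical outputs.  Output files are written to
a temporary directory and moved into place only when every enabled stage
succeeded; a stage failure aborts with the stage name and removes partial
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import shutil
import tempfile
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

from . import data as bundled
from . import __version__
from .active_sites import run_default_set, scaffold_inactive_keys
from .clusterfinder import (CfModel, DEFAULT_MIN_GENES, DEFAULT_MIN_TOKENS,
                            DEFAULT_THRESHOLD, DEFAULT_WINDOW,
                            integrate_with_rules, load_cf_model, predict)
from .compare import (compare_cluster, load_reference_bundle)
from .genome_io import (cluster_to_feature, extract_genes, hit_to_feature,
                        read_embl, read_fasta, read_genbank, write_biosynml,
                        write_genbank, write_summary_tab)
from .hmm import assign_family, filter_hits, load_profiles, scan_genes
from .lanthipeptide import analyze_cluster as analyze_lanthipeptides
from .records import BgcmineError, Gene, SequenceRecord
from .rules import call_clusters, merge_overlaps, parse_rules
from .structure import predict_cluster_structure

logger = logging.getLogger(__name__)

MIBIG_BASE_URL = "https://mibig.secondarymetabolites.org/repository/"


class StageError(BgcmineError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    inputs: list
    output_dir: Optional[str] = None
    input_format: Optional[str] = None  # autodetect by extension when None
    profiles_path: Optional[str] = None  # None: bundled toy set
    rules_path: Optional[str] = None  # None: bundled default rules
    clusterfinder: bool = False
    cf_model_path: Optional[str] = None
    cf_threshold: float = DEFAULT_THRESHOLD
    cf_min_tokens: int = DEFAULT_MIN_TOKENS
    cf_min_genes: int = DEFAULT_MIN_GENES
    cf_window: int = DEFAULT_WINDOW
    knownclusterblast: bool = False
    clusterblast: bool = False
    subclusterblast: bool = False
    reference_known: Optional[tuple] = None  # (fasta, sidecar or None)
    reference_genomic: Optional[tuple] = None
    reference_subcluster: Optional[tuple] = None
    active_sites: bool = True
    structure: bool = True
    lanthipeptides: bool = True
    smcog: bool = True
    emit_embl: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class AnalysisResults:
    records: list
    genes: dict  # record_id -> list[Gene]
    hits: dict  # record_id -> filtered DomainHit list
    clusters: list  # ClusterPrediction, numbered, analyses in .extras
    cf_predictions: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


_FORMAT_BY_SUFFIX = {
    ".gb": "genbank", ".gbk": "genbank", ".gbff": "genbank",
    ".embl": "embl",
    ".fa": "fasta-nucleotide", ".fasta": "fasta-nucleotide",
    ".fna": "fasta-nucleotide", ".faa": "fasta-protein",
}


def _read_input(path, fmt: Optional[str]) -> list:
    if fmt is None:
        fmt = _FORMAT_BY_SUFFIX.get(Path(path).suffix.lower())
        if fmt is None:
            raise BgcmineError(
                f"cannot infer input format from {path}; set input_format")
    if fmt == "genbank":
        return read_genbank(path)
    if fmt == "embl":
        return read_embl(path)
    if fmt == "fasta-nucleotide":
        return read_fasta(path, "nucleotide")
    if fmt == "fasta-protein":
        return read_fasta(path, "protein")
    raise BgcmineError(f"unknown input format {fmt!r}")


def cluster_genes(cluster, genes: Sequence[Gene]) -> list:
    """Genes overlapping the cluster span, in genomic order."""
    return [g for g in genes
            if g.record_id == cluster.record_id
            and g.start < cluster.end and cluster.start < g.end]


def run(config: PipelineConfig) -> AnalysisResults:
    """Execute every enabled stage; see the module docstring for contracts."""
    stage = "setup"
    try:
        profiles = (load_profiles(config.profiles_path)
                    if config.profiles_path else
                    list(bundled.toy_profiles().values()))
        profile_map = {p.name: p for p in profiles}
        rules = parse_rules(config.rules_path or
                            str(bundled.default_rules_path()),
                            known_profiles=profile_map)
        cf_model: Optional[CfModel] = None
        if config.clusterfinder:
            cf_model = load_cf_model(config.cf_model_path or
                                     str(bundled.default_cf_model_path()))
        references = {}
        for source, pair, enabled in (
                ("known", config.reference_known, config.knownclusterblast),
                ("genomic", config.reference_genomic, config.clusterblast),
                ("subcluster", config.reference_subcluster,
                 config.subclusterblast)):
            if enabled:
                if pair is None:
                    raise BgcmineError(
                        f"{source} comparison enabled but no reference "
                        "bundle configured")
                references[source] = load_reference_bundle(
                    pair[0], pair[1], source=source)

        stage = "genome_io"
        records: list[SequenceRecord] = []
        for path in config.inputs:
            records.extend(_read_input(path, config.input_format))
        genes = {r.id: extract_genes(r) for r in records}

        stage = "hmm_scan"
        hits = {}
        for r in records:
            raw = scan_genes(genes[r.id], profiles)
            hits[r.id] = filter_hits(raw, profile_map)

        stage = "cluster_rules"
        clusters = []
        for r in records:
            candidates = call_clusters(genes[r.id], hits[r.id], rules,
                                       r.id, len(r.seq) or 10 ** 9)
            clusters.extend(candidates)
        clusters = merge_overlaps(clusters)

        cf_predictions = {}
        if cf_model is not None:
            stage = "clusterfinder"
            unified = []
            for r in records:
                prediction = predict(
                    genes[r.id], hits[r.id], cf_model,
                    threshold=config.cf_threshold,
                    min_tokens=config.cf_min_tokens,
                    min_genes=config.cf_min_genes,
                    window=config.cf_window)
                cf_predictions[r.id] = prediction
                mine = [c for c in clusters if c.record_id == r.id]
                unified.extend(integrate_with_rules(
                    mine, prediction.regions, r.id, len(r.seq) or 10 ** 9))
            clusters = sorted(unified,
                              key=lambda c: (c.record_id, c.start, c.end))
            renumber = {}
            for c in clusters:
                renumber[c.record_id] = renumber.get(c.record_id, 0) + 1
                c.cluster_number = renumber[c.record_id]

        stage = "per_cluster_analyses"
        code_table = None
        for cluster in clusters:
            members = cluster_genes(cluster, genes[cluster.record_id])
            cluster.genes = members
            translations = {g.gene_id: g.translation for g in members}
            member_hits = [h for h in hits[cluster.record_id]
                           if h.gene_id in translations]
            motif_results = []
            inactive = frozenset()
            if config.active_sites:
                motif_results = run_default_set(
                    member_hits, translations,
                    {p.name: p.length for p in profiles})
                inactive = frozenset(scaffold_inactive_keys(motif_results))
                cluster.extras["motifs"] = motif_results
            if config.structure:
                if code_table is None:
                    from .structure import load_code_table
                    code_table = load_code_table()
                modules, scaffold = predict_cluster_structure(
                    members, member_hits, cluster.types,
                    inactive_keys=inactive, code_table=code_table)
                cluster.extras["modules"] = modules
                if scaffold is not None:
                    cluster.extras["scaffold"] = scaffold
            if config.lanthipeptides and "lantipeptide" in cluster.types:
                cluster.extras["lanthipeptides"] = analyze_lanthipeptides(
                    members)
            if config.smcog:
                families = {}
                for g in members:
                    call = assign_family(g, bundled.family_profiles())
                    if call is not None:
                        families[g.gene_id] = (
                            call[0], bundled.FAMILY_LABELS[call[0]], call[1])
                if families:
                    cluster.extras["families"] = families
            comparisons = []
            for source, refs in references.items():
                core = frozenset(
                    h.gene_id for h in member_hits
                    if h.profile in bundled.CORE_PROFILE_NAMES)
                ranked = compare_cluster(
                    members, refs, core_query_genes=core,
                    base_url=MIBIG_BASE_URL if source == "known" else None)
                comparisons.extend(ranked)
            if comparisons:
                cluster.extras["comparisons"] = comparisons

        results = AnalysisResults(
            records=records, genes=genes, hits=hits, clusters=clusters,
            cf_predictions=cf_predictions,
            manifest={
                "version": __version__,
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "n_records": len(records),
                "n_clusters": len(clusters),
            })

        if config.output_dir is not None:
            stage = "writers"
            _write_outputs(results, config)
        return results
    except BgcmineError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with stage and re-raise
        raise StageError(stage, exc) from exc


def _annotated_records(results: AnalysisResults) -> list:
    out = []
    gene_index = {}
    for record_genes in results.genes.values():
        for g in record_genes:
            gene_index[g.gene_id] = g
    for record in results.records:
        annotated = SequenceRecord(
            id=record.id, description=record.description, seq=record.seq,
            topology=record.topology,
            features=list(record.features),
            is_protein=record.is_protein)
        for cluster in results.clusters:
            if cluster.record_id != record.id:
                continue
            annotated.features.append(cluster_to_feature(cluster))
            for hit in cluster.supporting_hits:
                gene = gene_index.get(hit.gene_id)
                if gene is not None:
                    annotated.features.append(hit_to_feature(hit, gene))
        out.append(annotated)
    return out


def _write_outputs(results: AnalysisResults, config: PipelineConfig) -> None:
    out_dir = Path(config.output_dir)
    tmp = Path(tempfile.mkdtemp(prefix="bgcmine-out-"))
    try:
        annotated = _annotated_records(results)
        write_genbank(annotated, tmp / "results.gbk")
        if config.emit_embl:
            from .genome_io import write_embl
            write_embl(annotated, tmp / "results.embl")
        write_biosynml(results, tmp / "results.biosynml.xml")
        write_summary_tab(results, tmp / "summary.tsv")
        smiles_lines = []
        for cluster in results.clusters:
            scaffold = cluster.extras.get("scaffold")
            if scaffold is not None:
                smiles_lines.append(
                    f"{cluster.record_id}\tcluster{cluster.cluster_number}"
                    f"\t{scaffold.smiles}")
        (tmp / "scaffolds.smiles.tsv").write_text(
            "\n".join(smiles_lines) + ("\n" if smiles_lines else ""))
        (tmp / "run_manifest.json").write_text(
            json.dumps(results.manifest, indent=1, sort_keys=True) + "\n")
        out_dir.mkdir(parents=True, exist_ok=True)
        for item in tmp.iterdir():
            shutil.move(str(item), str(out_dir / item.name))
    finally:
        shutil.rmtree(tmp, ignore_errors=True)


# ---------------------------------------------------------------------------
# flat key=value config files (language-neutral)
# ---------------------------------------------------------------------------

_BOOL_KEYS = {"clusterfinder", "knownclusterblast", "clusterblast",
              "subclusterblast", "active_sites", "structure",
              "lanthipeptides", "smcog", "emit_embl"}
_INT_KEYS = {"cf_min_tokens", "cf_min_genes", "cf_window", "seed"}
_FLOAT_KEYS = {"cf_threshold"}


def load_config_file(path, base: Optional[PipelineConfig] = None
                     ) -> PipelineConfig:
    """Read a flat ``key = value`` config file; file values override the
    base config's fields."""
    config = base or PipelineConfig(inputs=[])
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, sep, value = line.partition("=")
            if not sep:
                raise BgcmineError(f"{path}: line {lineno}: expected key=value")
            key, value = key.strip(), value.strip()
            if key == "inputs":
                config.inputs = [v for v in value.split(",") if v]
            elif key in _BOOL_KEYS:
                setattr(config, key, value.lower() in ("1", "true", "yes"))
            elif key in _INT_KEYS:
                setattr(config, key, int(value))
            elif key in _FLOAT_KEYS:
                setattr(config, key, float(value))
            elif hasattr(config, key):
                setattr(config, key, value or None)
            else:
                raise BgcmineError(
                    f"{path}: line {lineno}: unknown key {key!r}")
    return config
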