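"""Cluster dereplication and comparison against reference collections.

One engine serves three analyses that differ only in the reference payload:
comparison against experimentally characterized clusters (dereplication),
against clusters detected in sequenced genomes, and against conserved
sub-operons.  Query proteins are aligned to every reference protein,
significant hits are kept (identity and coverage thresholds inherited from
the ClusterBlast lineage), and each reference is scored as::

    total_score = hit_gene_count + synteny_score + core_bonus

where ``synteny_score`` counts adjacent query-gene pairs whose best subject
genes are also consecutive (order-preserving) in the reference with a
consistent relative orientation, and ``core_bonus`` rewards hits that cover
a core biosynthetic gene.  References are ranked by total score and the
percentage of query genes with a hit is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .records import BgcmineError, Gene

DEFAULT_MIN_IDENTITY = 30.0
DEFAULT_MIN_COVERAGE = 25.0
DEFAULT_CORE_BONUS = 3
DEFAULT_TOP_N = 10

#: profiles whose presence marks a query gene as a core biosynthetic gene
DEFAULT_CORE_PROFILES = frozenset({"KS", "C", "A"})


@dataclass
class ReferenceCluster:
    """An ordered, stranded protein set for one characterized cluster."""

    ref_id: str
    label: str
    source: str  # known | genomic | subcluster
    genes: list  # of (gene_id, protein sequence, strand)

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"reference {self.ref_id} has no genes")
        ids = [g[0] for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError(f"reference {self.ref_id}: duplicate gene ids")
        if self.source not in ("known", "genomic", "subcluster"):
            raise ValueError(f"reference {self.ref_id}: bad source "
                             f"{self.source!r}")

    def gene_index(self, gene_id: str) -> int:
        for i, (gid, _, _) in enumerate(self.genes):
            if gid == gene_id:
                return i
        raise KeyError(gene_id)

    def gene_strand(self, gene_id: str) -> int:
        return self.genes[self.gene_index(gene_id)][2]


@dataclass
class SimilarityHit:
    query_gene: str
    subject_ref_id: str
    subject_gene: str
    percent_identity: float
    coverage: float
    score: float

    def __post_init__(self):
        if not (0 <= self.percent_identity <= 100):
            raise ValueError("identity out of range")
        if not (0 <= self.coverage <= 100):
            raise ValueError("coverage out of range")


@dataclass
class ClusterComparison:
    ref_id: str
    label: str
    hit_gene_count: int
    synteny_score: int
    core_bonus: int
    percent_query_genes_hit: float
    hyperlink: Optional[str] = None
    source: str = "known"
    hits: list = field(default_factory=list)

    @property
    def total_score(self) -> float:
        return self.hit_gene_count + self.synteny_score + self.core_bonus


# ---------------------------------------------------------------------------
# reference bundle I/O
# ---------------------------------------------------------------------------

def load_reference_bundle(fasta_path, sidecar_path=None, source="known"
                          ) -> list[ReferenceCluster]:
    """Load a reference collection.

    The FASTA headers are structured ``ref_id|gene_id|index|strand``; the
    optional tab-separated sidecar maps ``ref_id`` to a human-readable label
    (missing entries fall back to the ref_id itself).
    """
    labels: dict[str, str] = {}
    if sidecar_path is not None:
        with open(sidecar_path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                ref_id, _, label = line.partition("\t")
                labels[ref_id] = label or ref_id
    entries: dict[str, list] = {}
    seen: set = set()
    with open(fasta_path) as fh:
        header = None
        chunks: list[str] = []
        lineno_of_header = 0

        def flush():
            if header is None:
                return
            parts = header.split("|")
            if len(parts) != 4:
                raise BgcmineError(
                    f"{fasta_path}: line {lineno_of_header}: header "
                    f"{header!r} is not ref_id|gene_id|index|strand")
            ref_id, gene_id, index, strand = parts
            if (ref_id, gene_id) in seen:
                raise BgcmineError(
                    f"{fasta_path}: duplicate {ref_id}|{gene_id}")
            seen.add((ref_id, gene_id))
            entries.setdefault(ref_id, []).append(
                (int(index), gene_id, "".join(chunks), int(strand)))

        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0]
                lineno_of_header = lineno
                chunks = []
            elif line:
                chunks.append(line)
        flush()
    refs = []
    for ref_id in sorted(entries):
        genes = [(gid, seq, strand)
                 for _, gid, seq, strand in sorted(entries[ref_id])]
        refs.append(ReferenceCluster(ref_id, labels.get(ref_id, ref_id),
                                     source, genes))
    return refs


def save_reference_bundle(refs: Iterable[ReferenceCluster], fasta_path,
                          sidecar_path=None) -> None:
    with open(fasta_path, "w") as fh:
        for ref in refs:
            for index, (gid, seq, strand) in enumerate(ref.genes):
                fh.write(f">{ref.ref_id}|{gid}|{index}|{strand}\n{seq}\n")
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            for ref in refs:
                fh.write(f"{ref.ref_id}\t{ref.label}\n")


def reference_from_genes(ref_id: str, label: str, genes: Sequence[Gene],
                         source: str = "known") -> ReferenceCluster:
    """Turn a detected cluster's genes into a reference entry (self tests,
    bundle building)."""
    return ReferenceCluster(
        ref_id, label, source,
        [(g.gene_id, g.translation, g.strand)
         for g in sorted(genes, key=lambda g: g.start)])


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = None


def _aligner():
    global _ALIGNER
    if _ALIGNER is None:
        _ALIGNER = _make_aligner()
    return _ALIGNER


def _identity_and_span(alignment) -> tuple[int, int]:
    """(identical pairs, aligned residue-pair columns) of a local alignment."""
    identical = 0
    aligned = 0
    qseq, sseq = alignment.sequences
    for (qs, qe), (ss, se) in zip(*alignment.aligned):
        aligned += qe - qs
        for k in range(qe - qs):
            if qseq[qs + k] == sseq[ss + k]:
                identical += 1
    return identical, aligned


def align_pair(query_seq: str, subject_seq: str) -> Optional[tuple]:
    """Local alignment; returns (identity %, coverage %, score) or None."""
    aligner = _aligner()
    # substitution matrices only know the 24-letter alphabet
    q = "".join(c if c in "ACDEFGHIKLMNPQRSTVWYBZX*" else "X"
                for c in query_seq.upper())
    s = "".join(c if c in "ACDEFGHIKLMNPQRSTVWYBZX*" else "X"
                for c in subject_seq.upper())
    score = aligner.score(q, s)
    if score <= 0:
        return None
    alignment = next(iter(aligner.align(q, s)))
    identical, aligned = _identity_and_span(alignment)
    if aligned == 0:
        return None
    identity = 100.0 * identical / aligned
    coverage = 100.0 * aligned / min(len(q), len(s))
    return identity, min(coverage, 100.0), float(score)


def align_proteins(query_genes: Sequence[Gene],
                   references: Sequence[ReferenceCluster]
                   ) -> list[SimilarityHit]:
    """All-vs-all local alignment of query genes against reference genes."""
    hits: list[SimilarityHit] = []
    for gene in query_genes:
        for ref in references:
            for gid, seq, _strand in ref.genes:
                result = align_pair(gene.translation, seq)
                if result is None:
                    continue
                identity, coverage, score = result
                hits.append(SimilarityHit(gene.gene_id, ref.ref_id, gid,
                                          identity, coverage, score))
    return hits


def parse_tabular_alignments(path, source_ref_ids: Iterable[str]
                             ) -> list[SimilarityHit]:
    """Adapter for 12-column tabular alignment output (qseqid sseqid pident
    length mismatch gapopen qstart qend sstart send evalue bitscore).

    Subject ids must be structured ``ref_id|gene_id|index|strand``; coverage
    cannot be recovered exactly from the row, so aligned length over the
    subject span is used as reported.
    """
    known = set(source_ref_ids)
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise BgcmineError(f"{path}: line {lineno}: not 12 columns")
            sparts = f[1].split("|")
            if len(sparts) != 4:
                raise BgcmineError(
                    f"{path}: line {lineno}: subject id {f[1]!r} lacks "
                    "ref_id|gene_id|index|strand structure")
            ref_id, gene_id = sparts[0], sparts[1]
            if ref_id not in known:
                continue
            length = int(f[3])
            qspan = abs(int(f[7]) - int(f[6])) + 1
            sspan = abs(int(f[9]) - int(f[8])) + 1
            coverage = 100.0 * length / max(1, min(qspan, sspan))
            hits.append(SimilarityHit(
                f[0], ref_id, gene_id,
                float(f[2]), min(coverage, 100.0), float(f[11])))
    return hits


# ---------------------------------------------------------------------------
# significance filtering, scoring, ranking
# ---------------------------------------------------------------------------

def filter_significant(
    hits: Sequence[SimilarityHit],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list[SimilarityHit]:
    """Identity/coverage thresholds (inclusive), then best subject gene per
    (query gene, reference cluster)."""
    passing = [h for h in hits
               if h.percent_identity >= min_identity
               and h.coverage >= min_coverage]
    best: dict[tuple, SimilarityHit] = {}
    for h in sorted(passing, key=lambda h: (h.query_gene, h.subject_ref_id,
                                            -h.score, h.subject_gene)):
        best.setdefault((h.query_gene, h.subject_ref_id), h)
    return sorted(best.values(),
                  key=lambda h: (h.query_gene, h.subject_ref_id))


def score_comparison(
    query_genes: Sequence[Gene],
    reference: ReferenceCluster,
    hits: Sequence[SimilarityHit],
    core_query_genes: frozenset = frozenset(),
    core_bonus_value: int = DEFAULT_CORE_BONUS,
) -> ClusterComparison:
    """Score one reference against the query cluster.

    ``hits`` must already be significance-filtered; only hits against this
    reference are considered.  ``core_query_genes`` lists query gene ids
    carrying a core biosynthetic domain.
    """
    ref_hits = [h for h in hits if h.subject_ref_id == reference.ref_id]
    by_query = {h.query_gene: h for h in ref_hits}
    ordered = sorted(query_genes, key=lambda g: (g.start, g.gene_id))
    hit_gene_count = sum(1 for g in ordered if g.gene_id in by_query)
    synteny = 0
    for a, b in zip(ordered, ordered[1:]):
        ha, hb = by_query.get(a.gene_id), by_query.get(b.gene_id)
        if ha is None or hb is None:
            continue
        try:
            ja = reference.gene_index(ha.subject_gene)
            jb = reference.gene_index(hb.subject_gene)
        except KeyError:
            continue
        if jb != ja + 1:
            continue
        sa = reference.gene_strand(ha.subject_gene)
        sb = reference.gene_strand(hb.subject_gene)
        if a.strand * b.strand == sa * sb:
            synteny += 1
    core = (core_bonus_value
            if any(g.gene_id in by_query and g.gene_id in core_query_genes
                   for g in ordered) else 0)
    percent = (100.0 * hit_gene_count / len(ordered)) if ordered else 0.0
    return ClusterComparison(
        ref_id=reference.ref_id,
        label=reference.label,
        hit_gene_count=hit_gene_count,
        synteny_score=synteny,
        core_bonus=core,
        percent_query_genes_hit=percent,
        source=reference.source,
        hits=ref_hits,
    )


def rank(comparisons: Sequence[ClusterComparison],
         top_n: int = DEFAULT_TOP_N) -> list[ClusterComparison]:
    """Descending total score; ties by percent hit, then ref_id."""
    ordered = sorted(
        comparisons,
        key=lambda c: (-c.total_score, -c.percent_query_genes_hit, c.ref_id))
    return ordered[:top_n]


def attach_links(comparison: ClusterComparison,
                 base_url: str) -> ClusterComparison:
    """Hyperlink characterized references to their repository entry."""
    if comparison.source == "known":
        comparison.hyperlink = base_url + comparison.ref_id
    else:
        comparison.hyperlink = None
    return comparison


def compare_cluster(
    query_genes: Sequence[Gene],
    references: Sequence[ReferenceCluster],
    core_query_genes: frozenset = frozenset(),
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    top_n: int = DEFAULT_TOP_N,
    base_url: Optional[str] = None,
) -> list[ClusterComparison]:
    """Full pipeline: align, filter, score every reference, rank, link.

    References with zero kept hits are dropped before ranking.
    """
    raw = align_proteins(query_genes, references)
    kept = filter_significant(raw, min_identity, min_coverage)
    comparisons = []
    for ref in references:
        comp = score_comparison(query_genes, ref, kept, core_query_genes)
        if comp.hit_gene_count > 0:
            comparisons.append(comp)
    ranked = rank(comparisons, top_n)
    if base_url is not None:
        ranked = [attach_links(c, base_url) for c in ranked]
    return ranked
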