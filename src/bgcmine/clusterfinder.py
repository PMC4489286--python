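"""Probabilistic, rule-independent cluster detection.

A two-state hidden Markov model (states: inside a biosynthetic region vs.
genomic background) runs over the genome's ordered sequence of domain
annotations.  Emission distributions over the domain vocabulary encode how
much more often each domain family occurs inside known clusters than
outside.  Posterior decoding (forward-backward with per-position scaling)
yields P(cluster) per domain token; posteriors are smoothed with a centred
moving average and maximal above-threshold runs become called regions,
classified into saccharide / fatty-acid / putative subtypes by marker-domain
counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .records import BgcmineError, DomainHit, Gene
from .rules import ClusterPrediction

UNKNOWN = "UNKNOWN"

STATE_BGC, STATE_BG = 0, 1

DEFAULT_THRESHOLD = 0.6
DEFAULT_MIN_TOKENS = 5
DEFAULT_MIN_GENES = 5
DEFAULT_WINDOW = 5


@dataclass
class CfModel:
    """Two-state HMM over a domain vocabulary.

    ``emissions[s][token]`` is the emission probability of ``token`` in state
    ``s`` (0 = cluster, 1 = background).  Both states must include the
    ``UNKNOWN`` token so that out-of-vocabulary domains stay decodable.
    """

    initial: np.ndarray  # (2,)
    transitions: np.ndarray  # (2, 2)
    emissions: tuple[dict, dict]

    def __post_init__(self):
        self.initial = np.asarray(self.initial, float)
        self.transitions = np.asarray(self.transitions, float)
        if abs(self.initial.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution not normalized")
        for row in self.transitions:
            if abs(row.sum() - 1.0) > 1e-9:
                raise ValueError("transition row not normalized")
        for s, table in enumerate(self.emissions):
            if UNKNOWN not in table:
                raise ValueError(f"state {s} emissions lack {UNKNOWN}")
            total = sum(table.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"state {s} emissions sum to {total}")

    @property
    def vocabulary(self) -> set:
        return set(self.emissions[0]) | set(self.emissions[1])

    def emission(self, state: int, token: str) -> float:
        table = self.emissions[state]
        return table.get(token, table[UNKNOWN])


def load_cf_model(path) -> CfModel:
    """Read a model from the documented JSON format."""
    with open(path) as fh:
        raw = json.load(fh)
    return CfModel(
        initial=np.array(raw["initial"], float),
        transitions=np.array(raw["transitions"], float),
        emissions=(dict(raw["emissions"]["bgc"]),
                   dict(raw["emissions"]["background"])),
    )


def save_cf_model(model: CfModel, path) -> None:
    with open(path, "w") as fh:
        json.dump({
            "states": ["bgc", "background"],
            "initial": list(model.initial),
            "transitions": [list(r) for r in model.transitions],
            "emissions": {"bgc": model.emissions[0],
                          "background": model.emissions[1]},
        }, fh, indent=1, sort_keys=True)


@dataclass
class Token:
    """One domain annotation in genomic order, with its gene's span."""

    name: str
    gene_id: str
    start: int
    end: int


@dataclass
class CfRegion:
    start_token: int
    end_token: int  # half-open
    start: int
    end: int
    mean_probability: float
    cf_type: str = "Cf_putative"


@dataclass
class CfPrediction:
    tokens: list
    token_posteriors: list
    regions: list = field(default_factory=list)


def tokenize(genes: Sequence[Gene], hits: Sequence[DomainHit],
             vocabulary: Optional[set] = None) -> list[Token]:
    """Order one record's filtered hits into the HMM's token sequence.

    Hits are sorted by gene start then envelope start; profile names absent
    from ``vocabulary`` map to ``UNKNOWN``.  Each token keeps its gene's
    genomic interval.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    located = []
    for h in hits:
        gene = gene_by_id.get(h.gene_id)
        if gene is None:
            raise BgcmineError(f"hit references unknown gene {h.gene_id}")
        located.append((gene.start, h.env_start, h))
    located.sort(key=lambda t: (t[0], t[1], t[2].profile))
    tokens = []
    for gene_start, _, h in located:
        gene = gene_by_id[h.gene_id]
        name = h.profile
        if vocabulary is not None and name not in vocabulary:
            name = UNKNOWN
        tokens.append(Token(name, h.gene_id, gene.start, gene.end))
    return tokens


def posterior_decode(tokens: Sequence[Token], model: CfModel) -> list[float]:
    """P(cluster state) per token via scaled forward-backward."""
    if not tokens:
        raise BgcmineError("posterior_decode requires a non-empty token list")
    n = len(tokens)
    e = np.empty((n, 2))
    for i, tok in enumerate(tokens):
        e[i, 0] = model.emission(STATE_BGC, tok.name)
        e[i, 1] = model.emission(STATE_BG, tok.name)
        if e[i].sum() == 0:
            raise BgcmineError(
                f"token {tok.name!r} has zero emission probability in both "
                "states; model and vocabulary are inconsistent")
    T = model.transitions
    alpha = np.empty((n, 2))
    scale = np.empty(n)
    alpha[0] = model.initial * e[0]
    scale[0] = alpha[0].sum()
    alpha[0] /= scale[0]
    for i in range(1, n):
        alpha[i] = (alpha[i - 1] @ T) * e[i]
        scale[i] = alpha[i].sum()
        alpha[i] /= scale[i]
    beta = np.empty((n, 2))
    beta[-1] = 1.0
    for i in range(n - 2, -1, -1):
        beta[i] = (T @ (e[i + 1] * beta[i + 1])) / scale[i + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return [float(p) for p in gamma[:, STATE_BGC]]


def sequence_loglik(tokens: Sequence[Token], model: CfModel) -> float:
    """log P(token sequence | model), from the forward scaling factors."""
    if not tokens:
        raise BgcmineError("empty token list")
    n = len(tokens)
    e = np.array([[model.emission(0, t.name), model.emission(1, t.name)]
                  for t in tokens])
    alpha = model.initial * e[0]
    log_l = 0.0
    for i in range(n):
        if i:
            alpha = (alpha @ model.transitions) * e[i]
        s = alpha.sum()
        log_l += float(np.log(s))
        alpha = alpha / s
    return log_l


def smooth(posteriors: Sequence[float], window: int = DEFAULT_WINDOW
           ) -> list[float]:
    """Centred moving average; the window truncates at the boundaries."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window == 1:
        return list(posteriors)
    half = window // 2
    n = len(posteriors)
    out = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        seg = posteriors[lo:hi]
        out.append(sum(seg) / len(seg))
    return out


def call_regions(
    tokens: Sequence[Token],
    smoothed: Sequence[float],
    threshold: float = DEFAULT_THRESHOLD,
    min_tokens: int = DEFAULT_MIN_TOKENS,
    min_genes: int = DEFAULT_MIN_GENES,
) -> list[CfRegion]:
    """Maximal runs of above-threshold tokens, size-filtered.

    A run survives iff it spans at least ``min_tokens`` tokens *and* at
    least ``min_genes`` distinct genes.  The genomic span is the min/max of
    the member tokens' gene intervals; the reported probability is the mean
    of the smoothed posteriors over the run.
    """
    regions: list[CfRegion] = []
    i, n = 0, len(tokens)
    while i < n:
        if smoothed[i] < threshold:
            i += 1
            continue
        j = i
        while j < n and smoothed[j] >= threshold:
            j += 1
        genes = {tokens[k].gene_id for k in range(i, j)}
        if (j - i) >= min_tokens and len(genes) >= min_genes:
            regions.append(CfRegion(
                start_token=i,
                end_token=j,
                start=min(tokens[k].start for k in range(i, j)),
                end=max(tokens[k].end for k in range(i, j)),
                mean_probability=float(np.mean(smoothed[i:j])),
            ))
        i = j
    return regions


#: marker profile lists for region classification (configuration, not truth)
DEFAULT_SACCHARIDE_MARKERS = ("Glycos_transf", "Sugar_epim")
DEFAULT_FATTY_ACID_MARKERS = ("FabH", "FabF")
DEFAULT_MARKER_MIN = 2


def classify_region(
    region: CfRegion,
    tokens: Sequence[Token],
    saccharide_markers: Sequence[str] = DEFAULT_SACCHARIDE_MARKERS,
    fatty_acid_markers: Sequence[str] = DEFAULT_FATTY_ACID_MARKERS,
    marker_min: int = DEFAULT_MARKER_MIN,
) -> str:
    """Cf_saccharide / Cf_fatty_acid / Cf_putative call for one region.

    Saccharide markers take precedence over fatty-acid markers when both
    lists reach their count threshold.
    """
    names = [tokens[k].name for k in range(region.start_token,
                                           region.end_token)]
    sac = sum(1 for n in names if n in set(saccharide_markers))
    fat = sum(1 for n in names if n in set(fatty_acid_markers))
    if sac >= marker_min:
        return "Cf_saccharide"
    if fat >= marker_min:
        return "Cf_fatty_acid"
    return "Cf_putative"


def predict(
    genes: Sequence[Gene],
    hits: Sequence[DomainHit],
    model: CfModel,
    threshold: float = DEFAULT_THRESHOLD,
    min_tokens: int = DEFAULT_MIN_TOKENS,
    min_genes: int = DEFAULT_MIN_GENES,
    window: int = DEFAULT_WINDOW,
) -> CfPrediction:
    """Full per-record pipeline: tokenize, decode, smooth, call, classify."""
    tokens = tokenize(genes, hits, vocabulary=model.vocabulary)
    if not tokens:
        return CfPrediction(tokens=[], token_posteriors=[])
    posteriors = posterior_decode(tokens, model)
    smoothed = smooth(posteriors, window)
    regions = call_regions(tokens, smoothed, threshold, min_tokens, min_genes)
    for region in regions:
        region.cf_type = classify_region(region, tokens)
    return CfPrediction(tokens=tokens, token_posteriors=posteriors,
                        regions=regions)


def integrate_with_rules(
    rule_clusters: Sequence[ClusterPrediction],
    cf_regions: Sequence[CfRegion],
    record_id: str,
    record_length: int,
) -> list[ClusterPrediction]:
    """Combine probabilistic regions with rule-based clusters.

    A region overlapping (by at least 1 bp) a rule-based cluster annotates
    that cluster with its probability; non-overlapping regions become
    standalone predictions with ``detection="clusterfinder"``.  Numbering is
    reassigned left to right.
    """
    clusters = list(rule_clusters)
    extra: list[ClusterPrediction] = []
    for region in cf_regions:
        overlapping = [c for c in clusters
                       if c.record_id == record_id
                       and c.start < region.end and region.start < c.end]
        if overlapping:
            for c in overlapping:
                if c.probability is None or region.mean_probability > c.probability:
                    c.probability = region.mean_probability
        else:
            extra.append(ClusterPrediction(
                record_id=record_id,
                cluster_number=0,
                types=[region.cf_type],
                core_start=region.start,
                core_end=region.end,
                start=max(0, region.start),
                end=min(record_length, region.end),
                detection="clusterfinder",
                probability=region.mean_probability,
            ))
    unified = clusters + extra
    unified.sort(key=lambda c: (c.record_id, c.start, c.end))
    for number, c in enumerate(unified, 1):
        c.cluster_number = number
    return unified
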