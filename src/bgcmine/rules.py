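"""Rule-based biosynthetic gene cluster detection.

A cluster rule names a compound class (t1pks, nrps, terpene, ...) and gives a
boolean expression over profile names that must be satisfied by the domain
content of a group of neighbouring genes.  Genes carrying hits to profiles
mentioned in the rule are grouped greedily left to right while consecutive
contributing genes lie within ``cutoff_kb``; each group is tested against the
expression, and satisfied groups become cluster candidates whose core span is
extended by ``extension_kb`` on both sides.

Rule file stanzas look like::

    RULE t1pks
    CUTOFF 20
    EXTENSION 20
    CONDITION KS and AT

with expression grammar (precedence NOT > AND > OR, parentheses allowed)::

    expr     := term ("or" term)*
    term     := factor ("and" factor)*
    factor   := "not" factor | "(" expr ")" | atom
    atom     := NAME | "minimum" "(" INT "," "[" NAME ("," NAME)* "]" ")"
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .records import BgcmineError, DomainHit, Gene


class RuleParseError(BgcmineError):
    pass


# ---------------------------------------------------------------------------
# expression tree
# ---------------------------------------------------------------------------

class RuleExpression:
    """Base class; subclasses implement ``evaluate(present)`` over a set of
    profile names and ``profile_names()`` listing every referenced name."""

    def evaluate(self, present: set) -> bool:  # pragma: no cover - abstract
        raise NotImplementedError

    def profile_names(self) -> set:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass(frozen=True)
class Domain(RuleExpression):
    name: str

    def evaluate(self, present):
        return self.name in present

    def profile_names(self):
        return {self.name}

    def __str__(self):
        return self.name


@dataclass(frozen=True)
class And(RuleExpression):
    terms: tuple

    def evaluate(self, present):
        return all(t.evaluate(present) for t in self.terms)

    def profile_names(self):
        return set().union(*(t.profile_names() for t in self.terms))

    def __str__(self):
        return "(" + " and ".join(map(str, self.terms)) + ")"


@dataclass(frozen=True)
class Or(RuleExpression):
    terms: tuple

    def evaluate(self, present):
        return any(t.evaluate(present) for t in self.terms)

    def profile_names(self):
        return set().union(*(t.profile_names() for t in self.terms))

    def __str__(self):
        return "(" + " or ".join(map(str, self.terms)) + ")"


@dataclass(frozen=True)
class Not(RuleExpression):
    term: RuleExpression

    def evaluate(self, present):
        return not self.term.evaluate(present)

    def profile_names(self):
        return self.term.profile_names()

    def __str__(self):
        return f"not {self.term}"


@dataclass(frozen=True)
class Minimum(RuleExpression):
    """True iff at least ``n`` distinct listed profiles are present."""

    n: int
    names: tuple

    def evaluate(self, present):
        return sum(1 for name in self.names if name in present) >= self.n

    def profile_names(self):
        return set(self.names)

    def __str__(self):
        return f"minimum({self.n},[{','.join(self.names)}])"


def _is_positive(expr: RuleExpression) -> bool:
    """A rule must be satisfiable by hit presence: reject bare/or'd NOT."""
    if isinstance(expr, Not):
        return False
    if isinstance(expr, Or):
        return all(_is_positive(t) for t in expr.terms)
    if isinstance(expr, And):
        return any(_is_positive(t) for t in expr.terms)
    return True


@dataclass
class ClusterRule:
    type_name: str
    expression: RuleExpression
    cutoff_kb: float
    extension_kb: float

    def __post_init__(self):
        if self.cutoff_kb <= 0:
            raise ValueError(f"rule {self.type_name}: cutoff must be > 0")
        if self.extension_kb < 0:
            raise ValueError(f"rule {self.type_name}: extension must be >= 0")
        if not _is_positive(self.expression):
            raise RuleParseError(
                f"rule {self.type_name}: expression is not satisfiable by "
                "hit presence (NOT must be conjoined with a positive term)")


@dataclass
class ClusterPrediction:
    """A called cluster; ``types`` with more than one entry marks a hybrid."""

    record_id: str
    cluster_number: int
    types: list
    core_start: int
    core_end: int
    start: int
    end: int
    supporting_hits: list = field(default_factory=list)
    detection: str = "rules"  # or "clusterfinder"
    probability: Optional[float] = None
    #: populated by downstream per-cluster analyses
    genes: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.start <= self.core_start < self.core_end <= self.end):
            raise ValueError(
                f"cluster span invariant violated: {self.start} <= "
                f"{self.core_start} < {self.core_end} <= {self.end}")

    @property
    def type_label(self) -> str:
        return "-".join(self.types)

    def overlaps(self, other: "ClusterPrediction") -> bool:
        return (self.record_id == other.record_id
                and self.start < other.end and other.start < self.end)


# ---------------------------------------------------------------------------
# rule parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\(|\)|\[|\]|,|[A-Za-z_][A-Za-z0-9_.-]*|\d+)")


def _tokenize(text: str, where: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise RuleParseError(f"{where}: cannot tokenize at {text[pos:]!r}")
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens, where):
        self.tokens = tokens
        self.pos = 0
        self.where = where

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is None:
            raise RuleParseError(f"{self.where}: unexpected end of expression")
        self.pos += 1
        return tok

    def expect(self, tok):
        got = self.next()
        if got != tok:
            raise RuleParseError(f"{self.where}: expected {tok!r}, got {got!r}")

    def parse(self):
        expr = self.expr()
        if self.peek() is not None:
            raise RuleParseError(
                f"{self.where}: trailing tokens at {self.peek()!r}")
        return expr

    def expr(self):
        terms = [self.term()]
        while self.peek() == "or":
            self.next()
            terms.append(self.term())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def term(self):
        factors = [self.factor()]
        while self.peek() == "and":
            self.next()
            factors.append(self.factor())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def factor(self):
        tok = self.peek()
        if tok == "not":
            self.next()
            return Not(self.factor())
        if tok == "(":
            self.next()
            inner = self.expr()
            self.expect(")")
            return inner
        if tok == "minimum":
            self.next()
            self.expect("(")
            n = int(self.next())
            self.expect(",")
            self.expect("[")
            names = [self.next()]
            while self.peek() == ",":
                self.next()
                names.append(self.next())
            self.expect("]")
            self.expect(")")
            return Minimum(n, tuple(names))
        name = self.next()
        if name in ("and", "or", ")", "]", ","):
            raise RuleParseError(f"{self.where}: unexpected token {name!r}")
        return Domain(name)


def parse_expression(text: str, where: str = "expression") -> RuleExpression:
    return _Parser(_tokenize(text, where), where).parse()


def parse_rules(path, known_profiles: Optional[Iterable[str]] = None
                ) -> list[ClusterRule]:
    """Parse a rule file; ``known_profiles`` enables name validation."""
    known = set(known_profiles) if known_profiles is not None else None
    rules: list[ClusterRule] = []
    current: dict = {}

    def flush(where):
        if not current:
            return
        for key in ("type", "cutoff", "extension", "condition"):
            if key not in current:
                raise RuleParseError(f"{where}: rule missing {key.upper()}")
        expr = parse_expression(current["condition"],
                                f"rule {current['type']}")
        if known is not None:
            unknown = expr.profile_names() - known
            if unknown:
                raise RuleParseError(
                    f"rule {current['type']}: unknown profile name(s) "
                    + ", ".join(sorted(unknown)))
        rules.append(ClusterRule(current["type"], expr,
                                 float(current["cutoff"]),
                                 float(current["extension"])))
        current.clear()

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition(" ")
            key = key.upper()
            value = value.strip()
            if key == "RULE":
                flush(f"line {lineno}")
                current["type"] = value
            elif key in ("CUTOFF", "EXTENSION", "CONDITION"):
                if "type" not in current:
                    raise RuleParseError(f"line {lineno}: {key} before RULE")
                current[key.lower()] = value
            else:
                raise RuleParseError(f"line {lineno}: unknown keyword {key}")
    flush("end of file")
    if not rules:
        raise RuleParseError("rule file defines no rules")
    names = [r.type_name for r in rules]
    if len(names) != len(set(names)):
        raise RuleParseError("duplicate rule type names")
    return rules


# ---------------------------------------------------------------------------
# cluster calling
# ---------------------------------------------------------------------------

def _hits_by_gene(hits: Sequence[DomainHit]) -> dict:
    by_gene: dict[str, set] = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, set()).add(h.profile)
    return by_gene


def call_clusters(
    genes: Sequence[Gene],
    hits: Sequence[DomainHit],
    rules: Sequence[ClusterRule],
    record_id: str,
    record_length: int,
) -> list[ClusterPrediction]:
    """Evaluate every rule over one record's genes and filtered hits.

    Candidates are returned unmerged and unnumbered (``cluster_number`` 0);
    run :func:`merge_overlaps` to obtain the final cluster list.
    """
    profiles_by_gene = _hits_by_gene(hits)
    hits_by_gene: dict[str, list[DomainHit]] = {}
    for h in hits:
        hits_by_gene.setdefault(h.gene_id, []).append(h)
    genes_sorted = sorted(genes, key=lambda g: (g.start, g.end, g.gene_id))
    candidates: list[ClusterPrediction] = []
    for rule in rules:
        wanted = rule.expression.profile_names()
        contributing = [g for g in genes_sorted
                        if profiles_by_gene.get(g.gene_id, set()) & wanted]
        if not contributing:
            continue
        cutoff_bp = rule.cutoff_kb * 1000
        groups: list[list[Gene]] = [[contributing[0]]]
        for gene in contributing[1:]:
            # gap between nearest gene boundaries
            if gene.start - groups[-1][-1].end <= cutoff_bp:
                groups[-1].append(gene)
            else:
                groups.append([gene])
        for group in groups:
            present = set()
            for g in group:
                present |= profiles_by_gene.get(g.gene_id, set())
            if not rule.expression.evaluate(present):
                continue
            core_start = min(g.start for g in group)
            core_end = max(g.end for g in group)
            ext = int(rule.extension_kb * 1000)
            support = [h for g in group
                       for h in hits_by_gene.get(g.gene_id, [])]
            support.sort(key=lambda h: (h.gene_id, h.env_start, h.profile))
            candidates.append(ClusterPrediction(
                record_id=record_id,
                cluster_number=0,
                types=[rule.type_name],
                core_start=core_start,
                core_end=core_end,
                start=max(0, core_start - ext),
                end=min(record_length, core_end + ext),
                supporting_hits=support,
                detection="rules",
            ))
    candidates.sort(key=lambda c: (c.start, c.end, c.types))
    return candidates


def merge_overlaps(candidates: Sequence[ClusterPrediction]
                   ) -> list[ClusterPrediction]:
    """Merge overlapping candidate spans into final numbered clusters.

    The merged span is the union; types are deduplicated in ascending
    ``core_start`` order of the contributing candidates; numbering is
    reassigned left to right per record.  Idempotent and independent of the
    input order.
    """
    by_record: dict[str, list[ClusterPrediction]] = {}
    for c in candidates:
        by_record.setdefault(c.record_id, []).append(c)
    merged_all: list[ClusterPrediction] = []
    for record_id in sorted(by_record):
        pool = sorted(by_record[record_id],
                      key=lambda c: (c.start, c.end, c.core_start, c.types))
        merged: list[list[ClusterPrediction]] = []
        for cand in pool:
            if merged and cand.start < max(c.end for c in merged[-1]):
                merged[-1].append(cand)
            else:
                merged.append([cand])
        for number, group in enumerate(merged, 1):
            group_sorted = sorted(group, key=lambda c: (c.core_start, c.types))
            types: list[str] = []
            for c in group_sorted:
                for t in c.types:
                    if t not in types:
                        types.append(t)
            seen = set()
            support = []
            for c in group_sorted:
                for h in c.supporting_hits:
                    key = (h.gene_id, h.profile, h.env_start, h.env_end)
                    if key not in seen:
                        seen.add(key)
                        support.append(h)
            support.sort(key=lambda h: (h.gene_id, h.env_start, h.profile))
            probs = [c.probability for c in group_sorted
                     if c.probability is not None]
            merged_all.append(ClusterPrediction(
                record_id=record_id,
                cluster_number=number,
                types=types,
                core_start=min(c.core_start for c in group),
                core_end=max(c.core_end for c in group),
                start=min(c.start for c in group),
                end=max(c.end for c in group),
                supporting_hits=support,
                detection=("rules" if any(c.detection == "rules" for c in group)
                           else "clusterfinder"),
                probability=max(probs) if probs else None,
            ))
    return merged_all
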