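"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (path enumeration, all-intervals
search, log-space recursions) and shares no code with the package's
implementations it checks.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

from bgcmine.hmm import (ProfileModel, T_MM, T_MI, T_MD, T_IM, T_II, T_DM,
                         T_DD, encode_protein)


# ---------------------------------------------------------------------------
# profile-HMM single-hit path enumeration
# ---------------------------------------------------------------------------

def enumerate_hit_scores(seq: str, profile: ProfileModel) -> list:
    """Log2-odds score of every legal single-hit path (entry at any match
    column, exit from any match column, uniform 1/L entry/exit weights)."""
    x = encode_protein(seq)
    n = len(x)
    L = profile.length
    lp = {}

    def lo(table, c, xi):
        if xi < 0:
            return 0.0
        p = table[c, xi]
        if p <= 0:
            return -math.inf
        return math.log2(p) - math.log2(profile.null_model[xi])

    def lt(c, idx):
        p = profile.transitions[c, idx]
        return math.log2(p) if p > 0 else -math.inf

    entry = -math.log2(L)
    scores = []

    def walk(state, c, pos, acc):
        # state in {"M", "I", "D"}; c = current column (0-based);
        # pos = index of next unconsumed residue
        if acc == -math.inf:
            return
        if state == "M":
            scores.append(acc + entry)  # exit here
            if c + 1 < L:
                if pos < n:
                    walk("M", c + 1, pos + 1,
                         acc + lt(c, T_MM) + lo(profile.match_emissions,
                                                c + 1, x[pos]))
                walk("D", c + 1, pos, acc + lt(c, T_MD))
            if pos < n:
                walk("I", c, pos + 1,
                     acc + lt(c, T_MI) + lo(profile.insert_emissions,
                                            c, x[pos]))
        elif state == "I":
            if c + 1 < L and pos < n:
                walk("M", c + 1, pos + 1,
                     acc + lt(c, T_IM) + lo(profile.match_emissions,
                                            c + 1, x[pos]))
            if pos < n:
                walk("I", c, pos + 1,
                     acc + lt(c, T_II) + lo(profile.insert_emissions,
                                            c, x[pos]))
        else:  # D
            if c + 1 < L:
                if pos < n:
                    walk("M", c + 1, pos + 1,
                         acc + lt(c, T_DM) + lo(profile.match_emissions,
                                                c + 1, x[pos]))
                walk("D", c + 1, pos, acc + lt(c, T_DD))

    for i in range(n):
        for k in range(L):
            walk("M", k, i + 1,
                 entry + lo(profile.match_emissions, k, x[i]))
    return scores


def brute_viterbi(seq: str, profile: ProfileModel) -> float:
    scores = enumerate_hit_scores(seq, profile)
    return max(scores) if scores else -math.inf


def brute_forward(seq: str, profile: ProfileModel) -> float:
    scores = [s for s in enumerate_hit_scores(seq, profile)
              if s > -math.inf]
    if not scores:
        return -math.inf
    m = max(scores)
    return m + math.log2(sum(2 ** (s - m) for s in scores))


def random_profile(rng, length: int) -> ProfileModel:
    """A fully random (Dirichlet) profile for oracle comparisons."""
    match = rng.dirichlet(np.ones(20), size=length)
    insert = rng.dirichlet(np.ones(20), size=length)
    trans = np.empty((length, 7))
    trans[:, [T_MM, T_MI, T_MD]] = rng.dirichlet(np.ones(3), size=length)
    trans[:, [T_IM, T_II]] = rng.dirichlet(np.ones(2), size=length)
    trans[:, [T_DM, T_DD]] = rng.dirichlet(np.ones(2), size=length)
    null = rng.dirichlet(np.ones(20))
    return ProfileModel("rand", length, match, insert, trans, null, 0.0)


# ---------------------------------------------------------------------------
# two-state HMM posterior enumeration
# ---------------------------------------------------------------------------

def brute_posteriors(token_names, model) -> list:
    """P(state 0 at i) by summing over all 2^n state paths."""
    n = len(token_names)
    weights = {}
    total = 0.0
    for path in product((0, 1), repeat=n):
        p = model.initial[path[0]] * model.emission(path[0], token_names[0])
        for i in range(1, n):
            p *= (model.transitions[path[i - 1], path[i]]
                  * model.emission(path[i], token_names[i]))
        total += p
        weights[path] = p
    post = []
    for i in range(n):
        post.append(sum(p for path, p in weights.items() if path[i] == 0)
                    / total)
    return post


def log_forward_backward_loglik(token_names, model) -> tuple:
    """(forward log-likelihood, backward log-likelihood) in log space."""
    n = len(token_names)
    le = np.log([[model.emission(s, t) for s in (0, 1)]
                 for t in token_names])
    lT = np.log(model.transitions)
    li = np.log(model.initial)
    lf = li + le[0]
    for i in range(1, n):
        lf = np.array([
            np.logaddexp(lf[0] + lT[0, s], lf[1] + lT[1, s]) + le[i, s]
            for s in (0, 1)])
    fwd = np.logaddexp(lf[0], lf[1])
    lb = np.zeros(2)
    for i in range(n - 2, -1, -1):
        lb = np.array([
            np.logaddexp(lT[s, 0] + le[i + 1, 0] + lb[0],
                         lT[s, 1] + le[i + 1, 1] + lb[1])
            for s in (0, 1)])
    bwd = np.logaddexp(li[0] + le[0, 0] + lb[0], li[1] + le[0, 1] + lb[1])
    return float(fwd), float(bwd)


# ---------------------------------------------------------------------------
# rule engine: all-intervals evaluator
# ---------------------------------------------------------------------------

def brute_rule_candidates(genes, hits, rules):
    """Candidate (type, core_start, core_end) triples via exhaustive search.

    For each rule: contributing genes are those hitting a mentioned
    profile; every contiguous run of contributing genes is tested for the
    gap constraint and maximality, then for the expression over all
    profiles hit by its members.
    """
    by_gene = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, set()).add(h.profile)
    ordered = sorted(genes, key=lambda g: (g.start, g.end, g.gene_id))
    out = set()
    for rule in rules:
        wanted = rule.expression.profile_names()
        contrib = [g for g in ordered if by_gene.get(g.gene_id, set()) & wanted]
        cutoff = rule.cutoff_kb * 1000
        m = len(contrib)
        for i in range(m):
            for j in range(i, m):
                window = contrib[i:j + 1]
                gaps_ok = all(
                    window[k + 1].start - window[k].end <= cutoff
                    for k in range(len(window) - 1))
                if not gaps_ok:
                    continue
                left_sep = (i == 0 or
                            window[0].start - contrib[i - 1].end > cutoff)
                right_sep = (j == m - 1 or
                             contrib[j + 1].start - window[-1].end > cutoff)
                if not (left_sep and right_sep):
                    continue  # not a maximal group
                present = set()
                for g in window:
                    present |= by_gene.get(g.gene_id, set())
                if rule.expression.evaluate(present):
                    out.add((rule.type_name,
                             min(g.start for g in window),
                             max(g.end for g in window)))
    return out


# ---------------------------------------------------------------------------
# comparison scoring reimplementation
# ---------------------------------------------------------------------------

def brute_comparison(query_genes, reference, hits, core_query_genes,
                     min_identity=30.0, min_coverage=25.0, bonus=3):
    """Naive filter -> score pipeline over raw similarity hits."""
    kept = {}
    for h in hits:
        if h.subject_ref_id != reference.ref_id:
            continue
        if h.percent_identity < min_identity or h.coverage < min_coverage:
            continue
        old = kept.get(h.query_gene)
        if old is None or h.score > old.score or (
                h.score == old.score and h.subject_gene < old.subject_gene):
            kept[h.query_gene] = h
    ordered = sorted(query_genes, key=lambda g: (g.start, g.gene_id))
    count = sum(1 for g in ordered if g.gene_id in kept)
    ref_order = {gid: i for i, (gid, _, _) in enumerate(reference.genes)}
    ref_strand = {gid: s for gid, _, s in reference.genes}
    synteny = 0
    for a, b in zip(ordered, ordered[1:]):
        if a.gene_id in kept and b.gene_id in kept:
            sa = kept[a.gene_id].subject_gene
            sb = kept[b.gene_id].subject_gene
            if (ref_order.get(sb) == ref_order.get(sa, -9) + 1
                    and a.strand * b.strand
                    == ref_strand[sa] * ref_strand[sb]):
                synteny += 1
    core = bonus if any(g in kept for g in core_query_genes) else 0
    percent = 100.0 * count / len(ordered) if ordered else 0.0
    return count, synteny, core, count + synteny + core, percent
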