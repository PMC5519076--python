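"""Naive, loop-based reference implementations of every statistic.

Deliberately unvectorised and independent of the package internals: they
work on plain lists of call strings and dict-based frequency tables, so
agreement with the production code is a meaningful cross-check.
"""

from __future__ import annotations

import math

MISSING = ""


def class_freqs(calls):
    """Per-marker {class: relative frequency} over non-missing calls."""
    n = len(calls)
    m = len(calls[0]) if n else 0
    out = []
    for i in range(m):
        counts = {}
        for j in range(n):
            c = calls[j][i]
            if c != MISSING:
                counts[c] = counts.get(c, 0) + 1
        tot = sum(counts.values())
        out.append({c: k / tot for c, k in counts.items()})
    return out


def coverage_c(calls, covered, j):
    """C_j with covered (marker, class) pairs masked to zero."""
    freqs = class_freqs(calls)
    total, nn = 0.0, 0
    for i, c in enumerate(calls[j]):
        if c == MISSING:
            continue
        nn += 1
        if (i, c) not in covered:
            total += freqs[i][c]
    return total / nn if nn else 0.0


def diversity_d(calls, covered, j):
    """D_j around the sample's own masked C_j."""
    freqs = class_freqs(calls)
    c_j = coverage_c(calls, covered, j)
    terms = []
    for i, c in enumerate(calls[j]):
        if c == MISSING:
            continue
        terms.append(0.0 if (i, c) in covered else freqs[i][c])
    if not terms:
        return 0.0
    return sum((t - c_j) ** 2 for t in terms) / len(terms)


def coverage_cv(calls, subset):
    """CV% of a subset of row indices against entire-collection classes."""
    n = len(calls)
    m = len(calls[0]) if n else 0
    ratios = []
    for i in range(m):
        entire = {calls[j][i] for j in range(n)} - {MISSING}
        if not entire:
            continue
        in_sub = {calls[j][i] for j in subset} - {MISSING}
        ratios.append(len(in_sub & entire) / len(entire))
    return 100.0 * sum(ratios) / len(ratios) if ratios else 0.0


def alleles_of(code):
    if "/" in code:
        return code.split("/")
    if len(code) == 2:
        return list(code)
    return [code, code]


def ref_freq(calls, subset, i, ref):
    """Reference-allele frequency at marker i within a subset; None if no calls."""
    dos, cnt = 0.0, 0
    for j in subset:
        c = calls[j][i]
        if c == MISSING:
            continue
        al = alleles_of(c)
        dos += al.count(ref) / len(al)
        cnt += 1
    return dos / cnt if cnt else None


def major_allele(calls, i):
    dose = {}
    for row in calls:
        c = row[i]
        if c == MISSING:
            continue
        for a in alleles_of(c):
            dose[a] = dose.get(a, 0) + 1
    if not dose:
        return None
    best = max(dose.values())
    return sorted(a for a, d in dose.items() if d == best)[0]


def shannon_sh(calls, subset, refs=None):
    m = len(calls[0]) if calls else 0
    total = 0.0
    for i in range(m):
        ref = refs[i] if refs is not None else major_allele(calls, i)
        if ref is None:
            continue
        p = ref_freq(calls, subset, i, ref)
        if p is not None and p > 0:
            total -= p * math.log(p)
    return total


def modified_rogers_mr(calls, x, y):
    """MR over pairwise-complete markers; None if the pair shares none."""
    m = len(calls[0]) if calls else 0
    total, shared = 0.0, 0
    for i in range(m):
        cx, cy = calls[x][i], calls[y][i]
        if cx == MISSING or cy == MISSING:
            continue
        ax, ay = alleles_of(cx), alleles_of(cy)
        shared += 1
        for a in set(ax) | set(ay):
            total += (ax.count(a) / len(ax) - ay.count(a) / len(ay)) ** 2
    if shared == 0:
        return None
    return math.sqrt(total / (2 * shared))


def greedy_candidates(calls, remaining, covered):
    """Brute-force candidate pool and scores for one greedy step.

    Returns (pool, scores): pool = remaining samples with C>0 in the
    least-missing stratum that still adds coverage; empty when no remaining
    sample adds coverage.
    """
    gains = {j: coverage_c(calls, covered, j) for j in remaining}
    positive = [j for j in remaining if gains[j] > 0]
    if not positive:
        return [], {}
    miss = {j: sum(1 for c in calls[j] if c == MISSING) for j in positive}
    mc = min(miss.values())
    pool = [j for j in positive if miss[j] == mc]
    return pool, {j: gains[j] for j in pool}


def greedy_finalists(calls, remaining, covered, tie_decimals=12):
    """The set of samples the greedy step may legitimately pick."""
    pool, scores = greedy_candidates(calls, remaining, covered)
    if not pool:
        return []
    best = max(scores.values())
    tied = [j for j in pool if round(scores[j], tie_decimals) == round(best, tie_decimals)]
    if len(tied) == 1:
        return tied
    d = {j: diversity_d(calls, covered, j) for j in tied}
    dmin = min(d.values())
    return [j for j in tied if round(d[j], tie_decimals) == round(dmin, tie_decimals)]
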