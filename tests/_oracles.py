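"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's numpy-vectorised code paths: the
classifier oracle evaluates scalar log-pmf ratios per candidate rate with
the ``math`` module, and the overlap oracle is a naive all-pairs scan.
"""
from __future__ import annotations

import math


def oracle_log_pmf(y: int, lam: int) -> float:
    if lam == 0:
        return 0.0 if y == 0 else -math.inf
    return y * math.log(lam) - lam - math.lgamma(y + 1)


def oracle_likelihood_set(y: int, lo: int, hi: int, alpha: float) -> set[int]:
    logs = [oracle_log_pmf(y, lam) for lam in range(lo, hi + 1)]
    best = max(logs)
    if best == -math.inf:
        return set()
    cut = math.log(alpha)
    return {lo + i for i, v in enumerate(logs) if v - best >= cut}


def oracle_classify(y_plus: int, y_minus: int, alpha: float = 0.1):
    """Class and both likelihood sets by exhaustive enumeration."""
    lo, hi = min(y_plus, y_minus), max(y_plus, y_minus)
    ls_plus = oracle_likelihood_set(y_plus, lo, hi, alpha)
    ls_minus = oracle_likelihood_set(y_minus, lo, hi, alpha)
    if ls_plus & ls_minus:
        cls = "BOTH"
    elif y_plus > y_minus:
        cls = "PLUS"
    else:
        cls = "MINUS"
    return cls, ls_plus, ls_minus


def naive_count_overlaps(query, subject, respect_strand=True):
    """O(n·m) all-pairs overlap scan over GenomicInterval-like objects."""

    def compatible(a, b):
        return a.value == "." or b.value == "." or a is b

    counts = []
    for q in query:
        n = 0
        for s in subject:
            if q.seqname != s.seqname:
                continue
            if respect_strand and not compatible(q.strand, s.strand):
                continue
            if q.start < s.end and s.start < q.end:
                n += 1
        counts.append(n)
    return counts


def pearson_chi2(table):
    """Textbook Pearson chi-squared statistic Σ(O−E)²/E for a 2-D table."""
    rows = len(table)
    cols = len(table[0])
    row_sum = [sum(table[i]) for i in range(rows)]
    col_sum = [sum(table[i][j] for i in range(rows)) for j in range(cols)]
    total = sum(row_sum)
    stat = 0.0
    for i in range(rows):
        for j in range(cols):
            expected = row_sum[i] * col_sum[j] / total
            stat += (table[i][j] - expected) ** 2 / expected
    return stat


def paired_t(xs, ys):
    """Textbook paired t statistic mean(d) / (sd(d)/sqrt(n))."""
    diffs = [x - y for x, y in zip(xs, ys)]
    n = len(diffs)
    mean = sum(diffs) / n
    var = sum((d - mean) ** 2 for d in diffs) / (n - 1)
    return mean / math.sqrt(var / n)
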