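"""Independent brute-force reference implementations used as test oracles.

These deliberately take the slow, direct route — exhaustive window
enumeration, explicit pair counting, textbook constants — so that they
share no code path with the package implementations they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

HET = 1
MISSING = -1
HOM = (0, 2)


def window_valid(geno, pos, i, j, max_gap, max_hom, max_miss) -> bool:
    """Direct check of the run constraints on the window [i, j]."""
    if geno[i] != HET or geno[j] != HET:
        return False
    window = list(geno[i : j + 1])
    if sum(1 for g in window if g in HOM) > max_hom:
        return False
    if sum(1 for g in window if g == MISSING) > max_miss:
        return False
    for k in range(i, j):
        if pos[k + 1] - pos[k] > max_gap:
            return False
    return True


def brute_force_runs(geno, pos, max_gap, max_hom, max_miss):
    """All runs by exhaustive window enumeration plus left-to-right greedy
    selection: repeatedly take the valid window with the smallest start not
    yet consumed, extended as far right as any valid window allows."""
    n = len(geno)
    valid = [
        (i, j)
        for i in range(n)
        for j in range(i, n)
        if window_valid(geno, pos, i, j, max_gap, max_hom, max_miss)
    ]
    runs = []
    cursor = 0
    while True:
        candidates = [w for w in valid if w[0] >= cursor]
        if not candidates:
            break
        i0 = min(w[0] for w in candidates)
        j0 = max(w[1] for w in candidates if w[0] == i0)
        runs.append((i0, j0))
        cursor = j0 + 1
    out = []
    for i, j in runs:
        window = list(geno[i : j + 1])
        out.append(
            (
                i,
                j,
                sum(1 for g in window if g in HOM),
                sum(1 for g in window if g == MISSING),
            )
        )
    return out


def brute_force_hers(geno, pos, params):
    """Brute-force runs with the min_snp / min_length post-filters applied."""
    return [
        (i, j, nh, nm)
        for i, j, nh, nm in brute_force_runs(
            geno, pos, params.max_gap, params.max_hom, params.max_miss
        )
        if j - i + 1 >= params.min_snp and pos[j] - pos[i] >= params.min_length
    ]


def pairwise_pi(calls_one_site) -> float:
    """Per-site pi by enumerating every unordered pair of called alleles."""
    alleles = []
    for g in calls_one_site:
        if g == MISSING:
            continue
        alleles.extend({0: [0, 0], 1: [0, 1], 2: [1, 1]}[int(g)])
    if len(alleles) < 2:
        return math.nan
    pairs = list(itertools.combinations(alleles, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


def textbook_tajima_d(S: int, pi_sum: float, n: int) -> float:
    """Tajima's D written straight from the published constants."""
    if S == 0:
        return math.nan
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi_sum - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def pairwise_r2(x, y) -> float:
    """Squared Pearson correlation computed from first principles over
    individuals with both genotypes called."""
    pairs = [(a, b) for a, b in zip(x, y) if a != MISSING and b != MISSING]
    if len(pairs) < 2:
        return math.nan
    xs = [a for a, _ in pairs]
    ys = [b for _, b in pairs]
    mx = sum(xs) / len(xs)
    my = sum(ys) / len(ys)
    sxx = sum((a - mx) ** 2 for a in xs)
    syy = sum((b - my) ** 2 for b in ys)
    if sxx == 0 or syy == 0:
        return math.nan
    sxy = sum((a - mx) * (b - my) for a, b in pairs)
    return (sxy * sxy) / (sxx * syy)


def coverage_count(hers_rows, chrom, position) -> int:
    """Interval-stabbing count: individuals with >=1 run covering a site."""
    covered = set()
    for ind, c, start, end in hers_rows:
        if c == chrom and start <= position <= end:
            covered.add(ind)
    return len(covered)
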