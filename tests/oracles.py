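"""Independent brute-force oracles used to check the fast implementations.

Everything here is written with explicit Python loops and set operations,
deliberately sharing no code with the package's vectorized routines.
"""

import math


def brute_pair_components(x, y):
    """(A, B, C) component sums for two abundance vectors, by looping."""
    a = sum(min(xi, yi) for xi, yi in zip(x, y))
    b = sum(x) - a
    c = sum(y) - a
    return a, b, c


def brute_pairwise_partition(x, y):
    a, b, c = brute_pair_components(x, y)
    total = (b + c) / (2 * a + b + c)
    m = min(b, c)
    balanced = m / (a + m) if (a + m) > 0 else 0.0
    return total, balanced, total - balanced


def brute_multisite_partition(rows):
    """Multiple-site partition by enumerating every unordered plot pair."""
    n = len(rows)
    sum_a = sum_min = sum_max = 0.0
    for j in range(n):
        for k in range(j + 1, n):
            a, b, c = brute_pair_components(rows[j], rows[k])
            sum_a += a
            sum_min += min(b, c)
            sum_max += max(b, c)
    if sum_min + sum_max == 0:
        return 0.0, 0.0, 0.0
    total = (sum_min + sum_max) / (2 * sum_a + sum_min + sum_max)
    balanced = sum_min / (sum_a + sum_min)
    return total, balanced, total - balanced


def incidence_multisite_family(rows01):
    """Multiple-site Sorensen / Simpson-turnover / nestedness family on a
    presence-absence matrix, coded with set operations over plot pairs."""
    supports = [frozenset(i for i, v in enumerate(r) if v) for r in rows01]
    n = len(supports)
    sum_a = sum_min = sum_max = 0.0
    for j in range(n):
        for k in range(j + 1, n):
            shared = len(supports[j] & supports[k])
            only_j = len(supports[j] - supports[k])
            only_k = len(supports[k] - supports[j])
            sum_a += shared
            sum_min += min(only_j, only_k)
            sum_max += max(only_j, only_k)
    if sum_min + sum_max == 0:
        return 0.0, 0.0, 0.0
    sorensen = (sum_min + sum_max) / (2 * sum_a + sum_min + sum_max)
    simpson = sum_min / (sum_a + sum_min)
    return sorensen, simpson, sorensen - simpson


def jackknife_mean_se(values):
    """Closed-form jackknife SE of the sample mean: s / sqrt(n)."""
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return math.sqrt(var / n)
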