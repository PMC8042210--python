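"""Shared fixtures and independent brute-force oracles.

The oracle implementations here deliberately avoid the package's
vectorized code paths: they are literal transcriptions of the defining
formulas (double loops, per-position bin checks, per-object subset
tests) used to cross-check the real implementations.
"""

import math

import numpy as np
import pytest

from fsace.granulation import DecisionTable, GranularStructure, DecisionPartition


# ---------------------------------------------------------------- oracles


def oracle_bin(value, bins):
    """Scan the k intervals [t/k, (t+1)/k) (last closed) one by one."""
    for t in range(bins):
        lo, hi = t / bins, (t + 1) / bins
        if t == bins - 1:
            if lo <= value <= 1.0:
                return t
        elif lo <= value < hi:
            return t
    raise AssertionError("unreachable for value in [0,1]")


def oracle_laplacian(values, subset, sigma):
    n = values.shape[0]
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            d = math.sqrt(sum((values[i, a] - values[j, a]) ** 2 for a in subset))
            out[i, j] = math.exp(-d / sigma)
    return out


def oracle_approx_equal(row_a, row_b, bins):
    return all(
        oracle_bin(a, bins) == oracle_bin(b, bins) for a, b in zip(row_a, row_b)
    )


def oracle_granulate(entries, bins):
    """Pairwise closure: put i, j together iff their rows are bin-equal."""
    n = entries.shape[0]
    granules = []
    assigned = [None] * n
    for i in range(n):
        if assigned[i] is not None:
            continue
        g = [i]
        assigned[i] = len(granules)
        for j in range(i + 1, n):
            if assigned[j] is None and oracle_approx_equal(
                entries[i], entries[j], bins
            ):
                g.append(j)
                assigned[j] = assigned[i]
        granules.append(frozenset(g))
    return granules


def oracle_lower(granules, granule_of, X):
    return frozenset(i for i in range(len(granule_of)) if granules[granule_of[i]] <= X)


def oracle_upper(granules, granule_of, X):
    return frozenset(
        i for i in range(len(granule_of)) if granules[granule_of[i]] & X
    )


def oracle_accuracy(granules, granule_of, X):
    lo = oracle_lower(granules, granule_of, X)
    up = oracle_upper(granules, granule_of, X)
    return len(lo) / len(up)


def oracle_conditional_entropy(granules, granule_of, classes):
    """Literal double sum over classes and objects."""
    n = len(granule_of)
    h = 0.0
    for X in classes:
        for i in range(n):
            g = granules[granule_of[i]]
            c = len(g & X)
            if c > 0:
                h -= (c / n) * math.log2(c / len(g))
    return h


def oracle_ace(granules, granule_of, classes):
    n = len(granule_of)
    h = 0.0
    for X in classes:
        w = math.log2(2.0 - oracle_accuracy(granules, granule_of, X))
        for i in range(n):
            g = granules[granule_of[i]]
            c = len(g & X)
            if c > 0:
                h -= w * (c / n) * math.log2(c / len(g))
    return h


# ------------------------------------------------------------- generators


def random_partition(rng, n, max_parts=None):
    """A uniform-ish random set partition of range(n) as (granules, granule_of)."""
    max_parts = max_parts or n
    k = int(rng.integers(1, max_parts + 1))
    assign = rng.integers(0, k, size=n)
    # guarantee no empty parts by compacting labels
    _, assign = np.unique(assign, return_inverse=True)
    parts = {}
    for i, a in enumerate(assign):
        parts.setdefault(int(a), []).append(i)
    granules = [frozenset(v) for v in parts.values()]
    granule_of = [None] * n
    for gi, g in enumerate(granules):
        for i in g:
            granule_of[i] = gi
    return granules, granule_of


def as_structure(granules, granule_of, bins=4):
    return GranularStructure(
        tuple(tuple(sorted(g)) for g in granules), np.array(granule_of), bins
    )


def random_decision_partition(rng, n, max_classes=4):
    classes, class_of = random_partition(rng, n, max_parts=max_classes)
    return classes, class_of


def as_decision_partition(classes):
    return DecisionPartition(
        tuple(tuple(sorted(c)) for c in classes),
        tuple(f"c{j}" for j in range(len(classes))),
    )


def random_table(rng, n=8, m=3):
    return DecisionTable(
        rng.random((n, m)), rng.integers(0, 3, size=n).astype(str)
    )


# --------------------------------------------------------------- fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
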