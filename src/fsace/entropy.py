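"""Granule-based approximations, entropies and attribute importance.

The knowledge carried by an attribute subset B is scored by a
conditional entropy over the granulation it induces; the *approximate*
conditional entropy additionally damps each decision-class term by
``log2(2 - a(X_j))``, where ``a`` is the lower/upper approximation
cardinality ratio of the class.  All logarithms are base 2 and the
``0 * log 0 := 0`` convention applies throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .granulation import (
    DecisionPartition,
    DecisionTable,
    GranularStructure,
    decision_partition,
    granulate,
    laplacian_relation,
)

__all__ = [
    "EntropyReport",
    "lower_approximation",
    "upper_approximation",
    "approximate_accuracy",
    "conditional_entropy",
    "approximate_conditional_entropy",
    "granulation_for_subset",
    "entropy_report",
    "SubsetEntropyEvaluator",
    "iia",
    "iea",
    "is_reduction",
]


def lower_approximation(G: GranularStructure, X) -> frozenset:
    """Objects whose whole granule is contained in ``X``."""
    X = frozenset(int(i) for i in X)
    out = []
    for g in G.granules:
        if X.issuperset(g):
            out.extend(g)
    return frozenset(out)


def upper_approximation(G: GranularStructure, X) -> frozenset:
    """Objects whose granule meets ``X``; a superset of the lower approximation."""
    X = frozenset(int(i) for i in X)
    out = []
    for g in G.granules:
        if not X.isdisjoint(g):
            out.extend(g)
    return frozenset(out)


def approximate_accuracy(G: GranularStructure, X) -> float:
    """|lower| / |upper| for a nonempty ``X``; always in [0, 1]."""
    X = frozenset(int(i) for i in X)
    if not X:
        raise ValueError("approximate accuracy undefined for empty set")
    lower = lower_approximation(G, X)
    upper = upper_approximation(G, X)
    # upper ⊇ X ≠ ∅ by reflexivity, so the denominator is never zero
    return len(lower) / len(upper)


def _class_counts(G: GranularStructure, P: DecisionPartition) -> np.ndarray:
    """counts[g, j] = |granule g ∩ class j|."""
    n_g = len(G.granules)
    n_c = len(P.classes)
    counts = np.zeros((n_g, n_c), dtype=float)
    class_of = np.empty(G.n_objects, dtype=int)
    for j, c in enumerate(P.classes):
        for i in c:
            class_of[i] = j
    for gi, g in enumerate(G.granules):
        for i in g:
            counts[gi, class_of[i]] += 1
    return counts


def conditional_entropy(G: GranularStructure, P: DecisionPartition) -> float:
    """Conditional entropy of the decision partition given the granulation, in bits.

    The inner sum runs over objects, so each granule's term is counted
    once per member; empty intersections contribute zero.
    """
    if G.n_objects != P.n_objects:
        raise ValueError("granulation and partition cover different universes")
    n = G.n_objects
    sizes = np.array([len(g) for g in G.granules], dtype=float)
    counts = _class_counts(G, P)
    h = 0.0
    for gi in range(len(G.granules)):
        s = sizes[gi]
        for j in range(counts.shape[1]):
            c = counts[gi, j]
            if c > 0:
                h -= s * (c / n) * np.log2(c / s)
    return float(h)


def approximate_conditional_entropy(
    G: GranularStructure, P: DecisionPartition
) -> float:
    """Conditional entropy with each class term damped by ``log2(2 - a(X_j))``.

    Zero exactly when every granule lies inside a single decision class;
    equal to :func:`conditional_entropy` when every class accuracy is 0.
    """
    if G.n_objects != P.n_objects:
        raise ValueError("granulation and partition cover different universes")
    n = G.n_objects
    sizes = np.array([len(g) for g in G.granules], dtype=float)
    counts = _class_counts(G, P)
    weights = [
        np.log2(2.0 - approximate_accuracy(G, c)) for c in P.classes
    ]
    h = 0.0
    for gi in range(len(G.granules)):
        s = sizes[gi]
        for j, w in enumerate(weights):
            c = counts[gi, j]
            if c > 0:
                h -= w * s * (c / n) * np.log2(c / s)
    return float(h)


def universal_granulation(n: int, bins: int) -> GranularStructure:
    """Single granule covering the whole universe (the empty-subset convention)."""
    return GranularStructure((tuple(range(n)),), np.zeros(n, dtype=int), bins)


def granulation_for_subset(
    table: DecisionTable, subset, sigma: float, bins: int
) -> GranularStructure:
    """Granulate the universe under an attribute subset.

    The empty subset denotes "no discernibility" and yields the
    universal granule.
    """
    subset = tuple(sorted(int(a) for a in set(subset)))
    if len(subset) == 0:
        return universal_granulation(table.n_objects, bins)
    return granulate(laplacian_relation(table, subset, sigma), bins)


@dataclass(frozen=True)
class EntropyReport:
    """Entropies (bits) and per-class approximate accuracies for one subset."""

    h_conditional: float
    h_ace: float
    per_class_accuracy: tuple

    def to_json_dict(self) -> dict:
        return {
            "h_conditional": self.h_conditional,
            "h_ace": self.h_ace,
            "per_class_accuracy": list(self.per_class_accuracy),
        }


def entropy_report(
    table: DecisionTable, subset, sigma: float, bins: int
) -> EntropyReport:
    G = granulation_for_subset(table, subset, sigma, bins)
    P = decision_partition(table)
    acc = tuple(approximate_accuracy(G, c) for c in P.classes)
    return EntropyReport(
        conditional_entropy(G, P), approximate_conditional_entropy(G, P), acc
    )


class SubsetEntropyEvaluator:
    """Memoizing evaluator of H_ace over attribute subsets of a fixed table.

    Results are cached by subset; disabling the cache must not change any
    value (pure recomputation), only speed.
    """

    def __init__(
        self,
        table: DecisionTable,
        sigma: float,
        bins: int,
        use_cache: bool = True,
    ):
        if sigma <= 0:
            raise ValueError("nonpositive kernel width")
        if bins < 2:
            raise ValueError("bins must be ≥ 2")
        self.table = table
        self.sigma = float(sigma)
        self.bins = int(bins)
        self.partition = decision_partition(table)
        self.use_cache = use_cache
        self._cache: dict = {}

    def h_ace(self, subset) -> float:
        key = frozenset(int(a) for a in subset)
        if self.use_cache and key in self._cache:
            return self._cache[key]
        G = granulation_for_subset(self.table, key, self.sigma, self.bins)
        value = approximate_conditional_entropy(G, self.partition)
        if self.use_cache:
            self._cache[key] = value
        return value


def iia(
    table: DecisionTable, c: int, sigma: float, bins: int, evaluator=None
) -> float:
    """Internal importance of attribute ``c``: entropy rise when it is removed.

    ``H_ace(D/(C - {c})) - H_ace(D/C)``.
    """
    c = int(c)
    if table.n_attributes < 2:
        raise ValueError("cannot remove the only attribute")
    if not 0 <= c < table.n_attributes:
        raise IndexError("attribute index out of range")
    ev = evaluator or SubsetEntropyEvaluator(table, sigma, bins)
    full = set(range(table.n_attributes))
    return ev.h_ace(full - {c}) - ev.h_ace(full)


def iea(
    table: DecisionTable, B, d: int, sigma: float, bins: int, evaluator=None
) -> float:
    """External importance of attribute ``d``: entropy drop when added to ``B``.

    ``H_ace(D/B) - H_ace(D/(B ∪ {d}))``.  ``B`` may be empty (universal
    granule convention).
    """
    d = int(d)
    B = frozenset(int(a) for a in B)
    if d in B:
        raise ValueError("attribute already selected")
    if not 0 <= d < table.n_attributes:
        raise IndexError("attribute index out of range")
    ev = evaluator or SubsetEntropyEvaluator(table, sigma, bins)
    return ev.h_ace(B) - ev.h_ace(B | {d})


def is_reduction(
    table: DecisionTable, B, sigma: float, bins: int, tol: float = 1e-10
) -> bool:
    """Whether ``B`` preserves the full-set entropy with no removable attribute.

    Condition 1: ``|H_ace(D/B) - H_ace(D/C)| <= tol``.  Condition 2: for
    every ``b`` in ``B``, removing it raises the entropy above
    ``H_ace(D/C) + tol`` (a singleton ``B`` is checked against the
    empty-set convention).
    """
    B = frozenset(int(a) for a in B)
    if not B:
        raise ValueError("empty attribute subset")
    if any(a < 0 or a >= table.n_attributes for a in B):
        raise IndexError("attribute index out of range")
    ev = SubsetEntropyEvaluator(table, sigma, bins)
    h_full = ev.h_ace(frozenset(range(table.n_attributes)))
    if abs(ev.h_ace(B) - h_full) > tol:
        return False
    for b in B:
        if ev.h_ace(B - {b}) <= h_full + tol:
            return False
    return True
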