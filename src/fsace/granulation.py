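"""Laplacian-kernel fuzzy relations and bin-based granulation.

A decision table (objects x attributes plus one categorical label per
object) is turned into an n x n fuzzy relation matrix by a Laplacian
kernel on Euclidean distances over an attribute subset.  Two objects are
*approximately equal* when their relation rows fall, position by
position, into the same of ``bins`` equal-width intervals of [0, 1]; the
last interval is closed on the right.  Because binning is an equivalence
relation on rows, the induced granules partition the universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DecisionTable",
    "FuzzyRelationMatrix",
    "GranularStructure",
    "DecisionPartition",
    "laplacian_relation",
    "bin_index",
    "approx_equal",
    "row_signatures",
    "granulate",
    "decision_partition",
    "normalize_table",
]


@dataclass(frozen=True)
class DecisionTable:
    """A decision information system: numeric object rows plus one label each.

    Parameters
    ----------
    values : ndarray of shape (n_objects, n_attributes)
        Real-valued attribute matrix; must be finite.
    labels : ndarray of shape (n_objects,)
        Categorical decision label per object.
    attribute_ids : tuple of str
        One identifier per attribute (column).
    object_ids : tuple of str
        One identifier per object (row).
    """

    values: np.ndarray
    labels: np.ndarray
    attribute_ids: tuple = ()
    object_ids: tuple = ()

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels)
        if values.ndim != 2:
            raise ValueError("values must be a 2-d matrix")
        n, m = values.shape
        if n < 2:
            raise ValueError("need at least 2 objects")
        if m < 1:
            raise ValueError("need at least 1 attribute")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))
            cells = ", ".join(f"(row {i}, col {j})" for i, j in bad[:5])
            raise ValueError(f"non-finite values at {cells}")
        if labels.shape != (n,):
            raise ValueError("labels must be one per object")
        attribute_ids = tuple(self.attribute_ids) or tuple(
            f"a{j + 1}" for j in range(m)
        )
        object_ids = tuple(self.object_ids) or tuple(f"x{i + 1}" for i in range(n))
        if len(attribute_ids) != m:
            raise ValueError("attribute_ids length mismatch")
        if len(object_ids) != n:
            raise ValueError("object_ids length mismatch")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "attribute_ids", attribute_ids)
        object.__setattr__(self, "object_ids", object_ids)

    @property
    def n_objects(self) -> int:
        return self.values.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    @property
    def all_attributes(self) -> tuple:
        return tuple(range(self.n_attributes))


def normalize_table(table: DecisionTable) -> DecisionTable:
    """Min-max normalize each attribute to [0, 1].

    Constant attributes (zero range) map to all zeros rather than
    dividing by zero.
    """
    v = table.values
    lo = v.min(axis=0)
    rng = v.max(axis=0) - lo
    out = np.zeros_like(v)
    nz = rng > 0
    out[:, nz] = (v[:, nz] - lo[nz]) / rng[nz]
    return DecisionTable(out, table.labels, table.attribute_ids, table.object_ids)


@dataclass(frozen=True)
class FuzzyRelationMatrix:
    """Symmetric n x n similarity matrix with entries in (0, 1] and unit diagonal."""

    entries: np.ndarray
    sigma: float
    attribute_subset: tuple = ()

    def __post_init__(self):
        e = np.asarray(self.entries, dtype=float)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError("entries must be square")
        if not ((e > 0).all() and (e <= 1).all()):
            raise ValueError("entries must lie in (0, 1]")
        if not np.array_equal(np.diag(e), np.ones(e.shape[0])):
            raise ValueError("diagonal must be exactly 1")
        if not np.array_equal(e, e.T):
            raise ValueError("entries must be symmetric")
        object.__setattr__(self, "entries", e)
        object.__setattr__(self, "attribute_subset", tuple(self.attribute_subset))

    @property
    def n_objects(self) -> int:
        return self.entries.shape[0]


@dataclass(frozen=True)
class GranularStructure:
    """A partition of object indices into granules of bin-identical relation rows."""

    granules: tuple
    granule_of: np.ndarray
    bins: int

    def __post_init__(self):
        granules = tuple(tuple(int(i) for i in g) for g in self.granules)
        granule_of = np.asarray(self.granule_of, dtype=int)
        n = granule_of.shape[0]
        seen = sorted(i for g in granules for i in g)
        if seen != list(range(n)):
            raise ValueError("granules must partition the object indices")
        for gi, g in enumerate(granules):
            if len(g) == 0:
                raise ValueError("empty granule")
            for i in g:
                if granule_of[i] != gi:
                    raise ValueError("granule_of inconsistent with granules")
        object.__setattr__(self, "granules", granules)
        object.__setattr__(self, "granule_of", granule_of)

    @property
    def n_objects(self) -> int:
        return self.granule_of.shape[0]

    def granule(self, i: int) -> frozenset:
        """The granule containing object ``i``, as a set of indices."""
        return frozenset(self.granules[self.granule_of[i]])

    def to_json_dict(self, object_ids=None) -> dict:
        if object_ids is None:
            ids = [list(g) for g in self.granules]
        else:
            ids = [[object_ids[i] for i in g] for g in self.granules]
        return {"bins": self.bins, "granules": ids}


@dataclass(frozen=True)
class DecisionPartition:
    """Crisp classes of the universe induced by the decision labels."""

    classes: tuple
    class_labels: tuple = ()

    def __post_init__(self):
        classes = tuple(tuple(int(i) for i in c) for c in self.classes)
        n = sum(len(c) for c in classes)
        seen = sorted(i for c in classes for i in c)
        if seen != list(range(n)):
            raise ValueError("classes must partition the object indices")
        if any(len(c) == 0 for c in classes):
            raise ValueError("empty decision class")
        object.__setattr__(self, "classes", classes)
        object.__setattr__(self, "class_labels", tuple(self.class_labels))

    @property
    def n_objects(self) -> int:
        return sum(len(c) for c in self.classes)


def laplacian_relation(
    table: DecisionTable, subset, sigma: float
) -> FuzzyRelationMatrix:
    """Fuzzy relation matrix ``exp(-d_ij / sigma)`` over an attribute subset.

    ``d_ij`` is the Euclidean distance between objects i and j restricted
    to ``subset``.  The result is exactly symmetric with a unit diagonal.
    """
    subset = tuple(sorted(int(a) for a in set(subset)))
    if len(subset) == 0:
        raise ValueError("empty attribute subset")
    if sigma <= 0:
        raise ValueError("nonpositive kernel width")
    if any(a < 0 or a >= table.n_attributes for a in subset):
        raise IndexError("attribute index out of range")
    sub = table.values[:, list(subset)]
    d = squareform(pdist(sub, metric="euclidean"))
    entries = np.exp(-d / sigma)
    np.fill_diagonal(entries, 1.0)
    return FuzzyRelationMatrix(entries, float(sigma), subset)


def bin_index(value: float, bins: int) -> int:
    """Index of the equal-width bin of [0, 1] that ``value`` falls into.

    Bins are [0, 1/k), [1/k, 2/k), ..., [(k-1)/k, 1]; the last interval
    is closed so ``bin_index(1.0, k) == k - 1``.
    """
    if bins < 2:
        raise ValueError("bins must be ≥ 2")
    if not 0.0 <= value <= 1.0:
        raise ValueError("membership out of range")
    idx = int(np.floor(value * bins))
    return bins - 1 if idx >= bins else idx


def _signatures(rows: np.ndarray, bins: int) -> np.ndarray:
    """Vectorized bin indices for an array of membership values in [0, 1]."""
    rows = np.asarray(rows, dtype=float)
    if rows.min() < 0.0 or rows.max() > 1.0:
        raise ValueError("membership out of range")
    idx = np.floor(rows * bins).astype(np.int64)
    # value 1.0 (and any fp round-up at the top edge) lands in the last bin
    np.clip(idx, 0, bins - 1, out=idx)
    return idx


def row_signatures(entries: np.ndarray, bins: int) -> np.ndarray:
    """Discretized (binned) copy of a relation matrix's rows."""
    if bins < 2:
        raise ValueError("bins must be ≥ 2")
    return _signatures(entries, bins)


def approx_equal(row_a, row_b, bins: int) -> bool:
    """True iff the two membership rows are bin-identical at every position."""
    a = np.asarray(row_a, dtype=float)
    b = np.asarray(row_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("row length mismatch")
    if bins < 2:
        raise ValueError("bins must be ≥ 2")
    return bool(np.array_equal(_signatures(a, bins), _signatures(b, bins)))


def granulate(relation: FuzzyRelationMatrix, bins: int) -> GranularStructure:
    """Partition objects into granules of approximately-equal relation rows.

    Objects i and j share a granule iff their rows agree bin-by-bin at
    every position.  Rows are grouped by their discretized signature, so
    the cost is O(n^2) in the number of objects.
    """
    sig = row_signatures(relation.entries, bins)
    groups: dict = {}
    for i, row in enumerate(sig):
        groups.setdefault(row.tobytes(), []).append(i)
    granules = tuple(tuple(g) for g in groups.values())
    granule_of = np.empty(relation.n_objects, dtype=int)
    for gi, g in enumerate(granules):
        for i in g:
            granule_of[i] = gi
    return GranularStructure(granules, granule_of, bins)


def decision_partition(table: DecisionTable) -> DecisionPartition:
    """Classes of objects sharing a label, ordered by first appearance."""
    order: list = []
    members: dict = {}
    for i, lab in enumerate(table.labels):
        if lab not in members:
            members[lab] = []
            order.append(lab)
        members[lab].append(i)
    return DecisionPartition(
        tuple(tuple(members[lab]) for lab in order), tuple(order)
    )
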