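"""Synthetic decision tables with known ground truth, plus a CV harness.

The generator emulates the shape of small expression benchmarks: tens to
hundreds of samples, a handful of classes, a few class-informative
attributes buried in many standard-normal noise attributes.  Class means
of informative attributes follow a base-b digit code of the class index,
scaled by ``effect`` within-class standard deviations, so every pair of
classes is separated on at least one informative attribute and no
informative attribute duplicates another.

The evaluation harness mirrors a stratified k-fold protocol with three
stock classifiers: 3-nearest-neighbours, a CART-style decision tree and
an RBF-kernel SVM, all at library defaults otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .granulation import DecisionTable, normalize_table
from .selection import fsace_select

__all__ = [
    "SyntheticSpec",
    "generate_table",
    "make_classifier",
    "cross_validate",
    "sigma_sweep",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic decision table."""

    n_samples: int = 60
    n_classes: int = 3
    n_informative: int = 2
    n_noise: int = 20
    effect: float = 6.0
    class_proportions: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.n_classes < 1:
            raise ValueError("need at least 1 class")
        if self.n_informative < 1:
            raise ValueError("need at least 1 informative attribute")
        if self.n_noise < 0:
            raise ValueError("n_noise must be nonnegative")
        if self.effect <= 0:
            raise ValueError("effect must be positive")
        if self.class_proportions is not None:
            p = tuple(float(x) for x in self.class_proportions)
            if len(p) != self.n_classes:
                raise ValueError("one proportion per class required")
            if any(x <= 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
                raise ValueError("proportions must be positive and sum to 1")
            object.__setattr__(self, "class_proportions", p)


def _class_sizes(spec: SyntheticSpec) -> np.ndarray:
    p = spec.class_proportions or tuple(
        1.0 / spec.n_classes for _ in range(spec.n_classes)
    )
    raw = np.array(p) * spec.n_samples
    sizes = np.floor(raw).astype(int)
    # largest-remainder rounding; ties broken by class order
    for j in np.argsort(-(raw - sizes), kind="stable")[: spec.n_samples - sizes.sum()]:
        sizes[j] += 1
    if (sizes == 0).any():
        raise ValueError("class proportions infeasible for n_samples")
    return sizes


def _class_codes(n_classes: int, n_informative: int) -> np.ndarray:
    """Distinct per-class digit codes: codes[j, t] in {0, ..., b-1}."""
    b = 2
    while b**n_informative < n_classes:
        b += 1
    codes = np.zeros((n_classes, n_informative), dtype=float)
    for j in range(n_classes):
        x = j
        for t in range(n_informative):
            codes[j, t] = x % b
            x //= b
    return codes


def generate_table(spec: SyntheticSpec):
    """Draw a table from the spec; returns ``(table, ground_truth_indices)``.

    Informative attributes sit at seed-determined random positions;
    ``ground_truth`` is the sorted tuple of their 0-based column indices.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = _class_sizes(spec)
    labels = np.repeat([f"c{j}" for j in range(spec.n_classes)], sizes)
    y = np.repeat(np.arange(spec.n_classes), sizes)
    m = spec.n_informative + spec.n_noise

    codes = _class_codes(spec.n_classes, spec.n_informative)
    informative = codes[y] * spec.effect + rng.standard_normal(
        (spec.n_samples, spec.n_informative)
    )
    noise = rng.standard_normal((spec.n_samples, spec.n_noise))

    cols = rng.permutation(m)
    values = np.empty((spec.n_samples, m))
    values[:, cols[: spec.n_informative]] = informative
    values[:, cols[spec.n_informative :]] = noise
    truth = tuple(sorted(int(c) for c in cols[: spec.n_informative]))

    table = DecisionTable(
        values,
        labels,
        tuple(f"g{j + 1}" for j in range(m)),
        tuple(f"s{i + 1}" for i in range(spec.n_samples)),
    )
    return table, truth


def make_classifier(name: str, seed: int = 0):
    if name in {"knn", "knn3"}:
        return KNeighborsClassifier(n_neighbors=3)
    if name == "cart":
        return DecisionTreeClassifier(random_state=seed)
    if name in {"svm", "svm-rbf"}:
        return SVC(kernel="rbf")
    raise ValueError(f"unknown classifier {name!r}")


def cross_validate(
    table: DecisionTable,
    subset,
    classifier: str = "knn3",
    folds: int = 10,
    seed: int = 0,
) -> float:
    """Mean stratified k-fold accuracy of a classifier on an attribute subset."""
    subset = sorted(int(a) for a in set(subset))
    if not subset:
        raise ValueError("empty attribute subset")
    if folds < 2:
        raise ValueError("folds must be ≥ 2")
    _, counts = np.unique(table.labels, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; use folds ≤ {counts.min()}"
        )
    X = table.values[:, subset]
    y = table.labels.astype(str)
    if len(counts) > 1:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    else:  # single-class tables cannot be stratified
        skf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(X, y):
        clf = make_classifier(classifier, seed)
        clf.fit(X[train], y[train])
        accs.append(float(np.mean(clf.predict(X[test]) == y[test])))
    return float(np.mean(accs))


def sigma_sweep(
    table: DecisionTable,
    grid,
    bins: int = 4,
    tol: float = 1e-10,
    classifiers=("knn3", "cart", "svm-rbf"),
    folds: int = 10,
    seed: int = 0,
    max_features: int | None = None,
):
    """Run selection at each kernel width and cross-validate the result.

    Returns one record per sigma with the selected subset (0-based), its
    size and per-classifier CV accuracy — the raw material for
    accuracy-vs-sigma curves.
    """
    grid = [float(s) for s in grid]
    if not grid or any(s <= 0 for s in grid):
        raise ValueError("sigma grid must be nonempty and positive")
    records = []
    for s in grid:
        res = fsace_select(
            table, sigma=s, bins=bins, tol=tol, max_features=max_features
        )
        rec = {
            "sigma": s,
            "selected": list(res.selected),
            "size": len(res.selected),
            "converged": res.converged,
        }
        for name in classifiers:
            rec[f"accuracy_{name}"] = cross_validate(
                table, res.selected, name, folds=folds, seed=seed
            )
        records.append(rec)
    return records
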