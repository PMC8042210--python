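"""Greedy forward feature selection by approximate conditional entropy.

The search starts from the core attributes (those whose removal from the
full set strictly raises the entropy), then repeatedly adds the
remaining attribute with the largest external importance until the
selected subset's entropy matches the full-set entropy within ``tol``.
Ties in the argmax go to the lowest attribute index, so the algorithm is
fully deterministic.  Guarded termination (no improvement possible,
feature cap reached, or all attributes taken) is reported via
``stop_reason`` rather than looping forever.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .entropy import SubsetEntropyEvaluator
from .granulation import DecisionTable

__all__ = ["StepRecord", "SelectionResult", "find_core", "fsace_select"]


@dataclass(frozen=True)
class StepRecord:
    """One greedy iteration: the attribute added, its IEA, and the new entropy."""

    attribute: int
    iea: float
    h_ace: float

    def to_json_dict(self) -> dict:
        return {"attribute": self.attribute, "iea": self.iea, "h_ace": self.h_ace}


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a greedy forward selection run."""

    selected: tuple
    core: frozenset
    trace: tuple
    h_full: float
    h_selected: float
    converged: bool
    stop_reason: str  # entropy-matched | no-improvement | exhausted

    def __post_init__(self):
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("duplicate selected attributes")
        if not self.core <= set(self.selected):
            raise ValueError("core must be a subset of selected")

    def to_json_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "core": sorted(self.core),
            "trace": [t.to_json_dict() for t in self.trace],
            "h_full": self.h_full,
            "h_selected": self.h_selected,
            "converged": self.converged,
            "stop_reason": self.stop_reason,
        }


def find_core(
    table: DecisionTable,
    sigma: float,
    bins: int = 4,
    tol: float = 1e-10,
    evaluator: SubsetEntropyEvaluator | None = None,
) -> frozenset:
    """Attributes whose internal importance exceeds ``tol``.

    An attribute is a core attribute when dropping it from the full set
    strictly raises the approximate conditional entropy.  Tables with a
    single attribute have no removable attribute and hence an empty core.
    """
    ev = evaluator or SubsetEntropyEvaluator(table, sigma, bins)
    m = table.n_attributes
    if m < 2:
        return frozenset()
    full = frozenset(range(m))
    h_full = ev.h_ace(full)
    return frozenset(c for c in range(m) if ev.h_ace(full - {c}) - h_full > tol)


def fsace_select(
    table: DecisionTable,
    sigma: float,
    bins: int = 4,
    tol: float = 1e-10,
    skip_core: bool = False,
    max_features: int | None = None,
    prune: bool = False,
    use_cache: bool = True,
) -> SelectionResult:
    """Select a minimal attribute subset preserving the full-set entropy.

    Parameters
    ----------
    table : DecisionTable
        The decision system to reduce.
    sigma : float
        Laplacian kernel width (positive).
    bins : int
        Number of equal-width membership bins (>= 2).
    tol : float
        Absolute tolerance for entropy equality.
    skip_core : bool
        Skip the O(n^2 m^2) core computation and start greedy search
        from the empty set (a logged deviation, useful for wide tables).
    max_features : int or None
        Hard cap on the selected subset size.
    prune : bool
        After convergence, drop attributes whose removal keeps the
        entropy within ``tol`` of the full-set value (backward pass
        enforcing minimality; off by default).
    use_cache : bool
        Memoize subset entropies; results are identical either way.
    """
    if max_features is not None and max_features < 1:
        raise ValueError("max_features must be ≥ 1")
    m = table.n_attributes
    cap = m if max_features is None else min(max_features, m)
    ev = SubsetEntropyEvaluator(table, sigma, bins, use_cache=use_cache)

    h_full = ev.h_ace(frozenset(range(m)))
    core = (
        frozenset()
        if skip_core
        else find_core(table, sigma, bins, tol, evaluator=ev)
    )
    selected: list = sorted(core)
    trace: list = []

    if selected:
        h_sel = ev.h_ace(selected)
        if abs(h_sel - h_full) <= tol:
            return _finish(
                table, ev, selected, core, trace, h_full, h_sel, True,
                "entropy-matched", tol, prune,
            )
    else:
        h_sel = ev.h_ace(frozenset())

    while True:
        remaining = [a for a in range(m) if a not in selected]
        if not remaining or len(selected) >= cap:
            converged = abs(h_sel - h_full) <= tol
            reason = "entropy-matched" if converged else "exhausted"
            return _finish(
                table, ev, selected, core, trace, h_full, h_sel, converged,
                reason, tol, prune,
            )
        h_before = ev.h_ace(selected)
        best_attr, best_iea = None, -float("inf")
        for a in remaining:  # ties resolve to the lowest index
            gain = h_before - ev.h_ace(frozenset(selected) | {a})
            if gain > best_iea:
                best_attr, best_iea = a, gain
        selected.append(best_attr)
        h_sel = ev.h_ace(selected)
        trace.append(StepRecord(best_attr, best_iea, h_sel))
        if abs(h_sel - h_full) <= tol:
            return _finish(
                table, ev, selected, core, trace, h_full, h_sel, True,
                "entropy-matched", tol, prune,
            )
        if best_iea <= tol:
            return _finish(
                table, ev, selected, core, trace, h_full, h_sel, False,
                "no-improvement", tol, prune,
            )


def _finish(
    table, ev, selected, core, trace, h_full, h_sel, converged, reason, tol, prune
):
    selected = list(selected)
    if prune and len(selected) > 1:
        # backward pass: drop attributes that have become redundant
        changed = True
        while changed and len(selected) > 1:
            changed = False
            for a in list(selected):
                rest = frozenset(selected) - {a}
                if abs(ev.h_ace(rest) - h_full) <= tol:
                    selected.remove(a)
                    changed = True
                    break
        core = frozenset(core) & set(selected)
        h_sel = ev.h_ace(selected)
        trace = tuple(t for t in trace if t.attribute in selected)
    return SelectionResult(
        tuple(selected),
        frozenset(core),
        tuple(trace),
        float(h_full),
        float(h_sel),
        bool(converged),
        reason,
    )
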