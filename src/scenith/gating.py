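"""Threshold gating of events into named populations.

A stand-in for interactive gating: populations are defined by axis-aligned
threshold predicates on marker channels (composable into rectangles), with an
optional parent gate forming a forest.  Cutoffs are in raw arbitrary units —
no display transform is applied, consistent with the rest of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .events import ChannelMap, EventTable, validate_channels

_COMPARATORS = {
    ">": np.greater,
    "<": np.less,
    ">=": np.greater_equal,
    "<=": np.less_equal,
}

#: Label given to events matching no leaf gate.
UNGATED = "ungated"


@dataclass(frozen=True)
class GatePredicate:
    """One axis-aligned condition: ``marker <op> cutoff`` (cutoff in a.u.)."""

    marker: str  # marker role, resolved through the ChannelMap
    op: str
    cutoff: float

    def __post_init__(self) -> None:
        if self.op not in _COMPARATORS:
            raise ConfigError(
                f"unknown comparator {self.op!r}; use one of {sorted(_COMPARATORS)}"
            )


@dataclass(frozen=True)
class PopulationGate:
    name: str
    predicates: tuple[GatePredicate, ...]
    parent: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "predicates", tuple(self.predicates))
        if not self.predicates:
            raise ConfigError(f"gate {self.name!r} has no predicates")


@dataclass
class GateResult:
    """Per-event leaf-population labels plus per-gate membership counts."""

    labels: np.ndarray  # object array: leaf gate name or UNGATED
    counts: dict[str, int]  # every gate (incl. internal) plus UNGATED
    warnings: list[str] = field(default_factory=list)


def _check_forest(gates: list[PopulationGate]) -> None:
    names = [g.name for g in gates]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate gate names: {names}")
    by_name = {g.name: g for g in gates}
    for gate in gates:
        seen = {gate.name}
        node = gate
        while node.parent is not None:
            if node.parent not in by_name:
                raise ConfigError(
                    f"gate {node.name!r} names unknown parent {node.parent!r}"
                )
            if node.parent in seen:
                raise ConfigError(f"gate graph contains a cycle through {node.parent!r}")
            seen.add(node.parent)
            node = by_name[node.parent]


def apply_gates(
    table: EventTable, cmap: ChannelMap, gates: list[PopulationGate]
) -> GateResult:
    """Label every event with the leaf population it falls into.

    An event belongs to a gate iff it satisfies all the gate's predicates and
    belongs to the gate's parent.  Leaf gates (gates that are nobody's parent)
    define the population labels; when leaves overlap, the first matching leaf
    in definition order wins (deterministic).  Events matching no leaf are
    labelled ``"ungated"``.
    """
    gates = list(gates)
    _check_forest(gates)
    binding = validate_channels(table, cmap)

    membership: dict[str, np.ndarray] = {}

    def _mask(gate: PopulationGate) -> np.ndarray:
        if gate.name in membership:
            return membership[gate.name]
        mask = np.ones(table.n_events, dtype=bool)
        if gate.parent is not None:
            mask &= _mask(by_name[gate.parent])
        for pred in gate.predicates:
            if pred.marker not in binding.markers:
                raise ConfigError(
                    f"gate {gate.name!r} uses marker role {pred.marker!r} "
                    "absent from the channel map"
                )
            values = table.values[:, binding.markers[pred.marker]]
            mask &= _COMPARATORS[pred.op](values, pred.cutoff)
        membership[gate.name] = mask
        return mask

    by_name = {g.name: g for g in gates}
    parents = {g.parent for g in gates if g.parent is not None}
    leaves = [g for g in gates if g.name not in parents]

    labels = np.full(table.n_events, UNGATED, dtype=object)
    unlabelled = np.ones(table.n_events, dtype=bool)
    warnings: list[str] = []
    for gate in gates:
        _mask(gate)  # populate membership for counts
    for leaf in leaves:
        take = membership[leaf.name] & unlabelled
        labels[take] = leaf.name
        unlabelled &= ~take
    counts = {name: int(mask.sum()) for name, mask in membership.items()}
    counts[UNGATED] = int(unlabelled.sum())
    for name, count in counts.items():
        if name != UNGATED and count == 0:
            warnings.append(f"gate {name!r} matched 0 events")
    return GateResult(labels=labels, counts=counts, warnings=warnings)
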