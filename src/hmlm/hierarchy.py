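"""Scale-bridging operators between molecular, pathway, and cellular scales.

Three fixed scales are wired: molecular species (level 1) compose into
pathway units (level 2, one unit per functional module), which compose into
a single cellular unit (level 3).  The operators are deliberately simple and
deterministic: aggregation (children -> parent reductions), decomposition
(parent -> children broadcast or proportional splitting), and affine
translation between representational formats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = ["ScaleLevel", "molecular_pathway_levels", "aggregate_up", "decompose_down", "translate"]

_MODES = ("mean", "sum", "max")


@dataclass
class ScaleLevel:
    """One scale of the hierarchy with its composition map to the next.

    ``parent_map`` assigns every unit at this scale to its parent unit one
    scale up; it must be total (every unit has a parent) except at the top.
    """

    index: int
    units: list[str]
    parent_map: dict[str, str]

    def children_of(self, parent: str) -> list[str]:
        return [u for u in self.units if self.parent_map.get(u) == parent]

    def parents(self) -> list[str]:
        seen: list[str] = []
        for u in self.units:
            p = self.parent_map[u]
            if p not in seen:
                seen.append(p)
        return seen


def molecular_pathway_levels(net) -> tuple[ScaleLevel, ScaleLevel]:
    """Build the molecular->pathway and pathway->cellular levels of a network.

    Pathway units correspond one-to-one with the network's functional
    modules; the cellular scale is a single unit ``cell``.
    """
    molecular = ScaleLevel(
        index=1,
        units=list(net.species),
        parent_map={n.id: n.module for n in net.nodes},
    )
    modules = sorted(net.module_map)
    pathway = ScaleLevel(
        index=2,
        units=modules,
        parent_map={m: "cell" for m in modules},
    )
    return molecular, pathway


def aggregate_up(
    values: Mapping[str, float], level: ScaleLevel, mode: str = "mean"
) -> dict[str, float]:
    """Combine child-unit values into parent-unit values.

    ``mode`` is one of ``mean`` (default), ``sum``, ``max``.  Every parent
    must have at least one child with a value.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    groups: dict[str, list[float]] = {}
    for unit in level.units:
        if unit not in values:
            raise KeyError(f"no value supplied for unit {unit!r}")
        groups.setdefault(level.parent_map[unit], []).append(float(values[unit]))
    out: dict[str, float] = {}
    for parent, vals in groups.items():
        if not vals:
            raise ValueError(f"parent {parent!r} has no children")
        arr = np.asarray(vals)
        out[parent] = float({"mean": arr.mean, "sum": arr.sum, "max": arr.max}[mode]())
    return out


def decompose_down(
    value: float,
    children: Sequence[str],
    mode: str = "broadcast",
    weights: Sequence[float] | None = None,
) -> dict[str, float]:
    """Distribute a parent value over its children.

    ``broadcast`` copies the value to each child; ``proportional`` splits it
    in proportion to ``weights`` so the children sum to the parent value.
    """
    if not children:
        raise ValueError("children must be nonempty")
    if mode == "broadcast":
        return {c: float(value) for c in children}
    if mode == "proportional":
        if weights is None:
            raise ValueError("proportional mode requires weights")
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(children),):
            raise ValueError("weights length must match children")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        total = w.sum()
        if total <= 0:
            raise ValueError("weights must sum to a positive value")
        return {c: float(value * wi / total) for c, wi in zip(children, w)}
    raise ValueError("mode must be 'broadcast' or 'proportional'")


def translate(
    values: np.ndarray | Sequence[float],
    scale: float | np.ndarray = 1.0,
    offset: float | np.ndarray = 0.0,
) -> np.ndarray:
    """Affine format translation: ``scale @ values + offset``.

    ``scale`` may be a scalar (elementwise) or a matrix; shapes must be
    conformable.
    """
    v = np.asarray(values, dtype=float)
    s = np.asarray(scale, dtype=float)
    if s.ndim == 2:
        if s.shape[1] != v.shape[0]:
            raise ValueError(
                f"matrix scale of shape {s.shape} does not match input of "
                f"length {v.shape[0]}"
            )
        out = s @ v
    else:
        out = s * v
    return out + np.asarray(offset, dtype=float)
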