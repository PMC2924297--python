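"""Discrete factors over named variables, shared by scoring and inference.

A factor is a non-negative table over the joint states of an ordered tuple
of variables; every variable here is trinary with states ordered
(-1, 0, +1).  Factor product aligns variables by name via broadcasting;
marginalization sums variables out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

CARD = 3  # every pathway node is trinary


@dataclass
class Factor:
    variables: tuple[str, ...]
    table: np.ndarray  # shape (CARD,) * len(variables)

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if self.table.shape != (CARD,) * len(self.variables):
            raise ValueError("table shape does not match variable count")

    @classmethod
    def ones(cls, variables: Sequence[str]) -> "Factor":
        return cls(tuple(variables), np.ones((CARD,) * len(variables)))

    def multiply(self, other: "Factor") -> "Factor":
        new_vars = tuple(dict.fromkeys(self.variables + other.variables))
        return Factor(
            new_vars,
            self._expand(new_vars) * other._expand(new_vars),
        )

    def _expand(self, new_vars: tuple[str, ...]) -> np.ndarray:
        # move own axes into new_vars order, inserting broadcast axes
        src = [new_vars.index(v) for v in self.variables]
        arr = self.table
        shape = [1] * len(new_vars)
        for axis, pos in enumerate(src):
            shape[pos] = CARD
        order = np.argsort(src)
        arr = np.transpose(arr, axes=order)
        return arr.reshape(shape)

    def marginalize(self, keep: Iterable[str]) -> "Factor":
        keep = tuple(v for v in self.variables if v in set(keep))
        axes = tuple(i for i, v in enumerate(self.variables) if v not in keep)
        return Factor(keep, self.table.sum(axis=axes)) if axes else Factor(keep, self.table)

    def reduce(self, variable: str, state_index: int) -> "Factor":
        """Clamp ``variable`` to ``state_index``, zeroing all other states."""
        i = self.variables.index(variable)
        mask = np.zeros(CARD)
        mask[state_index] = 1.0
        shape = [1] * len(self.variables)
        shape[i] = CARD
        return Factor(self.variables, self.table * mask.reshape(shape))

    def normalize(self) -> "Factor":
        z = self.table.sum()
        if z <= 0:
            raise ZeroDivisionError("factor sums to zero")
        return Factor(self.variables, self.table / z)


def product(factors: Sequence[Factor]) -> Factor:
    if not factors:
        return Factor((), np.array(1.0))
    out = factors[0]
    for f in factors[1:]:
        out = out.multiply(f)
    return out


def eliminate(factors: Sequence[Factor], keep: Iterable[str]) -> Factor:
    """Sum-product variable elimination down to the ``keep`` marginal.

    Uses a min-degree elimination order with lexicographic tie-breaks; fine
    for the moderate treewidths of pathway-scale networks.
    """
    keep = set(keep)
    factors = list(factors)
    all_vars = sorted({v for f in factors for v in f.variables})
    to_go = [v for v in all_vars if v not in keep]
    while to_go:
        # min-degree: variable appearing with fewest distinct neighbours
        def degree(v: str) -> int:
            nbrs = {u for f in factors if v in f.variables for u in f.variables}
            return len(nbrs)

        v = min(sorted(to_go), key=degree)
        related = [f for f in factors if v in f.variables]
        rest = [f for f in factors if v not in f.variables]
        merged = product(related)
        summed = Factor(
            tuple(u for u in merged.variables if u != v),
            merged.table.sum(axis=merged.variables.index(v)),
        )
        factors = rest + [summed]
        to_go.remove(v)
    out = product(factors)
    return out.marginalize(keep)
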