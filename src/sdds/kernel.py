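"""Transition kernel of an SDDS.

For a state ``x``, each coordinate either moves to its rule's image
``f_i(x)`` or holds its current value.  The per-coordinate probabilities
are set by the propensity pair:

* ``x_i < f_i(x)``: move with probability ``p_up_i``, hold with ``1 - p_up_i``;
* ``x_i > f_i(x)``: move with probability ``p_down_i``, hold with ``1 - p_down_i``;
* ``x_i = f_i(x)``: hold with probability 1.

Coordinates update independently, so the weight of an edge ``x -> y`` is
the product of its coordinate terms, and ``y`` has positive weight only
when ``y_i`` is ``x_i`` or ``f_i(x)`` for every ``i``.  Zero-weight edges
are omitted bit-exactly: exact-zero factors prune enumeration branches
before any multiplication.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Sequence

from .model import SDDSModel, State

__all__ = [
    "coordinate_propensity",
    "transition_weight",
    "transition_distribution",
    "TransitionDistribution",
]


@dataclass
class TransitionDistribution:
    """Sparse successor distribution of a single source state.

    ``successors`` maps each positive-probability successor state to its
    transition probability; the probabilities sum to 1.
    """

    source: State
    successors: Dict[State, float]

    def __getitem__(self, y: Sequence[int]) -> float:
        return self.successors.get(tuple(y), 0.0)

    def support(self):
        return set(self.successors)

    def total(self) -> float:
        return sum(self.successors.values())


def coordinate_propensity(
    model: SDDSModel, x: Sequence[int], i: int, target_level: int
) -> float:
    """Probability that coordinate ``i`` of state ``x`` becomes ``target_level``.

    Zero for any level other than the current value ``x_i`` and the rule
    image ``f_i(x)``.
    """
    x = model.space.check_state(x)
    if not 0 <= i < model.n:
        raise IndexError(f"variable index {i} out of range for n={model.n}")
    xi = x[i]
    fi = model.rules[i](x, model.space)
    if target_level not in (xi, fi):
        return 0.0
    if xi == fi:
        return 1.0
    p = model.propensities[i].up if xi < fi else model.propensities[i].down
    return p if target_level == fi else 1.0 - p


def transition_weight(model: SDDSModel, x: Sequence[int], y: Sequence[int]) -> float:
    """Edge weight ``w(x -> y)``: the product of coordinate propensities."""
    x = model.space.check_state(x)
    y = model.space.check_state(y)
    w = 1.0
    for i in range(model.n):
        term = coordinate_propensity(model, x, i, y[i])
        if term == 0.0:
            return 0.0
        w *= term
    return w


def transition_distribution(model: SDDSModel, x: Sequence[int]) -> TransitionDistribution:
    """All positive-probability successors of ``x`` with their weights.

    Enumerates only over the coordinates whose image differs from the
    current value (at most ``2^k`` candidates, not the whole space).
    """
    x = model.space.check_state(x)
    choices = []  # per coordinate: list of (level, probability), zeros pruned
    for i in range(model.n):
        xi = x[i]
        fi = model.rules[i](x, model.space)
        if fi == xi:
            choices.append(((xi, 1.0),))
        else:
            p = model.propensities[i].up if xi < fi else model.propensities[i].down
            opts = []
            if p > 0.0:
                opts.append((fi, p))
            if p < 1.0:
                opts.append((xi, 1.0 - p))
            choices.append(tuple(opts))
    successors: Dict[State, float] = {}
    for combo in itertools.product(*choices):
        w = 1.0
        for _, term in combo:
            w *= term
        successors[tuple(level for level, _ in combo)] = w
    return TransitionDistribution(source=x, successors=successors)
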