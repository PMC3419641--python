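"""Core types for stochastic discrete dynamical systems (SDDS).

An SDDS over variables ``x_1 .. x_n`` with finite, totally ordered level
sets assigns to each variable a triplet ``(f_i, p_up_i, p_down_i)``: a
multi-valued update rule and a pair of propensity probabilities.  When the
rule calls for the variable to rise, the update fires with probability
``p_up``; when it calls for it to fall, with probability ``p_down``;
otherwise the variable holds its value.  States are tuples of integer
levels, rendered as digit strings (``"0011"``) whenever every cardinality
is at most 10.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

State = tuple  # tuple of per-variable integer levels

__all__ = [
    "State",
    "StateSpace",
    "UpdateRule",
    "PropensityPair",
    "SDDSModel",
    "ModelValidationError",
    "state_from_string",
    "state_to_string",
]


class ModelValidationError(ValueError):
    """A model or state violates a structural invariant."""


@dataclass(frozen=True)
class StateSpace:
    """Ordered product of finite level sets ``X = X_1 x ... x X_n``.

    Variable ``i`` takes the consecutive integer levels
    ``0 .. cardinalities[i] - 1`` in their natural order.  Variable 0 is
    the leftmost digit of string notation and the most significant
    coordinate of the lexicographic state rank.
    """

    names: tuple
    cardinalities: tuple

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "cardinalities", tuple(int(c) for c in self.cardinalities))
        if len(self.names) != len(self.cardinalities):
            raise ModelValidationError("names and cardinalities differ in length")
        if len(self.names) < 1:
            raise ModelValidationError("a state space needs at least one variable")
        if len(set(self.names)) != len(self.names):
            raise ModelValidationError("variable names must be unique")
        for name, card in zip(self.names, self.cardinalities):
            if card < 2:
                raise ModelValidationError(
                    f"variable {name!r} has cardinality {card}; at least 2 levels required"
                )

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def total_states(self) -> int:
        return math.prod(self.cardinalities)

    def states(self) -> Iterator[State]:
        """All states in lexicographic order (variable 0 slowest)."""
        return itertools.product(*(range(c) for c in self.cardinalities))

    def contains(self, state: Sequence[int]) -> bool:
        return len(state) == self.n and all(
            0 <= v < c for v, c in zip(state, self.cardinalities)
        )

    def check_state(self, state: Sequence[int]) -> State:
        state = tuple(int(v) for v in state)
        if not self.contains(state):
            raise ModelValidationError(f"state {state} not in space {self.cardinalities}")
        return state

    def index(self, state: Sequence[int]) -> int:
        """Lexicographic rank of a state, variable 0 most significant."""
        rank = 0
        for v, c in zip(state, self.cardinalities):
            rank = rank * c + v
        return rank

    def state_at(self, rank: int) -> State:
        rank = int(rank)
        levels = []
        for c in reversed(self.cardinalities):
            levels.append(rank % c)
            rank //= c
        return tuple(reversed(levels))

    def variable_index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ModelValidationError(f"unknown variable {name!r}") from None


def state_from_string(s: str, space: StateSpace) -> State:
    """Decode positional digit notation, e.g. ``"0011"``.

    Only defined when every cardinality is at most 10; the leftmost digit
    is variable 0.
    """
    if any(c > 10 for c in space.cardinalities):
        raise ModelValidationError(
            "digit-string state notation requires all cardinalities <= 10"
        )
    if len(s) != space.n:
        raise ModelValidationError(
            f"state string {s!r} has length {len(s)}, expected {space.n}"
        )
    if not s.isdigit():
        raise ModelValidationError(f"state string {s!r} contains non-digit characters")
    return space.check_state(tuple(int(ch) for ch in s))


def state_to_string(state: Sequence[int], space: StateSpace) -> str:
    if any(c > 10 for c in space.cardinalities):
        raise ModelValidationError(
            "digit-string state notation requires all cardinalities <= 10"
        )
    return "".join(str(v) for v in space.check_state(state))


@dataclass
class UpdateRule:
    """Update function ``f_i : X -> X_i`` stored as an expanded truth table.

    ``inputs`` lists the variable indices the rule reads, and ``table``
    holds the target level for every combination of input levels in
    row-major order (first listed input slowest).  ``expr`` optionally
    retains the expression the table was expanded from.
    """

    target: int
    inputs: tuple
    table: np.ndarray
    expr: str | None = None

    def __post_init__(self):
        self.inputs = tuple(int(i) for i in self.inputs)
        self.table = np.asarray(self.table, dtype=np.int64)

    def validate(self, space: StateSpace) -> None:
        if not 0 <= self.target < space.n:
            raise ModelValidationError(f"rule target index {self.target} out of range")
        for i in self.inputs:
            if not 0 <= i < space.n:
                raise ModelValidationError(f"rule input index {i} out of range")
        expected = math.prod(space.cardinalities[i] for i in self.inputs) if self.inputs else 1
        if self.table.shape != (expected,):
            raise ModelValidationError(
                f"rule for {space.names[self.target]!r}: table has {self.table.size} "
                f"entries, expected {expected} (one per input-state)"
            )
        card = space.cardinalities[self.target]
        if self.table.size and (self.table.min() < 0 or self.table.max() >= card):
            bad = int(self.table[(self.table < 0) | (self.table >= card)][0])
            raise ModelValidationError(
                f"rule for {space.names[self.target]!r}: output {bad} outside "
                f"levels 0..{card - 1}"
            )

    def row_index(self, state: Sequence[int], space: StateSpace) -> int:
        rank = 0
        for i in self.inputs:
            rank = rank * space.cardinalities[i] + state[i]
        return rank

    def __call__(self, state: Sequence[int], space: StateSpace) -> int:
        return int(self.table[self.row_index(state, space)])


@dataclass(frozen=True)
class PropensityPair:
    """Activation/degradation propensities, both probabilities in [0, 1]."""

    up: float
    down: float

    def __post_init__(self):
        for label, p in (("activation", self.up), ("degradation", self.down)):
            if not (isinstance(p, (int, float)) and 0.0 <= float(p) <= 1.0):
                raise ModelValidationError(
                    f"{label} propensity {p!r} is not a probability in [0, 1]"
                )
        object.__setattr__(self, "up", float(self.up))
        object.__setattr__(self, "down", float(self.down))


@dataclass
class SDDSModel:
    """A stochastic discrete dynamical system: one (rule, propensity pair)
    triplet per variable.

    ``image(x)`` evaluates the underlying deterministic synchronous map
    ``G = (f_1, ..., f_n)``.
    """

    space: StateSpace
    rules: tuple
    propensities: tuple
    name: str | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.rules = tuple(self.rules)
        self.propensities = tuple(self.propensities)
        if len(self.rules) != self.space.n:
            raise ModelValidationError(
                f"{len(self.rules)} rules for {self.space.n} variables"
            )
        if len(self.propensities) != self.space.n:
            raise ModelValidationError(
                f"{len(self.propensities)} propensity pairs for {self.space.n} variables"
            )
        targets = sorted(r.target for r in self.rules)
        if targets != list(range(self.space.n)):
            raise ModelValidationError("exactly one rule per variable is required")
        self.rules = tuple(sorted(self.rules, key=lambda r: r.target))
        for rule in self.rules:
            rule.validate(self.space)

    @property
    def n(self) -> int:
        return self.space.n

    def image(self, state: Sequence[int]) -> State:
        """Deterministic synchronous successor ``G(x)``."""
        state = tuple(state)
        return tuple(rule(state, self.space) for rule in self.rules)

    def image_table(self) -> np.ndarray:
        """Rank of ``G(x)`` for every state rank (cached; enumerates X)."""
        tab = self._cache.get("image_table")
        if tab is None:
            space = self.space
            tab = np.empty(space.total_states, dtype=np.int64)
            for rank, x in enumerate(space.states()):
                tab[rank] = space.index(self.image(x))
            self._cache["image_table"] = tab
        return tab

    def with_propensities(self, overrides: Mapping) -> "SDDSModel":
        """Copy of the model with some propensity pairs replaced.

        ``overrides`` maps variable name (or index) to an ``(up, down)``
        pair or :class:`PropensityPair`.
        """
        props = list(self.propensities)
        for key, value in overrides.items():
            i = key if isinstance(key, int) else self.space.variable_index(key)
            if not isinstance(value, PropensityPair):
                value = PropensityPair(*value)
            props[i] = value
        return SDDSModel(self.space, self.rules, tuple(props), name=self.name)

    def rules_equal(self, other: "SDDSModel") -> bool:
        """Extensional equality of update rules: same image on all of X."""
        if self.space != other.space:
            return False
        return bool(np.array_equal(self.image_table(), other.image_table()))
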