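"""State-space analysis: transition graph, attractors, exact distributions.

These routines enumerate the whole state space and are meant for the
model sizes where that is feasible (a configurable cap, one million
states by default); Monte-Carlo simulation covers larger systems.

Distribution vectors are indexed by the lexicographic rank of states with
variable 1 most significant, so external tools can align columns.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .kernel import transition_distribution
from .model import ModelValidationError, SDDSModel, State, state_to_string

__all__ = [
    "StateSpaceCapExceeded",
    "build_state_graph",
    "transition_matrix",
    "fixed_points",
    "attractors",
    "AttractorSet",
    "exact_distribution",
    "expected_levels",
    "deterministic_trajectory",
    "graph_to_dot",
    "graph_to_edge_csv",
    "distribution_to_csv",
]

DEFAULT_STATE_CAP = 10**6


class StateSpaceCapExceeded(RuntimeError):
    """The state space is too large to enumerate; use simulation instead."""


def _check_cap(model: SDDSModel, cap: int) -> None:
    if model.space.total_states > cap:
        raise StateSpaceCapExceeded(
            f"state space has {model.space.total_states} states, above the cap of "
            f"{cap}; use the simulation workflow instead of full enumeration"
        )


def build_state_graph(model: SDDSModel, cap: int = DEFAULT_STATE_CAP) -> nx.DiGraph:
    """Weighted digraph over X containing exactly the positive-weight edges."""
    _check_cap(model, cap)
    graph = nx.DiGraph()
    for x in model.space.states():
        graph.add_node(x)
    for x in model.space.states():
        for y, w in transition_distribution(model, x).successors.items():
            graph.add_edge(x, y, weight=w)
    return graph


def transition_matrix(model: SDDSModel, cap: int = DEFAULT_STATE_CAP) -> sp.csr_matrix:
    """Row-stochastic transition matrix in lexicographic state order."""
    _check_cap(model, cap)
    space = model.space
    rows, cols, data = [], [], []
    for rank, x in enumerate(space.states()):
        for y, w in transition_distribution(model, x).successors.items():
            rows.append(rank)
            cols.append(space.index(y))
            data.append(w)
    size = space.total_states
    return sp.csr_matrix((data, (rows, cols)), shape=(size, size))


def fixed_points(model: SDDSModel, cap: int = DEFAULT_STATE_CAP) -> set:
    """States with ``G(x) = x``; these are exactly the absorbing states of
    the stochastic system, independent of the propensity values."""
    _check_cap(model, cap)
    tab = model.image_table()
    return {
        model.space.state_at(rank)
        for rank in np.flatnonzero(tab == np.arange(tab.size))
    }


@dataclass
class AttractorSet:
    """Terminal strongly connected components of the positive-weight graph.

    Singleton components are fixed points; larger ones are listed as
    cycles (complex attractors).
    """

    fixed_points: set
    cycles: list

    def all_states(self) -> set:
        states = set(self.fixed_points)
        for cyc in self.cycles:
            states |= set(cyc)
        return states


def attractors(graph: nx.DiGraph) -> AttractorSet:
    cond = nx.condensation(graph)
    fps = set()
    cycles = []
    for node in cond.nodes:
        if cond.out_degree(node) == 0:
            members = cond.nodes[node]["members"]
            if len(members) == 1:
                fps.add(next(iter(members)))
            else:
                cycles.append(frozenset(members))
    cycles.sort(key=lambda c: sorted(c))
    return AttractorSet(fixed_points=fps, cycles=cycles)


def exact_distribution(
    model: SDDSModel,
    init,
    steps: int,
    cap: int = DEFAULT_STATE_CAP,
) -> np.ndarray:
    """Propagate an initial distribution ``steps`` times through the kernel.

    ``init`` is either a single state (point mass) or a probability vector
    over X in lexicographic order.
    """
    _check_cap(model, cap)
    size = model.space.total_states
    if isinstance(init, (tuple, list)) and len(init) == model.space.n and all(
        isinstance(v, (int, np.integer)) for v in init
    ):
        v = np.zeros(size)
        v[model.space.index(model.space.check_state(init))] = 1.0
    else:
        v = np.asarray(init, dtype=float)
        if v.shape != (size,):
            raise ModelValidationError(
                f"init vector has shape {v.shape}, expected ({size},)"
            )
        if abs(v.sum() - 1.0) > 1e-9 or (v < 0).any():
            raise ModelValidationError("init vector must be a probability distribution")
    matrix = transition_matrix(model, cap=cap)
    for _ in range(int(steps)):
        v = v @ matrix
    return v


def expected_levels(model: SDDSModel, distribution: np.ndarray) -> np.ndarray:
    """Per-variable expected level under a distribution over X."""
    space = model.space
    levels = np.array(list(space.states()))
    return distribution @ levels


def deterministic_trajectory(
    model: SDDSModel,
    init: Sequence[int],
    steps: int,
    scheme: str = "synchronous",
    order: Iterable[int] | None = None,
) -> list:
    """Trajectory of the deterministic system G under a classical scheme.

    ``synchronous`` applies all rules at once; ``asynchronous`` applies
    them sequentially in a fixed ``order`` (a permutation of variable
    indices) within each time step.
    """
    x = model.space.check_state(init)
    traj = [x]
    if scheme == "synchronous":
        for _ in range(int(steps)):
            x = model.image(x)
            traj.append(x)
        return traj
    if scheme == "asynchronous":
        if order is None:
            order = range(model.n)
        order = [int(i) for i in order]
        if sorted(order) != list(range(model.n)):
            raise ModelValidationError(
                "asynchronous order must be a permutation of all variable indices"
            )
        for _ in range(int(steps)):
            for i in order:
                levels = list(x)
                levels[i] = model.rules[i](x, model.space)
                x = tuple(levels)
            traj.append(x)
        return traj
    raise ModelValidationError(f"unknown update scheme {scheme!r}")


# ------------------------------------------------------------- exports


def _label(state: State, model: SDDSModel) -> str:
    if all(c <= 10 for c in model.space.cardinalities):
        return state_to_string(state, model.space)
    return "(" + ",".join(str(v) for v in state) + ")"


def graph_to_dot(
    graph: nx.DiGraph, model: SDDSModel, include_self_loops: bool = False
) -> str:
    """DOT rendering with weights as edge labels (6 significant digits).

    Self-loops are omitted from the drawing by default, matching the
    usual presentation of these diagrams; data exports always keep them.
    """
    out = io.StringIO()
    out.write("digraph statespace {\n")
    for node in graph.nodes:
        out.write(f'  "{_label(node, model)}";\n')
    for x, y, data in graph.edges(data=True):
        if x == y and not include_self_loops:
            continue
        out.write(
            f'  "{_label(x, model)}" -> "{_label(y, model)}" '
            f'[label="{data["weight"]:.6g}"];\n'
        )
    out.write("}\n")
    return out.getvalue()


def graph_to_edge_csv(graph: nx.DiGraph, model: SDDSModel) -> str:
    lines = ["source_state,target_state,weight"]
    for x, y, data in graph.edges(data=True):
        lines.append(f"{_label(x, model)},{_label(y, model)},{data['weight']!r}")
    return "\n".join(lines) + "\n"


def distribution_to_csv(model: SDDSModel, distribution: np.ndarray) -> str:
    lines = ["state,probability"]
    for rank, state in enumerate(model.space.states()):
        lines.append(f"{_label(state, model)},{float(distribution[rank])!r}")
    return "\n".join(lines) + "\n"
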