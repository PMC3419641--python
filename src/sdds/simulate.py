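"""Monte-Carlo simulation of SDDS trajectories and cell populations.

Each variable is sampled independently within a time step (ascending
variable index, one uniform draw per coordinate whose image differs from
its current value), so a sampled step follows exactly the same law as
:func:`sdds.kernel.transition_distribution`.

Reproducibility contract: every cell of a population gets its own
generator derived from the master seed through
``numpy.random.SeedSequence(entropy=seed, spawn_key=(*stream, cell_index))``.
The per-cell streams therefore do not depend on execution order, and a
run is reproducible bit-exactly from ``(model, init, n_cells, steps,
seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np

from .model import ModelValidationError, SDDSModel, State

__all__ = [
    "Trajectory",
    "PopulationSummary",
    "OutcomeTally",
    "sample_step",
    "cell_rng",
    "simulate_cell",
    "simulate_population",
    "classify_outcomes",
    "propensity_sweep",
    "symmetric_assignments",
    "first_hit_time",
    "trajectory_to_csv",
    "summary_to_csv",
    "sweep_to_tsv",
]

OCCUPANCY_CAP = 4096  # record per-state counts only for spaces up to this size


def _step_info(model: SDDSModel, x: State):
    """(coords, probs, targets) of the coordinates that can move from x."""
    cache = model._cache.setdefault("step_info", {})
    info = cache.get(x)
    if info is None:
        image = model.image(x)
        coords, probs, targets = [], [], []
        for i, (xi, fi) in enumerate(zip(x, image)):
            if xi != fi:
                pp = model.propensities[i]
                coords.append(i)
                probs.append(pp.up if xi < fi else pp.down)
                targets.append(fi)
        info = (tuple(coords), np.asarray(probs), tuple(targets))
        cache[x] = info
    return info


def sample_step(model: SDDSModel, x: Sequence[int], rng: np.random.Generator) -> State:
    """Draw one stochastic update of every coordinate of ``x``."""
    x = tuple(x)
    coords, probs, targets = _step_info(model, x)
    if not coords:
        return x
    u = rng.random(len(coords))
    if (u >= probs).all():
        return x
    levels = list(x)
    for j, c in enumerate(coords):
        if u[j] < probs[j]:
            levels[c] = targets[j]
    return tuple(levels)


def cell_rng(master_seed: int, cell_index: int, stream: tuple = ()) -> np.random.Generator:
    """Per-cell generator; independent of the order cells are simulated in."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(*stream, int(cell_index)))
    return np.random.default_rng(ss)


@dataclass
class Trajectory:
    """A single sampled cell path: ``states[0]`` is the initial state."""

    states: list
    seed: int | None = None
    model_name: str | None = None

    @property
    def steps(self) -> int:
        return len(self.states) - 1

    def final(self) -> State:
        return self.states[-1]


def _run_cell(model: SDDSModel, init: State, steps: int, rng: np.random.Generator) -> list:
    states = [init]
    x = init
    for _ in range(steps):
        x = sample_step(model, x, rng)
        states.append(x)
    return states


def simulate_cell(
    model: SDDSModel,
    init: Sequence[int],
    steps: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Repeatedly apply :func:`sample_step`; same seed, same trajectory."""
    init = model.space.check_state(init)
    if steps < 0:
        raise ModelValidationError("steps must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    return Trajectory(
        states=_run_cell(model, init, int(steps), rng),
        seed=seed,
        model_name=model.name,
    )


@dataclass
class PopulationSummary:
    """Per-step, per-variable mean and standard deviation over a population.

    ``state_counts`` (present for small state spaces) holds the number of
    cells in each state at each step, indexed ``[step, state_rank]``.
    """

    names: tuple
    means: np.ndarray  # (steps + 1, n)
    sds: np.ndarray  # (steps + 1, n)
    n_cells: int
    steps: int
    seed: int | None
    state_counts: np.ndarray | None = None

    def frequencies(self, step: int) -> np.ndarray:
        if self.state_counts is None:
            raise ModelValidationError("state occupancy was not recorded for this run")
        return self.state_counts[step] / self.n_cells


def simulate_population(
    model: SDDSModel,
    init: Sequence[int],
    n_cells: int,
    steps: int,
    seed: int,
    stream: tuple = (),
) -> PopulationSummary:
    """Simulate ``n_cells`` independent cells and aggregate level statistics."""
    init = model.space.check_state(init)
    if n_cells < 1:
        raise ModelValidationError("n_cells must be >= 1")
    n = model.space.n
    total = model.space.total_states
    track_states = total <= OCCUPANCY_CAP
    sums = np.zeros((steps + 1, n))
    sumsq = np.zeros((steps + 1, n))
    counts = np.zeros((steps + 1, total), dtype=np.int64) if track_states else None
    index = model.space.index
    for cell in range(n_cells):
        states = _run_cell(model, init, int(steps), cell_rng(seed, cell, stream))
        arr = np.asarray(states, dtype=float)
        sums += arr
        sumsq += arr * arr
        if track_states:
            for t, x in enumerate(states):
                counts[t, index(x)] += 1
    means = sums / n_cells
    variances = np.maximum(sumsq / n_cells - means**2, 0.0)
    return PopulationSummary(
        names=model.space.names,
        means=means,
        sds=np.sqrt(variances),
        n_cells=n_cells,
        steps=int(steps),
        seed=seed,
        state_counts=counts,
    )


@dataclass
class OutcomeTally:
    """Counts of trajectories per labeled attractor, plus unresolved ones."""

    counts: Dict[str, int]
    unresolved: int
    n_cells: int

    def fraction(self, label: str) -> float:
        return self.counts[label] / self.n_cells


def _normalize_labels(model: SDDSModel, labels: Mapping) -> Dict[str, frozenset]:
    from .model import state_from_string

    norm: Dict[str, frozenset] = {}
    seen: Dict[State, str] = {}
    for name, states in labels.items():
        states = [states] if isinstance(states, (str, tuple)) else list(states)
        converted = set()
        for s in states:
            s = state_from_string(s, model.space) if isinstance(s, str) else model.space.check_state(s)
            if s in seen:
                raise ModelValidationError(
                    f"state {s} appears in both labels {seen[s]!r} and {name!r}"
                )
            seen[s] = name
            converted.add(s)
        norm[name] = frozenset(converted)
    return norm


def classify_outcomes(
    model: SDDSModel,
    labels: Mapping,
    trajectories: Iterable[Trajectory] | None = None,
    init: Sequence[int] | None = None,
    n_cells: int | None = None,
    steps: int | None = None,
    seed: int | None = None,
    stream: tuple = (),
) -> OutcomeTally:
    """Tally trajectories by the labeled attractor containing their final state.

    ``labels`` maps an outcome name to a set of states (digit strings or
    tuples); the sets must be disjoint.  Either pass ``trajectories`` or
    the ``(init, n_cells, steps, seed)`` of a fresh population.
    """
    norm = _normalize_labels(model, labels)
    if trajectories is None:
        if init is None or n_cells is None or steps is None or seed is None:
            raise ModelValidationError(
                "classify_outcomes needs trajectories or (init, n_cells, steps, seed)"
            )
        init = model.space.check_state(init)
        finals = []
        for cell in range(n_cells):
            x = init
            rng = cell_rng(seed, cell, stream)
            for _ in range(int(steps)):
                x = sample_step(model, x, rng)
            finals.append(x)
    else:
        finals = [t.final() for t in trajectories]
    counts = {name: 0 for name in norm}
    unresolved = 0
    for x in finals:
        for name, states in norm.items():
            if x in states:
                counts[name] += 1
                break
        else:
            unresolved += 1
    return OutcomeTally(counts=counts, unresolved=unresolved, n_cells=len(finals))


def symmetric_assignments(var_a: str, var_b: str, values: Iterable[float]) -> list:
    """Antagonistic propensity grid: ``a`` drives ``var_a`` up and ``var_b``
    down while ``1 - a`` does the reverse, one assignment per grid value."""
    out = []
    for a in values:
        a = float(a)
        out.append((a, {var_a: (a, 1.0 - a), var_b: (1.0 - a, a)}))
    return out


def propensity_sweep(
    model: SDDSModel,
    init: Sequence[int],
    n_cells: int,
    steps: int,
    assignments: Sequence,
    labels: Mapping,
    seed: int,
) -> list:
    """One outcome tally per propensity assignment.

    ``assignments`` is a list of ``(grid_value, overrides)`` pairs, e.g.
    from :func:`symmetric_assignments`.  Each grid point gets its own
    sub-stream of the master seed.
    """
    rows = []
    for idx, (value, overrides) in enumerate(assignments):
        swept = model.with_propensities(overrides)
        tally = classify_outcomes(
            swept, labels, init=init, n_cells=n_cells, steps=steps,
            seed=seed, stream=(idx,),
        )
        rows.append((value, tally))
    return rows


def first_hit_time(trajectory: Trajectory, var_index: int, level: int):
    """First step at which a variable reaches a level, or None."""
    for t, state in enumerate(trajectory.states):
        if state[var_index] == level:
            return t
    return None


# ------------------------------------------------------------- exports


def trajectory_to_csv(trajectory: Trajectory, names: Sequence[str]) -> str:
    lines = ["step," + ",".join(names)]
    for t, state in enumerate(trajectory.states):
        lines.append(f"{t}," + ",".join(str(v) for v in state))
    return "\n".join(lines) + "\n"


def summary_to_csv(summary: PopulationSummary) -> str:
    header = ["step"]
    for nm in summary.names:
        header += [f"mean_{nm}", f"sd_{nm}"]
    lines = [",".join(header)]
    for t in range(summary.steps + 1):
        row = [str(t)]
        for j in range(len(summary.names)):
            row += [repr(float(summary.means[t, j])), repr(float(summary.sds[t, j]))]
        lines.append(",".join(row))
    return "\n".join(lines) + "\n"


def sweep_to_tsv(rows: Sequence, labels: Sequence[str]) -> str:
    header = ["a"] + [f"n_{nm}" for nm in labels] + ["n_unresolved"] + [
        f"fraction_{nm}" for nm in labels
    ]
    lines = ["\t".join(header)]
    for value, tally in rows:
        fields = [repr(float(value))]
        fields += [str(tally.counts[nm]) for nm in labels]
        fields.append(str(tally.unresolved))
        fields += [repr(tally.counts[nm] / tally.n_cells) for nm in labels]
        lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"
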