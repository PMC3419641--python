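"""Bundled models and the random-model generator.

Three models ship with the package:

``example_2_1_1``
    The two-variable Boolean illustration (``f1 = x2``,
    ``f2 = x1 AND NOT x2``) whose full transition graph is small enough
    to write down: eleven positive-weight edges and the fixed point 00.

``p53_mdm2``
    A four-variable damage-response network (p53 at three levels;
    cytoplasmic and nuclear Mdm2 and DNA damage Boolean).  The default
    propensities keep damage repair slow (degradation propensity 0.05),
    producing noisy p53 oscillations in single cells and a damped mean
    oscillation across a population.

``phage_lambda``
    The four-gene lysis/lysogeny switch (CI at three levels, CRO at
    four, CII and N Boolean), bistable between the lysogenic fixed point
    2000 and the lytic 2-cycle {0200, 0300}.

The multi-valued update rules of the two biological models are
transcriptions of the published logical models of these systems (the
Abou-Jaoude p53-Mdm2 model and the Thieffry-Thomas lambda switch), with
multilevel genes moving one level per step toward their logical image.
Because a transcription error could silently change the science,
``load_fixture`` re-derives the documented structural facts — fixed
points, the lambda 2-cycle, the qualitative repression constraints, the
worked example's printed probabilities — on every load and fails loudly
if any check breaks.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Sequence

import numpy as np

from .analysis import attractors, build_state_graph, fixed_points
from .io import parse_model
from .kernel import transition_distribution
from .model import PropensityPair, SDDSModel, StateSpace, UpdateRule

__all__ = [
    "FIXTURE_NAMES",
    "FixtureIntegrityError",
    "load_fixture",
    "default_init",
    "random_model",
    "EXAMPLE_TRANSITIONS",
    "LAMBDA_TABLE2",
    "LAMBDA_TABLE3",
    "LAMBDA_LABELS",
    "P53_DAMPING_GRID",
]

FIXTURE_NAMES = ("example_2_1_1", "p53_mdm2", "phage_lambda")

#: The eleven positive one-step probabilities of the worked example,
#: written as the products of their coordinate factors.
EXAMPLE_TRANSITIONS = {
    ("01", "10"): 0.1 * 0.9,
    ("01", "00"): (1 - 0.1) * 0.9,
    ("01", "01"): (1 - 0.1) * (1 - 0.9),
    ("01", "11"): 0.1 * (1 - 0.9),
    ("10", "10"): (1 - 0.2) * (1 - 0.5),
    ("10", "01"): 0.2 * 0.5,
    ("10", "00"): 0.2 * (1 - 0.5),
    ("10", "11"): (1 - 0.2) * 0.5,
    ("11", "11"): 1 * (1 - 0.9),
    ("11", "10"): 1 * 0.9,
    ("00", "00"): 1.0,
}

#: Propensity set favouring CI (lysogeny-prone) and its CRO-favouring mirror.
LAMBDA_TABLE2 = {"CI": (0.8, 0.2), "CRO": (0.2, 0.8), "CII": (0.9, 0.9), "N": (0.9, 0.9)}
LAMBDA_TABLE3 = {"CI": (0.3, 0.7), "CRO": (0.7, 0.3), "CII": (0.9, 0.9), "N": (0.9, 0.9)}

#: Attractor labels for outcome classification in the lambda model.
LAMBDA_LABELS = {"lysogeny": ["2000"], "lysis": ["0200", "0300"]}

#: Damage degradation propensities used for the population damping series.
P53_DAMPING_GRID = (0.05, 0.10, 0.15, 0.20)


class FixtureIntegrityError(RuntimeError):
    """A bundled model fails one of its documented structural checks."""


def _read_fixture_doc(name: str) -> dict:
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    path = resources.files("sdds").joinpath("data", f"{name}.json")
    return json.loads(path.read_text())


def default_init(name: str) -> str:
    """Default initial state (digit string) of a bundled model."""
    return _read_fixture_doc(name)["init"]


def load_fixture(name: str) -> SDDSModel:
    """Load a bundled model and verify its structural integrity."""
    doc = _read_fixture_doc(name)
    model = parse_model(json.dumps(doc), dialect="json")
    _INTEGRITY_CHECKS[name](model)
    return model


def _require(condition: bool, name: str, message: str) -> None:
    if not condition:
        raise FixtureIntegrityError(f"fixture {name!r}: {message}")


def _check_example(model: SDDSModel) -> None:
    space = model.space
    _require(space.cardinalities == (2, 2), "example_2_1_1", "state space must be Boolean 2x2")
    seen = {}
    for x in space.states():
        dist = transition_distribution(model, x)
        for y, w in dist.successors.items():
            seen[("".join(map(str, x)), "".join(map(str, y)))] = w
    _require(
        set(seen) == set(EXAMPLE_TRANSITIONS)
        and all(seen[k] == v for k, v in EXAMPLE_TRANSITIONS.items()),
        "example_2_1_1",
        "transition graph does not match the eleven documented probabilities",
    )
    _require(fixed_points(model) == {(0, 0)}, "example_2_1_1", "00 must be the only fixed point")


def _check_p53(model: SDDSModel) -> None:
    name = "p53_mdm2"
    _require(model.space.names == ("P", "Mc", "Mn", "Dam"), name, "variable order must be P, Mc, Mn, Dam")
    _require(model.space.cardinalities == (3, 2, 2, 2), name, "state space must be [0,2]x[0,1]^3")
    _require(fixed_points(model) == {(0, 0, 1, 0)}, name, "0010 must be the unique fixed point")
    dam_rule = model.rules[3]
    _require(
        set(dam_rule.inputs) <= {3} and all(v == 0 for v in dam_rule.table),
        name,
        "damage must decay monotonically (rule reads only Dam, image 0)",
    )
    att = attractors(build_state_graph(model))
    _require(
        att.fixed_points == {(0, 0, 1, 0)} and not att.cycles,
        name,
        "the undamaged steady state must be the only attractor",
    )


def _check_lambda(model: SDDSModel) -> None:
    name = "phage_lambda"
    _require(model.space.names == ("CI", "CRO", "CII", "N"), name, "variable order must be CI, CRO, CII, N")
    _require(model.space.cardinalities == (3, 4, 2, 2), name, "state space must be [0,2]x[0,3]x[0,1]^2")
    _require(fixed_points(model) == {(2, 0, 0, 0)}, name, "2000 must be the unique fixed point")
    for x in model.space.states():
        ci, cro, cii, nn = x
        f = model.image(x)
        if ci == 2:
            _require(
                f[2] == 0 and f[3] == 0 and (f[1] < cro or cro == 0),
                name,
                f"full CI must switch every other gene off (violated at {x})",
            )
        if cro == 0:
            _require(f[0] == min(ci + 1, 2), name, f"CI must rise toward full expression when CRO is absent (violated at {x})")
        if cro >= 1 and cii == 0:
            _require(f[0] == max(ci - 1, 0), name, f"CI must fall when CRO is active and CII absent (violated at {x})")
    att = attractors(build_state_graph(model))
    _require(
        att.fixed_points == {(2, 0, 0, 0)}
        and att.cycles == [frozenset({(0, 2, 0, 0), (0, 3, 0, 0)})],
        name,
        "attractors must be the lysogenic fixed point and the lytic 2-cycle",
    )


_INTEGRITY_CHECKS = {
    "example_2_1_1": _check_example,
    "p53_mdm2": _check_p53,
    "phage_lambda": _check_lambda,
}


def random_model(
    n_vars: int | None = None,
    cardinalities: Sequence[int] | None = None,
    seed: int | None = None,
    propensity_range: tuple = (0.0, 1.0),
) -> SDDSModel:
    """Uniformly random truth tables with propensities drawn uniformly
    from ``propensity_range``; reproducible from ``seed``."""
    if cardinalities is None:
        if n_vars is None:
            raise ValueError("give n_vars or cardinalities")
        cardinalities = (2,) * n_vars
    cardinalities = tuple(int(c) for c in cardinalities)
    n = len(cardinalities)
    space = StateSpace(tuple(f"x{i + 1}" for i in range(n)), cardinalities)
    rng = np.random.default_rng(seed)
    rules = tuple(
        UpdateRule(
            target=i,
            inputs=tuple(range(n)),
            table=rng.integers(0, cardinalities[i], size=space.total_states),
        )
        for i in range(n)
    )
    lo, hi = propensity_range
    props = tuple(
        PropensityPair(*(lo + (hi - lo) * rng.random(2))) for _ in range(n)
    )
    return SDDSModel(space, rules, props, name=f"random(seed={seed})")
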