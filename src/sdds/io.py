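"""Reading and writing SDDS model files.

Two dialects are supported:

``json``
    ``{"variables": [{"name": "P", "levels": 3}, ...],
    "rules": {"P": "<expression>" | "@tablename" | {"inputs": [...],
    "table": [...]}}, "tables": {...}, "propensities": {"P": {"up": .9,
    "down": .9}}}``.  Named tables and inline tables are arrays in
    row-major order (first input slowest); ``@name`` references read the
    whole variable ordering as inputs.  Optional keys ``name``, ``init``
    and ``description`` are carried through untouched.

``tsv``
    A flat truth table: ``#``-prefixed header lines declare variables and
    propensities, then a header row of variable names plus one ``f.<var>``
    column per variable, and one row per state of X in lexicographic
    order (variable 1 slowest).

All probabilities are serialized as decimals.  ``parse_model(write_model(m))``
is extensionally equal to ``m`` (same truth tables, same propensities).
"""

from __future__ import annotations

import itertools
import json
import math
from typing import Sequence

import numpy as np

from .expr import parse_rule_expression
from .model import (
    ModelValidationError,
    PropensityPair,
    SDDSModel,
    StateSpace,
    UpdateRule,
)

__all__ = ["parse_model", "write_model", "ModelParseError"]


class ModelParseError(ValueError):
    """Model file text does not conform to the dialect grammar."""


def parse_model(text: str, dialect: str = "json") -> SDDSModel:
    if dialect == "json":
        return _parse_json(text)
    if dialect in ("tsv", "truth-table-tsv"):
        return _parse_tsv(text)
    raise ModelParseError(f"unknown dialect {dialect!r}; use 'json' or 'tsv'")


def write_model(model: SDDSModel, dialect: str = "json") -> str:
    if dialect == "json":
        return _write_json(model)
    if dialect in ("tsv", "truth-table-tsv"):
        return _write_tsv(model)
    raise ModelParseError(f"unknown dialect {dialect!r}; use 'json' or 'tsv'")


# ---------------------------------------------------------------- JSON


def _parse_json(text: str) -> SDDSModel:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelParseError(f"malformed JSON at line {exc.lineno}: {exc.msg}") from None
    if not isinstance(doc, dict):
        raise ModelParseError("model document must be a JSON object")

    variables = doc.get("variables")
    if not isinstance(variables, list) or not variables:
        raise ModelParseError("missing or empty 'variables' list")
    names, cards = [], []
    for entry in variables:
        if not isinstance(entry, dict) or "name" not in entry or "levels" not in entry:
            raise ModelParseError(
                f"each variable needs 'name' and 'levels', got {entry!r}"
            )
        names.append(str(entry["name"]))
        cards.append(int(entry["levels"]))
    try:
        space = StateSpace(tuple(names), tuple(cards))
    except ModelValidationError as exc:
        raise ModelParseError(str(exc)) from None

    rules_doc = doc.get("rules")
    if not isinstance(rules_doc, dict):
        raise ModelParseError("missing 'rules' object")
    tables_doc = doc.get("tables", {})
    rules = []
    for i, name in enumerate(space.names):
        if name not in rules_doc:
            raise ModelParseError(f"missing rule for variable {name!r}")
        rules.append(_parse_json_rule(name, i, rules_doc[name], tables_doc, space))

    props_doc = doc.get("propensities")
    if not isinstance(props_doc, dict):
        raise ModelParseError("missing 'propensities' object")
    props = []
    for name in space.names:
        if name not in props_doc:
            raise ModelValidationError(f"missing propensity pair for variable {name!r}")
        pd = props_doc[name]
        if not isinstance(pd, dict) or "up" not in pd or "down" not in pd:
            raise ModelParseError(
                f"propensities for {name!r} need 'up' and 'down' fields"
            )
        props.append(PropensityPair(pd["up"], pd["down"]))

    return SDDSModel(space, tuple(rules), tuple(props), name=doc.get("name"))


def _parse_json_rule(name, target, spec, tables_doc, space) -> UpdateRule:
    if isinstance(spec, str) and spec.startswith("@"):
        ref = spec[1:]
        if ref not in tables_doc:
            raise ModelParseError(f"rule for {name!r} references unknown table {ref!r}")
        table = np.asarray(tables_doc[ref], dtype=np.int64)
        rule = UpdateRule(target=target, inputs=tuple(range(space.n)), table=table)
        rule.validate(space)
        return rule
    if isinstance(spec, str):
        return parse_rule_expression(spec, target, space)
    if isinstance(spec, dict) and "table" in spec:
        input_names = spec.get("inputs")
        if input_names is None:
            inputs = tuple(range(space.n))
        else:
            inputs = tuple(space.variable_index(nm) for nm in input_names)
        rule = UpdateRule(
            target=target,
            inputs=inputs,
            table=np.asarray(spec["table"], dtype=np.int64),
            expr=spec.get("expr"),
        )
        rule.validate(space)
        return rule
    raise ModelParseError(
        f"rule for {name!r} must be an expression string, '@table' reference, "
        f"or an object with 'inputs' and 'table'"
    )


def _write_json(model: SDDSModel) -> str:
    space = model.space
    doc = {
        "variables": [
            {"name": nm, "levels": card}
            for nm, card in zip(space.names, space.cardinalities)
        ],
        "rules": {},
        "propensities": {},
    }
    if model.name:
        doc["name"] = model.name
    for rule in model.rules:
        entry = {
            "inputs": [space.names[i] for i in rule.inputs],
            "table": [int(v) for v in rule.table],
        }
        if rule.expr:
            entry["expr"] = rule.expr
        doc["rules"][space.names[rule.target]] = entry
    for nm, pp in zip(space.names, model.propensities):
        doc["propensities"][nm] = {"up": pp.up, "down": pp.down}
    return json.dumps(doc, indent=1)


# ----------------------------------------------------------------- TSV


def _parse_tsv(text: str) -> SDDSModel:
    names, cards = [], []
    props = {}
    body = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            fields = line[1:].strip().split("\t")
            if fields[0] == "variable":
                if len(fields) != 3:
                    raise ModelParseError(f"line {lineno}: bad variable declaration")
                names.append(fields[1])
                cards.append(int(fields[2]))
            elif fields[0] == "propensity":
                if len(fields) != 4:
                    raise ModelParseError(f"line {lineno}: bad propensity declaration")
                props[fields[1]] = PropensityPair(float(fields[2]), float(fields[3]))
            # other comment lines are ignored
        else:
            body.append((lineno, line.split("\t")))
    if not names:
        raise ModelParseError("no '# variable' declarations found")
    try:
        space = StateSpace(tuple(names), tuple(cards))
    except ModelValidationError as exc:
        raise ModelParseError(str(exc)) from None

    if not body:
        raise ModelParseError("no truth-table rows found")
    header = body[0][1]
    expected_header = list(space.names) + [f"f.{nm}" for nm in space.names]
    if header != expected_header:
        raise ModelParseError(
            f"line {body[0][0]}: header {header!r} does not match {expected_header!r}"
        )
    rows = body[1:]
    if len(rows) != space.total_states:
        raise ModelParseError(
            f"{len(rows)} truth-table rows for {space.total_states} states"
        )
    tables = np.empty((space.total_states, space.n), dtype=np.int64)
    for (lineno, fields), state in zip(rows, space.states()):
        if len(fields) != 2 * space.n:
            raise ModelParseError(f"line {lineno}: expected {2 * space.n} columns")
        try:
            values = [int(v) for v in fields]
        except ValueError:
            raise ModelParseError(f"line {lineno}: non-integer table entry") from None
        if tuple(values[: space.n]) != state:
            raise ModelParseError(
                f"line {lineno}: states must appear in lexicographic order; "
                f"expected {state}, got {tuple(values[: space.n])}"
            )
        tables[space.index(state)] = values[space.n :]

    rules = []
    for i in range(space.n):
        rule = UpdateRule(target=i, inputs=tuple(range(space.n)), table=tables[:, i])
        rule.validate(space)
        rules.append(rule)
    prop_list = []
    for nm in space.names:
        if nm not in props:
            raise ModelValidationError(f"missing propensity pair for variable {nm!r}")
        prop_list.append(props[nm])
    return SDDSModel(space, tuple(rules), tuple(prop_list))


def _write_tsv(model: SDDSModel) -> str:
    space = model.space
    lines = ["# sdds-model"]
    for nm, card in zip(space.names, space.cardinalities):
        lines.append(f"# variable\t{nm}\t{card}")
    for nm, pp in zip(space.names, model.propensities):
        lines.append(f"# propensity\t{nm}\t{pp.up!r}\t{pp.down!r}")
    lines.append("\t".join(list(space.names) + [f"f.{nm}" for nm in space.names]))
    for state in space.states():
        image = model.image(state)
        lines.append("\t".join(str(v) for v in (*state, *image)))
    return "\n".join(lines) + "\n"
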