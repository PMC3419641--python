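"""Rule expression language.

Expressions are a convenience layer over truth tables; they are expanded
exhaustively at parse time.  The grammar is a small arithmetic/logical
subset of Python syntax:

* integer constants and variable names;
* ``+``, ``-``, ``*`` and unary ``-``;
* comparisons ``== != < <= > >=`` yielding 0/1 (useful as thresholds);
* ``min(...)`` and ``max(...)`` with two or more arguments, which double
  as AND/OR on 0/1 values;
* ``not(v)`` for a variable name ``v``: the level complement
  ``card(v) - 1 - v``;
* conditional expressions ``a if cond else b`` (``cond`` true when
  nonzero).

Every expression is total by construction; the expanded table is
validated against the target variable's levels by the caller.
"""

from __future__ import annotations

import ast
import itertools
import operator
from typing import Sequence

import numpy as np

from .model import ModelValidationError, StateSpace, UpdateRule

__all__ = ["parse_rule_expression", "ExpressionError"]


class ExpressionError(ModelValidationError):
    """An update-rule expression does not conform to the grammar."""


_BINOPS = {ast.Add: operator.add, ast.Sub: operator.sub, ast.Mult: operator.mul}
_CMPOPS = {
    ast.Eq: operator.eq,
    ast.NotEq: operator.ne,
    ast.Lt: operator.lt,
    ast.LtE: operator.le,
    ast.Gt: operator.gt,
    ast.GtE: operator.ge,
}


def _collect_names(node: ast.AST) -> list:
    """Variable names referenced by an expression (call names excluded)."""
    skip = {
        id(sub.func)
        for sub in ast.walk(node)
        if isinstance(sub, ast.Call) and isinstance(sub.func, ast.Name)
    }
    return [
        sub.id
        for sub in ast.walk(node)
        if isinstance(sub, ast.Name) and id(sub) not in skip
    ]


class _Evaluator:
    def __init__(self, space: StateSpace, env: dict):
        self.space = space
        self.env = env

    def eval(self, node: ast.AST) -> int:
        if isinstance(node, ast.Expression):
            return self.eval(node.body)
        if isinstance(node, ast.Constant):
            if not isinstance(node.value, int) or isinstance(node.value, bool):
                raise ExpressionError(f"only integer constants allowed, got {node.value!r}")
            return node.value
        if isinstance(node, ast.Name):
            if node.id not in self.env:
                raise ExpressionError(f"unknown variable {node.id!r} in expression")
            return self.env[node.id]
        if isinstance(node, ast.BinOp) and type(node.op) in _BINOPS:
            return _BINOPS[type(node.op)](self.eval(node.left), self.eval(node.right))
        if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.USub):
            return -self.eval(node.operand)
        if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.Not):
            # not(v): level complement card(v) - 1 - v of a variable
            if not isinstance(node.operand, ast.Name):
                raise ExpressionError("not() takes a single variable name")
            var = node.operand.id
            if var not in self.env:
                raise ExpressionError(f"unknown variable {var!r} in expression")
            card = self.space.cardinalities[self.space.variable_index(var)]
            return card - 1 - self.env[var]
        if isinstance(node, ast.Compare):
            left = self.eval(node.left)
            result = 1
            for op, comp in zip(node.ops, node.comparators):
                if type(op) not in _CMPOPS:
                    raise ExpressionError(f"comparison {ast.dump(op)} not supported")
                right = self.eval(comp)
                result = result and int(_CMPOPS[type(op)](left, right))
                left = right
            return int(result)
        if isinstance(node, ast.IfExp):
            return self.eval(node.body) if self.eval(node.test) != 0 else self.eval(node.orelse)
        if isinstance(node, ast.Call):
            if not isinstance(node.func, ast.Name) or node.keywords:
                raise ExpressionError("only plain min/max/not calls are allowed")
            fname = node.func.id
            if fname in ("min", "max"):
                if len(node.args) < 2:
                    raise ExpressionError(f"{fname}() needs at least two arguments")
                vals = [self.eval(a) for a in node.args]
                return min(vals) if fname == "min" else max(vals)
            raise ExpressionError(f"unknown function {fname!r}")
        raise ExpressionError(f"unsupported syntax: {ast.dump(node)}")


def parse_rule_expression(expr: str, target: int, space: StateSpace) -> UpdateRule:
    """Expand an expression into a truth table over the variables it reads."""
    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(f"cannot parse expression {expr!r}: {exc.msg}") from None
    names = _collect_names(tree)
    for nm in names:
        if nm not in space.names:
            raise ExpressionError(f"unknown variable {nm!r} in expression {expr!r}")
    inputs = tuple(sorted({space.variable_index(nm) for nm in names}))
    cards = [space.cardinalities[i] for i in inputs]
    table = np.empty(int(np.prod(cards)) if inputs else 1, dtype=np.int64)
    for row, combo in enumerate(itertools.product(*(range(c) for c in cards))):
        env = {space.names[i]: v for i, v in zip(inputs, combo)}
        table[row] = _Evaluator(space, env).eval(tree)
    rule = UpdateRule(target=target, inputs=inputs, table=table, expr=expr)
    rule.validate(space)
    return rule
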