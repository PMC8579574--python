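"""Tiny safe arithmetic-expression engine for index formulas.

Formulas are data, not code: each discrimination index ships as a string over
the CBC field names, parsed once into an AST restricted to
+ - * / ** unary minus, abs(), numeric constants, and comparison terms
(``a < b`` evaluating to 1.0/0.0, used by composite scores that count
component tests).  Anything else is rejected at parse time.
"""

from __future__ import annotations

import ast
import math

FIELD_NAMES = (
    "hb", "hct", "mcv", "mch", "mchc", "rbc", "rdw",
    "hba2", "ferritin", "serum_iron", "tibc",
)

_BINOPS = {
    ast.Add: lambda a, b: a + b,
    ast.Sub: lambda a, b: a - b,
    ast.Mult: lambda a, b: a * b,
    ast.Div: lambda a, b: a / b,
    ast.Pow: lambda a, b: a ** b,
}
_CMPOPS = {
    ast.Lt: lambda a, b: a < b,
    ast.LtE: lambda a, b: a <= b,
    ast.Gt: lambda a, b: a > b,
    ast.GtE: lambda a, b: a >= b,
}


class ExpressionError(ValueError):
    """Malformed or disallowed formula text."""


class EvaluationError(ValueError):
    """Formula could not be evaluated on a record (names the field/cause)."""


def _validate(node: ast.AST, found: set[str]) -> None:
    if isinstance(node, ast.Expression):
        _validate(node.body, found)
    elif isinstance(node, ast.BinOp) and type(node.op) in _BINOPS:
        _validate(node.left, found)
        _validate(node.right, found)
    elif isinstance(node, ast.UnaryOp) and isinstance(node.op, (ast.USub, ast.UAdd)):
        _validate(node.operand, found)
    elif isinstance(node, ast.Constant):
        if not isinstance(node.value, (int, float)):
            raise ExpressionError(f"non-numeric constant {node.value!r}")
    elif isinstance(node, ast.Name):
        if node.id not in FIELD_NAMES:
            raise ExpressionError(f"unknown field {node.id!r}")
        found.add(node.id)
    elif isinstance(node, ast.Call):
        if not (isinstance(node.func, ast.Name) and node.func.id == "abs"):
            raise ExpressionError("only abs() calls are allowed")
        if len(node.args) != 1 or node.keywords:
            raise ExpressionError("abs() takes exactly one argument")
        _validate(node.args[0], found)
    elif isinstance(node, ast.Compare):
        if len(node.ops) != 1 or type(node.ops[0]) not in _CMPOPS:
            raise ExpressionError("only single <, <=, >, >= comparisons allowed")
        _validate(node.left, found)
        _validate(node.comparators[0], found)
    else:
        raise ExpressionError(f"disallowed syntax: {type(node).__name__}")


def _eval(node: ast.AST, values: dict) -> float:
    if isinstance(node, ast.Expression):
        return _eval(node.body, values)
    if isinstance(node, ast.BinOp):
        left = _eval(node.left, values)
        right = _eval(node.right, values)
        try:
            return _BINOPS[type(node.op)](left, right)
        except ZeroDivisionError:
            raise EvaluationError("division by zero") from None
    if isinstance(node, ast.UnaryOp):
        operand = _eval(node.operand, values)
        return -operand if isinstance(node.op, ast.USub) else operand
    if isinstance(node, ast.Constant):
        return float(node.value)
    if isinstance(node, ast.Name):
        value = values.get(node.id)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise EvaluationError(f"missing field '{node.id}'")
        return float(value)
    if isinstance(node, ast.Call):
        return abs(_eval(node.args[0], values))
    if isinstance(node, ast.Compare):
        ok = _CMPOPS[type(node.ops[0])](
            _eval(node.left, values), _eval(node.comparators[0], values)
        )
        return 1.0 if ok else 0.0
    raise ExpressionError(f"disallowed syntax: {type(node).__name__}")  # pragma: no cover


class Expression:
    """A compiled formula; callable on a dict of field values."""

    def __init__(self, text: str):
        try:
            tree = ast.parse(text, mode="eval")
        except SyntaxError as exc:
            raise ExpressionError(f"cannot parse {text!r}: {exc}") from None
        found: set[str] = set()
        _validate(tree, found)
        self.text = text
        self.fields = frozenset(found)
        self._tree = tree

    def __call__(self, values: dict) -> float:
        result = _eval(self._tree, values)
        if math.isnan(result) or math.isinf(result):
            raise EvaluationError(f"non-finite result from {self.text!r}")
        return result

    def __repr__(self) -> str:  # pragma: no cover
        return f"Expression({self.text!r})"
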