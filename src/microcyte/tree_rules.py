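"""Decision-rule classifiers over CBC fields.

Three layers:

* a generic rule engine — an ordered list of conjunctive threshold paths
  (field <= t / field > t) mapping a record to IDA or BTT, with a
  region-enumeration audit proving the paths are mutually exclusive and
  jointly exhaustive;
* the published six-leaf rule set on MCV, Hb and MCHC extracted by an
  unbiased-split classification tree (CRUISE) on the reference cohort,
  shipped both in code and as ``data/cruise.json``;
* a deliberately simple greedy Gini tree fitter, so the full pipeline can be
  exercised end to end and variable importances demonstrated without any of
  the specialised tree packages.  It is a demonstrator, not a
  reimplementation of those algorithms.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import BTT, IDA, PatientRecord

__all__ = [
    "SplitCondition",
    "RulePath",
    "RuleSet",
    "FittedTree",
    "TreeNode",
    "cruise_ruleset",
    "predict_ruleset",
    "audit_ruleset",
    "fit_greedy_tree",
    "variable_importance",
    "tree_to_ruleset",
    "load_ruleset",
    "save_ruleset",
    "RuleSetError",
]

LE = "<="
GT = ">"


class RuleSetError(ValueError):
    """Invalid rule set (overlapping or non-exhaustive paths) or bad input."""


@dataclass(frozen=True)
class SplitCondition:
    field: str
    op: str  # "<=" or ">"
    threshold: float

    def __post_init__(self):
        if self.op not in (LE, GT):
            raise ValueError(f"op must be '<=' or '>', got {self.op!r}")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def holds(self, value: float) -> bool:
        return value <= self.threshold if self.op == LE else value > self.threshold

    def __str__(self) -> str:
        return f"{self.field} {self.op} {self.threshold:g}"


@dataclass(frozen=True)
class RulePath:
    conditions: tuple[SplitCondition, ...]
    label: str

    def matches(self, values: Mapping[str, float]) -> bool:
        return all(c.holds(values[c.field]) for c in self.conditions)


@dataclass(frozen=True)
class RuleSet:
    name: str
    paths: tuple[RulePath, ...]

    @property
    def fields(self) -> tuple[str, ...]:
        seen: list[str] = []
        for path in self.paths:
            for cond in path.conditions:
                if cond.field not in seen:
                    seen.append(cond.field)
        return tuple(seen)


def _cond(field: str, op: str, threshold: float) -> SplitCondition:
    return SplitCondition(field, op, threshold)


def cruise_ruleset() -> RuleSet:
    """The published six-leaf CRUISE rule set on MCV (fL), Hb (g/dL), MCHC (g/dL).

    BTT regions: MCV > 71.25; 67.65 < MCV <= 71.25 with Hb <= 11.15; and
    MCV <= 67.65 with Hb <= 8.85 and MCHC <= 30.32.  The complementary three
    regions are IDA.
    """
    paths = (
        RulePath((_cond("mcv", GT, 71.25),), BTT),
        RulePath((_cond("mcv", GT, 67.65), _cond("mcv", LE, 71.25),
                  _cond("hb", LE, 11.15)), BTT),
        RulePath((_cond("mcv", GT, 67.65), _cond("mcv", LE, 71.25),
                  _cond("hb", GT, 11.15)), IDA),
        RulePath((_cond("mcv", LE, 67.65), _cond("hb", GT, 8.85)), IDA),
        RulePath((_cond("mcv", LE, 67.65), _cond("hb", LE, 8.85),
                  _cond("mchc", LE, 30.32)), BTT),
        RulePath((_cond("mcv", LE, 67.65), _cond("hb", LE, 8.85),
                  _cond("mchc", GT, 30.32)), IDA),
    )
    return RuleSet("CRUISE", paths)


def _record_values(rules: RuleSet, record: PatientRecord | Mapping[str, float]) -> dict:
    values = record.as_dict() if isinstance(record, PatientRecord) else dict(record)
    for name in rules.fields:
        value = values.get(name)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise RuleSetError(f"missing field '{name}' required by rule set")
    return values


def predict_ruleset(rules: RuleSet, record: PatientRecord | Mapping[str, float]) -> str:
    """Classify one record; exactly one path must match."""
    values = _record_values(rules, record)
    matches = [p for p in rules.paths if p.matches(values)]
    if len(matches) != 1:
        raise RuleSetError(
            f"rule set {rules.name!r} matched {len(matches)} paths "
            f"(must be exactly 1): inconsistent rule set"
        )
    return matches[0].label


def audit_ruleset(rules: RuleSet) -> dict:
    """Prove exclusivity/exhaustiveness by enumerating all threshold regions.

    The thresholds appearing in the rule set partition each field's axis into
    intervals; one probe value per interval (each threshold itself, the
    midpoints, and a point above the maximum) hits every region of the
    induced grid.  A valid rule set matches exactly one path everywhere.
    """
    probes: dict[str, list[float]] = {}
    for name in rules.fields:
        thresholds = sorted(
            {c.threshold for p in rules.paths for c in p.conditions if c.field == name}
        )
        pts = list(thresholds)
        pts.extend(
            (a + b) / 2 for a, b in zip(thresholds, thresholds[1:])
        )
        pts.append(thresholds[-1] + 1.0)
        probes[name] = sorted(pts)
    exclusive = True
    exhaustive = True
    names = list(probes)
    for combo in itertools.product(*(probes[n] for n in names)):
        values = dict(zip(names, combo))
        n_match = sum(p.matches(values) for p in rules.paths)
        if n_match > 1:
            exclusive = False
        if n_match == 0:
            exhaustive = False
    return {
        "exclusive": exclusive,
        "exhaustive": exhaustive,
        "leaf_count": len(rules.paths),
    }


# ---------------------------------------------------------------------------
# JSON interface

def save_ruleset(rules: RuleSet, path) -> None:
    raw = {
        "name": rules.name,
        "paths": [
            {
                "conditions": [
                    {"field": c.field, "op": c.op, "threshold": c.threshold}
                    for c in p.conditions
                ],
                "label": p.label,
            }
            for p in rules.paths
        ],
    }
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(raw, handle, indent=2)
        handle.write("\n")


def _parse_ruleset(raw: dict) -> RuleSet:
    paths = tuple(
        RulePath(
            tuple(
                SplitCondition(c["field"], c["op"], float(c["threshold"]))
                for c in p["conditions"]
            ),
            p["label"],
        )
        for p in raw["paths"]
    )
    return RuleSet(raw["name"], paths)


def load_ruleset(path) -> RuleSet:
    with open(path, encoding="utf-8") as handle:
        return _parse_ruleset(json.load(handle))


def builtin_cruise_json() -> RuleSet:
    """The shipped cruise.json (identical to :func:`cruise_ruleset`)."""
    text = resources.files("microcyte.data").joinpath("cruise.json").read_text("utf-8")
    return _parse_ruleset(json.loads(text))


# ---------------------------------------------------------------------------
# Greedy Gini tree (demonstrative fitter)

@dataclass
class TreeNode:
    """Internal node (condition set, children) or leaf (label)."""

    label: str | None = None
    condition: SplitCondition | None = None
    left: "TreeNode | None" = None   # condition holds (field <= threshold)
    right: "TreeNode | None" = None  # field > threshold
    impurity_decrease: float = 0.0   # weighted by the node's sample fraction
    n: int = 0


@dataclass
class FittedTree:
    root: TreeNode
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]

    def predict_one(self, values: Mapping[str, float]) -> str:
        node = self.root
        while node.label is None:
            value = values[node.condition.field]
            node = node.left if node.condition.holds(value) else node.right
        return node.label

    def predict(self, X: pd.DataFrame) -> list[str]:
        return [self.predict_one(row) for row in X.to_dict("records")]

    def depth(self) -> int:
        def _d(node):
            if node.label is not None:
                return 0
            return 1 + max(_d(node.left), _d(node.right))
        return _d(self.root)


def _gini(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts / total
    return float(1.0 - (p ** 2).sum())


def _best_split(X: pd.DataFrame, y_codes: np.ndarray, n_classes: int,
                min_leaf: int) -> tuple[str, float, float] | None:
    """Best (field, threshold, weighted impurity decrease), ties broken by
    lowest field name then lowest threshold; None when no split strictly
    decreases impurity."""
    n = len(y_codes)
    parent_counts = np.bincount(y_codes, minlength=n_classes)
    parent_gini = _gini(parent_counts)
    best: tuple[str, float, float] | None = None
    for name in sorted(X.columns):
        x = X[name].to_numpy(dtype=float)
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y_codes[order]
        # one-hot cumulative class counts along the sorted axis
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), ys] = 1.0
        left_counts = np.cumsum(onehot, axis=0)
        distinct = np.nonzero(np.diff(xs) > 0)[0]  # split after position i
        for i in distinct:
            n_left = i + 1
            n_right = n - n_left
            if n_left < min_leaf or n_right < min_leaf:
                continue
            lc = left_counts[i]
            rc = parent_counts - lc
            decrease = parent_gini - (
                n_left / n * _gini(lc) + n_right / n * _gini(rc)
            )
            if decrease <= 1e-12:
                continue
            threshold = (xs[i] + xs[i + 1]) / 2.0
            candidate = (name, threshold, decrease)
            if best is None or decrease > best[2] + 1e-12:
                best = candidate
            # equal decrease: earlier (lower) field name wins via loop order,
            # and within a field the lower threshold wins via scan order
    return best


def fit_greedy_tree(
    cohort: Sequence[PatientRecord] | pd.DataFrame,
    labels: Sequence[str] | None = None,
    *,
    features: Sequence[str] | None = None,
    max_depth: int = 5,
    min_leaf: int = 1,
) -> FittedTree:
    """Fit an axis-aligned binary classification tree by exhaustive greedy
    Gini search over midpoint thresholds.

    Deterministic: candidate thresholds are midpoints between consecutive
    distinct sorted values; ties in impurity decrease are broken by the
    lexicographically lowest field name, then the lowest threshold.  A node
    becomes a leaf when pure, at depth limit, or when no split strictly
    decreases weighted Gini impurity.
    """
    if isinstance(cohort, pd.DataFrame):
        X = cohort.copy()
        if labels is None:
            raise ValueError("labels required with a DataFrame input")
        y = list(labels)
    else:
        if len(cohort) == 0:
            raise ValueError("empty cohort")
        from .cohort import CBC_FIELDS

        features = tuple(features or CBC_FIELDS)
        X = pd.DataFrame([{f: getattr(r, f) for f in features} for r in cohort])
        y = [r.label for r in cohort] if labels is None else list(labels)
    if len(X) == 0:
        raise ValueError("empty cohort")
    classes = tuple(sorted(set(y)))
    if len(classes) < 2:
        raise ValueError("need at least two classes to fit a tree")
    class_to_code = {c: i for i, c in enumerate(classes)}
    y_codes = np.array([class_to_code[v] for v in y])
    n_total = len(y_codes)

    def grow(rows: np.ndarray, depth: int) -> TreeNode:
        codes = y_codes[rows]
        counts = np.bincount(codes, minlength=len(classes))
        majority = classes[int(np.argmax(counts))]  # tie -> lowest class name
        node = TreeNode(n=len(rows))
        if depth >= max_depth or counts.max() == len(rows):
            node.label = majority
            return node
        found = _best_split(X.iloc[rows], codes, len(classes), min_leaf)
        if found is None:
            node.label = majority
            return node
        name, threshold, decrease = found
        mask = X.iloc[rows][name].to_numpy(dtype=float) <= threshold
        node.condition = SplitCondition(name, LE, threshold)
        node.impurity_decrease = decrease * len(rows) / n_total
        node.left = grow(rows[mask], depth + 1)
        node.right = grow(rows[~mask], depth + 1)
        return node

    root = grow(np.arange(n_total), 0)
    return FittedTree(root, tuple(X.columns), classes)


def variable_importance(tree: FittedTree) -> dict[str, float]:
    """Summed weighted impurity decrease per field, scaled so max = 100.

    Fields the tree never splits on get 0; a single-leaf tree is all zeros.
    """
    totals = {name: 0.0 for name in tree.feature_names}

    def walk(node: TreeNode) -> None:
        if node.label is not None:
            return
        totals[node.condition.field] += node.impurity_decrease
        walk(node.left)
        walk(node.right)

    walk(tree.root)
    top = max(totals.values())
    if top <= 0:
        return {name: 0.0 for name in totals}
    return {name: 100.0 * v / top for name, v in totals.items()}


def tree_to_ruleset(tree: FittedTree, name: str = "fitted") -> RuleSet:
    """Flatten a fitted tree into an equivalent conjunctive rule set."""
    paths: list[RulePath] = []

    def walk(node: TreeNode, conditions: tuple[SplitCondition, ...]) -> None:
        if node.label is not None:
            paths.append(RulePath(conditions, node.label))
            return
        c = node.condition
        walk(node.left, conditions + (SplitCondition(c.field, LE, c.threshold),))
        walk(node.right, conditions + (SplitCondition(c.field, GT, c.threshold),))

    walk(tree.root, ())
    return RuleSet(name, tuple(paths))
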