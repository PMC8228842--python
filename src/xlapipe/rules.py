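"""Production rules and decision-tree-to-rule compilation.

A rule is an ordered conjunction of attribute conditions with a severity
conclusion.  Compiling a decision tree emits one rule per root-to-leaf path,
with same-attribute conditions merged into a single interval.  Numeric
conditions follow the package-wide split convention: ``lt`` is strict
(``value < bound``), ``ge`` is inclusive, and intervals are closed-open
``[low, high)``, so a compiled rule set tiles the attribute space exactly.

Rule sets serialize to canonical JSON (lossless round trip) and to
CLIPS-style ``defrule`` text; the parser accepts both dialects but for CLIPS
only the subset this compiler emits.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping

from .trees import DecisionTree

NEG_INF = float("-inf")
POS_INF = float("inf")

_OPS = ("lt", "ge", "interval", "eq")


@dataclass(frozen=True)
class Condition:
    """One attribute test: ``lt`` (<), ``ge`` (>=), ``interval`` [low, high),
    or ``eq`` for label-valued attributes."""

    attribute: str
    op: str
    bound: float | tuple[float, float] | str

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"unknown operator {self.op!r}; expected one of {_OPS}")
        if self.op == "interval":
            low, high = self.bound
            if not low < high:
                raise ValueError(
                    f"malformed interval ({low}, {high}): low must be < high"
                )
            object.__setattr__(self, "bound", (float(low), float(high)))
        elif self.op in ("lt", "ge"):
            object.__setattr__(self, "bound", float(self.bound))

    def holds(self, value: float | str) -> bool:
        if self.op == "eq":
            return value == self.bound
        v = float(value)
        if self.op == "lt":
            return v < self.bound
        if self.op == "ge":
            return v >= self.bound
        low, high = self.bound
        return low <= v < high

    def as_interval(self) -> tuple[float, float]:
        """Numeric condition as a [low, high) interval."""
        if self.op == "lt":
            return (NEG_INF, float(self.bound))
        if self.op == "ge":
            return (float(self.bound), POS_INF)
        if self.op == "interval":
            return self.bound  # type: ignore[return-value]
        raise ValueError("eq conditions have no numeric interval")


def _interval_condition(attribute: str, low: float, high: float) -> Condition:
    """Most compact condition for the region low <= value < high."""
    if low == NEG_INF and high == POS_INF:
        raise ValueError("unbounded condition carries no information")
    if low == NEG_INF:
        return Condition(attribute, "lt", high)
    if high == POS_INF:
        return Condition(attribute, "ge", low)
    return Condition(attribute, "interval", (low, high))


@dataclass(frozen=True)
class Rule:
    id: str
    conditions: tuple[Condition, ...]
    conclusion: str
    provenance: str = "manual"

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))
        # conditions on one numeric attribute must intersect
        spans: dict[str, tuple[float, float]] = {}
        for cond in self.conditions:
            if cond.op == "eq":
                continue
            low, high = cond.as_interval()
            if cond.attribute in spans:
                plow, phigh = spans[cond.attribute]
                low, high = max(low, plow), min(high, phigh)
                if not low < high:
                    raise ValueError(
                        f"rule {self.id!r}: conditions on {cond.attribute!r} "
                        "have empty intersection"
                    )
            spans[cond.attribute] = (low, high)

    def matches(self, facts: Mapping[str, float | str]) -> bool:
        return all(c.holds(facts[c.attribute]) for c in self.conditions)

    def attributes(self) -> list[str]:
        seen: list[str] = []
        for c in self.conditions:
            if c.attribute not in seen:
                seen.append(c.attribute)
        return seen


@dataclass
class RuleSet:
    """Ordered production rules plus attribute-domain metadata.

    ``domain`` maps label-valued attributes to their admissible labels; numeric
    attributes need no entry (their domain is the real line).  The
    ``exhaustive``/``mutually_exclusive`` flags are verified constructively by
    :func:`check_partition`.
    """

    rules: list[Rule]
    domain: dict[str, list[str]] = field(default_factory=dict)
    exhaustive: bool = False
    mutually_exclusive: bool = False
    name: str = ""

    def attributes(self) -> list[str]:
        seen: list[str] = []
        for rule in self.rules:
            for a in rule.attributes():
                if a not in seen:
                    seen.append(a)
        return seen

    def conclusions(self) -> list[str]:
        seen: list[str] = []
        for rule in self.rules:
            if rule.conclusion not in seen:
                seen.append(rule.conclusion)
        return seen


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------

def compile_rules(tree: DecisionTree, name: str = "") -> RuleSet:
    """One rule per root-to-leaf path, left-to-right leaf order.

    Each path's split outcomes are merged per attribute into a single
    [low, high) interval, so the compiled set partitions the attribute space:
    it is exhaustive and mutually exclusive by construction (and re-verified
    by interval arithmetic here).
    """
    rules: list[Rule] = []
    for i, (path, leaf) in enumerate(tree.paths(), start=1):
        spans: dict[str, tuple[float, float]] = {}
        order: list[str] = []
        for attribute, threshold, went_left in path:
            low, high = spans.get(attribute, (NEG_INF, POS_INF))
            if went_left:
                high = min(high, threshold)
            else:
                low = max(low, threshold)
            spans[attribute] = (low, high)
            if attribute not in order:
                order.append(attribute)
        conditions = tuple(_interval_condition(a, *spans[a]) for a in order)
        rid = f"{name}-r{i}" if name else f"r{i}"
        rules.append(Rule(rid, conditions, leaf.label, provenance=f"tree-path-{i}"))
    ruleset = RuleSet(rules, name=name or "compiled")
    ruleset.exhaustive, ruleset.mutually_exclusive = check_partition(ruleset)
    return ruleset


def _grid_points(ruleset: RuleSet) -> dict[str, list[float | str]]:
    """One probe value per cell of the threshold-induced grid, per attribute."""
    points: dict[str, list[float | str]] = {}
    for attr in ruleset.attributes():
        cuts: set[float] = set()
        labels: set[str] = set()
        for rule in ruleset.rules:
            for cond in rule.conditions:
                if cond.attribute != attr:
                    continue
                if cond.op == "eq":
                    labels.add(cond.bound)  # type: ignore[arg-type]
                else:
                    low, high = cond.as_interval()
                    cuts.update(b for b in (low, high) if math.isfinite(b))
        if labels:
            dom = ruleset.domain.get(attr)
            if dom is None:
                raise ValueError(
                    f"attribute {attr!r} has label conditions but no domain metadata"
                )
            points[attr] = list(dom)
            continue
        edges = sorted(cuts)
        if not edges:
            points[attr] = [0.0]
            continue
        probes: list[float | str] = [edges[0] - 1.0]
        for a, b in zip(edges[:-1], edges[1:]):
            probes.append((a + b) / 2.0)
        # [low, high) intervals: an edge value itself belongs to the cell above
        probes.extend(edges)
        points[attr] = probes
    return points


def check_partition(ruleset: RuleSet) -> tuple[bool, bool]:
    """(exhaustive, mutually_exclusive) by exact interval arithmetic.

    Conditions are axis-aligned with finitely many thresholds, so probing one
    representative point per cell of the refined grid decides both properties
    exactly.
    """
    if not ruleset.rules:
        return (False, True)
    attrs = ruleset.attributes()
    points = _grid_points(ruleset)
    exhaustive = True
    exclusive = True
    for combo in product(*(points[a] for a in attrs)):
        facts = dict(zip(attrs, combo))
        n = sum(1 for rule in ruleset.rules if rule.matches(facts))
        if n == 0:
            exhaustive = False
        if n > 1:
            exclusive = False
        if not exhaustive and not exclusive:
            break
    return exhaustive, exclusive


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def _condition_to_json(cond: Condition) -> dict:
    bound = list(cond.bound) if cond.op == "interval" else cond.bound
    return {"attribute": cond.attribute, "op": cond.op, "bound": bound}


def _condition_from_json(data: dict) -> Condition:
    bound = data["bound"]
    if data["op"] == "interval":
        bound = (float(bound[0]), float(bound[1]))
    return Condition(data["attribute"], data["op"], bound)


def serialize_rules(ruleset: RuleSet, dialect: str = "json") -> str:
    """Render a rule set as canonical JSON or CLIPS-style defrule text."""
    if dialect == "json":
        doc = {
            "name": ruleset.name,
            "domain": ruleset.domain,
            "exhaustive": ruleset.exhaustive,
            "mutually_exclusive": ruleset.mutually_exclusive,
            "rules": [
                {
                    "id": rule.id,
                    "conditions": [_condition_to_json(c) for c in rule.conditions],
                    "conclusion": rule.conclusion,
                    "provenance": rule.provenance,
                }
                for rule in ruleset.rules
            ],
        }
        return json.dumps(doc, indent=2) + "\n"
    if dialect == "clips":
        return _serialize_clips(ruleset)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'json' or 'clips'")


def _clips_test(cond: Condition) -> str:
    var = f"?{cond.attribute}"
    if cond.op == "lt":
        return f"(test (< {var} {cond.bound:g}))"
    if cond.op == "ge":
        return f"(test (>= {var} {cond.bound:g}))"
    if cond.op == "interval":
        low, high = cond.bound
        return f"(test (and (>= {var} {low:g}) (< {var} {high:g})))"
    return f'(test (eq {var} "{cond.bound}"))'


def _serialize_clips(ruleset: RuleSet) -> str:
    blocks: list[str] = []
    for rule in ruleset.rules:
        lines = [f'(defrule {rule.id} "{rule.provenance}"']
        for attr in rule.attributes():
            lines.append(f"    (fact (attribute {attr}) (value ?{attr}))")
        for cond in rule.conditions:
            lines.append(f"    {_clips_test(cond)}")
        lines.append("    =>")
        lines.append(f'    (assert (conclusion "{rule.conclusion}")))')
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


_DEFRULE_RE = re.compile(r'\(defrule\s+(\S+)\s+"([^"]*)"')
_TEST_RE = re.compile(
    r"\(test\s+\((?:(<|>=)\s+\?(\w+)\s+([-\d.eE+]+)"
    r"|and\s+\(>=\s+\?(\w+)\s+([-\d.eE+]+)\)\s+\(<\s+\?\w+\s+([-\d.eE+]+)\)"
    r'|eq\s+\?(\w+)\s+"([^"]*)")\)\)'
)
_CONCLUSION_RE = re.compile(r'\(assert\s+\(conclusion\s+"([^"]*)"\)\)\)')


def parse_rules(text: str, dialect: str = "json") -> RuleSet:
    """Inverse of :func:`serialize_rules` on its own output."""
    if dialect == "json":
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ValueError(f"JSON syntax error at line {exc.lineno}: {exc.msg}") from exc
        rules = [
            Rule(
                r["id"],
                tuple(_condition_from_json(c) for c in r["conditions"]),
                r["conclusion"],
                r.get("provenance", "manual"),
            )
            for r in doc["rules"]
        ]
        return RuleSet(
            rules,
            domain={k: list(v) for k, v in doc.get("domain", {}).items()},
            exhaustive=bool(doc.get("exhaustive", False)),
            mutually_exclusive=bool(doc.get("mutually_exclusive", False)),
            name=doc.get("name", ""),
        )
    if dialect == "clips":
        return _parse_clips(text)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'json' or 'clips'")


def _parse_clips(text: str) -> RuleSet:
    rules: list[Rule] = []
    blocks = [b for b in re.split(r"\n\s*\n", text) if b.strip()]
    for block in blocks:
        line_no = text[: text.index(block)].count("\n") + 1
        head = _DEFRULE_RE.search(block)
        concl = _CONCLUSION_RE.search(block)
        if head is None or concl is None:
            raise ValueError(f"CLIPS syntax error near line {line_no}: malformed defrule")
        conditions: list[Condition] = []
        for m in _TEST_RE.finditer(block):
            if m.group(1):
                op = "lt" if m.group(1) == "<" else "ge"
                conditions.append(Condition(m.group(2), op, float(m.group(3))))
            elif m.group(4):
                conditions.append(
                    Condition(m.group(4), "interval", (float(m.group(5)), float(m.group(6))))
                )
            else:
                conditions.append(Condition(m.group(7), "eq", m.group(8)))
        rules.append(Rule(head.group(1), tuple(conditions), concl.group(1), head.group(2)))
    ruleset = RuleSet(rules, name="parsed-clips")
    ruleset.exhaustive, ruleset.mutually_exclusive = check_partition(ruleset)
    return ruleset
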