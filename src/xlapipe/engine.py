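"""A small forward-chaining production system.

Working memory holds one fact per attribute; matching builds an agenda of
rules whose every condition holds, ordered by specificity (condition count)
then declaration order; a run fires the top rule once.  Conclusions are
terminal — they do not re-enter working memory — because the severity rule
sets are one level deep.  For a compiled (mutually exclusive, exhaustive)
rule set the agenda has exactly one entry, so any conflict-resolution
strategy agrees; the fixed strategy makes hand-written overlapping rule sets
predictable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .rules import Rule, RuleSet


@dataclass(frozen=True)
class Fact:
    attribute: str
    value: float | str


@dataclass
class WorkingMemory:
    """Attribute-unique fact store."""

    facts: dict[str, float | str] = field(default_factory=dict)

    @classmethod
    def from_facts(cls, facts: Iterable[Fact] | Mapping[str, float | str]) -> "WorkingMemory":
        if isinstance(facts, Mapping):
            return cls(dict(facts))
        wm = cls()
        for fact in facts:
            wm.assert_fact(fact)
        return wm

    def assert_fact(self, fact: Fact) -> None:
        if fact.attribute in self.facts and self.facts[fact.attribute] != fact.value:
            raise ValueError(
                f"conflicting fact for attribute {fact.attribute!r}: "
                f"{self.facts[fact.attribute]!r} vs {fact.value!r}"
            )
        self.facts[fact.attribute] = fact.value


@dataclass
class ConditionTrace:
    attribute: str
    op: str
    bound: object
    value: object
    satisfied: bool


@dataclass
class RuleTrace:
    rule_id: str
    satisfied: bool
    conditions: list[ConditionTrace]


@dataclass
class InferenceResult:
    conclusion: str | None
    fired: list[str]
    trace: list[RuleTrace]


class MissingFactError(KeyError):
    """Working memory lacks facts for attributes the rule set references."""

    def __init__(self, attributes: list[str]):
        self.attributes = attributes
        super().__init__(f"missing facts for attributes: {', '.join(attributes)}")


def match(ruleset: RuleSet, wm: WorkingMemory) -> list[str]:
    """Agenda of satisfied rule ids: most conditions first, then rule order."""
    missing = [a for a in ruleset.attributes() if a not in wm.facts]
    if missing:
        raise MissingFactError(missing)
    satisfied = [
        (len(rule.conditions), -i, rule.id)
        for i, rule in enumerate(ruleset.rules)
        if rule.matches(wm.facts)
    ]
    satisfied.sort(reverse=True)
    return [rid for _, _, rid in satisfied]


def _trace_rule(rule: Rule, wm: WorkingMemory) -> RuleTrace:
    conds = [
        ConditionTrace(c.attribute, c.op, c.bound, wm.facts.get(c.attribute), c.holds(wm.facts[c.attribute]))
        for c in rule.conditions
    ]
    return RuleTrace(rule.id, all(c.satisfied for c in conds), conds)


def run(ruleset: RuleSet, facts: Iterable[Fact] | Mapping[str, float | str]) -> InferenceResult:
    """Single forward-chaining cycle: match, resolve conflicts, fire once.

    An empty agenda yields conclusion ``None`` with a diagnostic trace of
    every rule's condition evaluations.
    """
    wm = WorkingMemory.from_facts(facts)
    agenda = match(ruleset, wm)
    trace = [_trace_rule(rule, wm) for rule in ruleset.rules]
    if not agenda:
        return InferenceResult(conclusion=None, fired=[], trace=trace)
    top = agenda[0]
    conclusion = next(r.conclusion for r in ruleset.rules if r.id == top)
    return InferenceResult(conclusion=conclusion, fired=[top], trace=trace)


class FactValidationError(ValueError):
    """Raised with one message per offending input field."""

    def __init__(self, messages: dict[str, str]):
        self.messages = messages
        details = "; ".join(f"{k}: {v}" for k, v in messages.items())
        super().__init__(f"invalid inputs — {details}")


#: Attributes whose facts are labels rather than numbers.
LABEL_ATTRIBUTES = {"mutation_severity", "course"}


def validate_facts(raw: Mapping[str, object]) -> list[Fact]:
    """Turn raw user inputs into facts, rejecting non-numeric or negative
    values with a per-field message.  Label-valued attributes pass through."""
    facts: list[Fact] = []
    errors: dict[str, str] = {}
    for name, value in raw.items():
        if name in LABEL_ATTRIBUTES:
            facts.append(Fact(name, str(value)))
            continue
        try:
            number = float(value)  # type: ignore[arg-type]
        except (TypeError, ValueError):
            errors[name] = f"expected a numeric value, got {value!r}"
            continue
        if number != number or number in (float("inf"), float("-inf")):
            errors[name] = f"value must be finite, got {value!r}"
        elif number < 0:
            errors[name] = f"value must be non-negative, got {value!r}"
        else:
            facts.append(Fact(name, number))
    if errors:
        raise FactValidationError(errors)
    return facts
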