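"""XLA knowledge bases: threshold catalog, rule sets, verification harness.

The published severity logic is qualitative ("IgM% is undetectable", "the age
of onset is early").  :class:`ThresholdCatalog` grounds those terms
numerically; the defaults are the unique simple grounding consistent with
every printed verification case (onset 19 and 23 months behave as early, 47
as late; IgM 12 as undetectable, 92 as detectable; IgG 19 vs 73; IgA bands
below 20, 20-50, above 50).

Six rule sets are shipped:

* ``kb1_course_ig`` — disease course from Ig percentages and onset age; the
  seven-rule set printed verbatim, compiled from its source tree.
* ``kb2_mutation_ig`` — mutation severity from Ig percentages; a five-leaf
  reconstruction of the published tree (four splits: IgM undetectable,
  IgG detectable, IgA reduced, IgM above a high cutoff).
* ``kb3_course_btk`` .. ``kb6_mutation_history`` — partial, prose-derived
  rule sets; they are not exhaustive, and facts outside their coverage yield
  conclusion ``None``.

The "extremely severe" conclusion of the printed first rule is mapped to the
label "very severe" used everywhere else, which is what the verification
table expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .engine import Fact, run
from .rules import Condition, Rule, RuleSet, compile_rules
from .trees import DecisionTree, Internal, Leaf

COURSE_LABELS = ("very severe", "severe", "less severe")
MUTATION_LABELS = ("severe", "less severe")

KB_NAMES = (
    "kb1_course_ig",
    "kb2_mutation_ig",
    "kb3_course_btk",
    "kb4_course_combined",
    "kb5_mutation_btk",
    "kb6_mutation_history",
)


@dataclass(frozen=True)
class ThresholdCatalog:
    """Numeric grounding of the qualitative rule terms.

    All values are configurable; the defaults reproduce both verification
    tables.  Units: months for ``onset_early_max``, percent of the
    age-specific norm for everything else.
    """

    onset_early_max: float = 24.0
    undetectable_pct_max: float = 20.0
    iga_low_max: float = 20.0
    iga_mid_max: float = 50.0
    btk_lib_low_max: float = 20.0
    bcells_absent_max: float = 5.0
    igm_high_min: float = 60.0

    def __post_init__(self) -> None:
        if not self.iga_low_max < self.iga_mid_max:
            raise ValueError("iga_low_max must be below iga_mid_max")
        for name in (
            "onset_early_max",
            "undetectable_pct_max",
            "iga_low_max",
            "iga_mid_max",
            "btk_lib_low_max",
            "bcells_absent_max",
            "igm_high_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_CATALOG = ThresholdCatalog()


def _leaf(label: str) -> Leaf:
    return Leaf(label, {label: 0})


def kb1_source_tree(catalog: ThresholdCatalog = DEFAULT_CATALOG) -> DecisionTree:
    """The course-from-immunoglobulins tree whose seven root-to-leaf paths
    are the published rule set."""
    u = catalog.undetectable_pct_max
    early = catalog.onset_early_max
    root = Internal(
        "igm_pct",
        u,
        Internal(  # IgM undetectable
            "age_ob",
            early,
            Internal("igg_pct", u, _leaf("very severe"), _leaf("severe"), {}),
            _leaf("severe"),
            {},
        ),
        Internal(  # IgM detectable
            "age_ob",
            early,
            Internal(
                "iga_pct",
                catalog.iga_low_max,
                _leaf("severe"),
                Internal(
                    "iga_pct",
                    catalog.iga_mid_max,
                    _leaf("less severe"),
                    _leaf("severe"),
                    {},
                ),
                {},
            ),
            _leaf("less severe"),
            {},
        ),
        {},
    )
    return DecisionTree(
        root,
        target="course",
        class_order=COURSE_LABELS,
        attributes=("igm_pct", "age_ob", "igg_pct", "iga_pct"),
    )


def kb2_source_tree(catalog: ThresholdCatalog = DEFAULT_CATALOG) -> DecisionTree:
    """Mutation severity from immunoglobulins (five-leaf reconstruction)."""
    u = catalog.undetectable_pct_max
    root = Internal(
        "igm_pct",
        u,
        _leaf("severe"),  # IgM undetectable
        Internal(
            "igg_pct",
            u,
            Internal(  # IgG undetectable
                "iga_pct",
                catalog.iga_low_max,
                _leaf("severe"),  # IgA reduced
                Internal(
                    "igm_pct",
                    catalog.igm_high_min,
                    _leaf("less severe"),
                    _leaf("severe"),
                    {},
                ),
                {},
            ),
            _leaf("less severe"),  # IgG detectable
            {},
        ),
        {},
    )
    return DecisionTree(
        root,
        target="mutation_severity",
        class_order=MUTATION_LABELS,
        attributes=("igm_pct", "igg_pct", "iga_pct"),
    )


def _kb3(catalog: ThresholdCatalog) -> RuleSet:
    rules = [
        Rule(
            "kb3-r1",
            (
                Condition("btk_lib", "lt", catalog.btk_lib_low_max),
                Condition("bcells_pct", "lt", catalog.bcells_absent_max),
            ),
            "severe",
        ),
        Rule(
            "kb3-r2",
            (
                Condition("btk_lib", "ge", catalog.btk_lib_low_max),
                Condition("bcells_pct", "ge", catalog.bcells_absent_max),
            ),
            "less severe",
        ),
    ]
    return RuleSet(rules, name="kb3_course_btk")


def _kb4(catalog: ThresholdCatalog) -> RuleSet:
    rules = [
        Rule(
            "kb4-r1",
            (
                Condition("mutation_severity", "eq", "severe"),
                Condition("severe_diseases", "ge", 1.0),
                Condition("age_ob", "lt", catalog.onset_early_max),
            ),
            "very severe",
        ),
        Rule(
            "kb4-r2",
            (
                Condition("mutation_severity", "eq", "less severe"),
                Condition("age_ob", "ge", catalog.onset_early_max),
            ),
            "less severe",
        ),
    ]
    return RuleSet(
        rules,
        domain={"mutation_severity": list(MUTATION_LABELS)},
        name="kb4_course_combined",
    )


def _kb5(catalog: ThresholdCatalog) -> RuleSet:
    rules = [
        Rule(
            "kb5-r1",
            (Condition("btk_lib", "ge", catalog.btk_lib_low_max),),
            "less severe",
        ),
        Rule(
            "kb5-r2",
            (
                Condition("btk_lib", "lt", catalog.btk_lib_low_max),
                Condition("age_ob", "ge", catalog.onset_early_max),
            ),
            "severe",
        ),
        Rule(
            "kb5-r3",
            (
                Condition("btk_lib", "lt", catalog.btk_lib_low_max),
                Condition("bcells_pct", "lt", catalog.bcells_absent_max),
            ),
            "severe",
        ),
    ]
    return RuleSet(rules, name="kb5_mutation_btk")


def _kb6(catalog: ThresholdCatalog) -> RuleSet:
    rules = [
        Rule("kb6-r1", (Condition("less_severe_diseases", "ge", 4.0),), "severe"),
        Rule(
            "kb6-r2",
            (
                Condition("less_severe_diseases", "lt", 4.0),
                Condition("pulmonology", "ge", 2.0),
            ),
            "severe",
        ),
        Rule(
            "kb6-r3",
            (
                Condition("less_severe_diseases", "lt", 2.0),
                Condition("pulmonology", "lt", 2.0),
                Condition("otorhinolaryngology", "lt", 2.0),
            ),
            "less severe",
        ),
    ]
    return RuleSet(rules, name="kb6_mutation_history")


def load_kb(name: str, catalog: ThresholdCatalog = DEFAULT_CATALOG) -> RuleSet:
    """Load one of the six shipped rule sets under a threshold catalog."""
    if name == "kb1_course_ig":
        ruleset = compile_rules(kb1_source_tree(catalog), name="kb1")
        ruleset.name = name
        return ruleset
    if name == "kb2_mutation_ig":
        ruleset = compile_rules(kb2_source_tree(catalog), name="kb2")
        ruleset.name = name
        return ruleset
    if name == "kb3_course_btk":
        return _kb3(catalog)
    if name == "kb4_course_combined":
        return _kb4(catalog)
    if name == "kb5_mutation_btk":
        return _kb5(catalog)
    if name == "kb6_mutation_history":
        return _kb6(catalog)
    raise ValueError(f"unknown knowledge base {name!r}; known: {KB_NAMES}")


# ---------------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VerificationCase:
    case_id: str
    inputs: dict[str, float]
    expected: str


@dataclass
class CaseResult:
    case: VerificationCase
    actual: str | None
    passed: bool
    fired: list[str]


@dataclass
class VerificationReport:
    kb_name: str
    results: list[CaseResult]

    @property
    def n_matched(self) -> int:
        return sum(r.passed for r in self.results)

    @property
    def n_cases(self) -> int:
        return len(self.results)

    def mismatches(self) -> list[CaseResult]:
        return [r for r in self.results if not r.passed]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row = {"case_id": r.case.case_id, **r.case.inputs}
            row.update(expected=r.case.expected, actual=r.actual, passed=r.passed)
            rows.append(row)
        return pd.DataFrame(rows)


def load_cases(table: str) -> list[VerificationCase]:
    """Shipped verification cases: ``course`` (7 cases) or ``mutation`` (5)."""
    files = {
        "course": "course_verification_cases.csv",
        "mutation": "mutation_verification_cases.csv",
    }
    if table not in files:
        raise ValueError(f"unknown case table {table!r}; known: {sorted(files)}")
    path = resources.files("xlapipe.data").joinpath(files[table])
    with resources.as_file(path) as p:
        df = pd.read_csv(p)
    cases = []
    for _, row in df.iterrows():
        inputs = {
            c: float(row[c]) for c in df.columns if c not in ("case_id", "expected")
        }
        cases.append(VerificationCase(str(row["case_id"]), inputs, row["expected"]))
    return cases


def run_verification(kb: RuleSet, cases: list[VerificationCase]) -> VerificationReport:
    """Run inference on each case and compare with the expected label.

    Mismatches are data in the report, not errors.
    """
    if not cases:
        raise ValueError("no verification cases supplied")
    results = []
    for case in cases:
        facts = [Fact(k, v) for k, v in case.inputs.items()]
        outcome = run(kb, facts)
        results.append(
            CaseResult(
                case=case,
                actual=outcome.conclusion,
                passed=outcome.conclusion == case.expected,
                fired=outcome.fired,
            )
        )
    return VerificationReport(kb.name, results)
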