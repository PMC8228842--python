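"""Seeded synthetic XLA cohorts in the raw 37-column schema.

The real 51-patient database is not published at patient level; only its
label marginals are (course: very severe 17 / severe 22 / less severe 12;
mutation: severe 28 / less severe 23).  This generator emulates it: course
labels are drawn first with exactly the configured counts, mutation labels
are allocated conditionally on course (a worse course makes a severe
mutation more likely, preserving the dependency the combined-attribute tree
exploits), and features are sampled conditionally on the labels.

Course-linked features (onset age, Ig percent-of-norm) are drawn from
truncated normals placed inside the region of one course rule of the
``kb1_course_ig`` knowledge base, so that with ``noise_level=0`` every
record satisfies the rule it was generated from and rule inference recovers
the course label exactly.  ``noise_level`` is the fraction of records whose
features are drawn from a rule with a *different* conclusion
(label-inconsistent records); labels themselves are never changed, so the
marginals stay exact.  Mutation-linked features (Btk expression, B-cell
level) separate across the Btk-expression threshold, and past-disease flag
rates rise with course severity and with mutation severity.

Raw immunoglobulin values are emitted in g/L by inverting the bundled
percent-of-norm reference table at the age of diagnosis, so preprocessing is
exercised end to end.  A configurable fraction of blanks is injected into
two numeric columns to mirror the original database's missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .kb import DEFAULT_CATALOG, ThresholdCatalog
from .preprocess import (
    DISEASE_FLAGS,
    RAW_COLUMNS,
    ReferenceRanges,
    default_reference_ranges,
    default_severe_set,
)

COURSE_ORDER = ("very severe", "severe", "less severe")
MUTATION_ORDER = ("severe", "less severe")


@dataclass(frozen=True)
class CohortConfig:
    """Study-population conditions for one synthetic cohort."""

    n_patients: int = 51
    course_counts: Mapping[str, int] = field(
        default_factory=lambda: {"very severe": 17, "severe": 22, "less severe": 12}
    )
    mutation_counts: Mapping[str, int] = field(
        default_factory=lambda: {"severe": 28, "less severe": 23}
    )
    seed: int = 0
    noise_level: float = 0.15
    missing_fraction: float = 0.10
    missing_columns: tuple[str, str] = ("b_cells", "btk_monocytes")

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if sum(self.course_counts.values()) != self.n_patients:
            raise ValueError(
                f"course counts {dict(self.course_counts)} do not sum to "
                f"n_patients={self.n_patients}"
            )
        if sum(self.mutation_counts.values()) != self.n_patients:
            raise ValueError(
                f"mutation counts {dict(self.mutation_counts)} do not sum to "
                f"n_patients={self.n_patients}"
            )
        if any(v < 0 for v in self.course_counts.values()):
            raise ValueError("course counts must be non-negative")
        if any(v < 0 for v in self.mutation_counts.values()):
            raise ValueError("mutation counts must be non-negative")
        if not 0.0 <= self.noise_level <= 1.0:
            raise ValueError("noise_level must be in [0, 1]")
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ValueError("missing_fraction must be in [0, 1]")

    @classmethod
    def from_dict(cls, doc: dict) -> "CohortConfig":
        kwargs = dict(doc)
        if "missing_columns" in kwargs:
            kwargs["missing_columns"] = tuple(kwargs["missing_columns"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# feature samplers
# ---------------------------------------------------------------------------

def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    return float(np.clip(rng.normal(mean, sd), lo, hi))


class _Samplers:
    """Band samplers keeping a safety margin away from every rule threshold."""

    def __init__(self, catalog: ThresholdCatalog):
        u = catalog.undetectable_pct_max
        early = catalog.onset_early_max
        lo_a, mid_a = catalog.iga_low_max, catalog.iga_mid_max
        btk = catalog.btk_lib_low_max
        bc = catalog.bcells_absent_max
        self.bands = {
            # the undetectable-IgM stratum is split into two sub-bands: the
            # very-severe rule region sits below the severe ones, so a grown
            # tree can carve the very-severe block with a single threshold
            ("igm_pct", "low_vs"): (0.3 * u, 2.5, 1, 0.5 * u),
            ("igm_pct", "low_s"): (0.7 * u, 2.0, 0.55 * u, 0.85 * u),
            # detectable IgM also stratifies with course (lower level, more
            # severe course), mirroring the published tree narrative
            ("igm_pct", "det_s"): (80, 6, 70, 92),
            ("igm_pct", "det_ls"): (110, 8, 97, 140),
            ("igg_pct", "low"): (0.45 * u, 1.5, 0.3 * u, 0.6 * u),
            ("igg_pct", "det"): (75, 12, 55, 110),
            ("iga_pct", "low"): (10, 4, 1, lo_a - 3),
            ("iga_pct", "mid"): ((lo_a + mid_a) / 2, 6, lo_a + 3, mid_a - 3),
            ("iga_pct", "high"): (80, 18, mid_a + 3, 140),
            ("age_ob", "early"): (10, 6, 1, early - 2),
            ("age_ob", "late"): (60, 30, early + 3, 170),
            ("btk_lib", "low"): (10, 4, 1, btk - 2),
            ("btk_lib", "high"): (50, 15, btk + 4, 95),
            # B-cell level only tends low with a severe mutation; the bands
            # overlap so Btk expression stays the primary mutation marker
            ("bcells_pct", "absent"): (3, 2, 0.2, bc + 3),
            ("bcells_pct", "present"): (9, 5, 2, 35),
        }

    def draw(self, rng: np.random.Generator, attr: str, band: str) -> float:
        return _trunc_normal(rng, *self.bands[(attr, band)])


#: Feature bands defining each course rule's region.  Keys follow the seven
#: compiled rules of kb1_course_ig, in left-to-right leaf order.  Every
#: analyte is pinned to a band (rule-constrained bands first; the remaining
#: choices keep each block cell homogeneous in its conclusion, so the rule
#: structure is recoverable by greedy tree induction at the study's sample
#: size).
_RULE_BANDS: dict[int, dict[str, str]] = {
    1: {"igm_pct": "low_vs", "age_ob": "early", "igg_pct": "low", "iga_pct": "low"},
    2: {"igm_pct": "low_s", "age_ob": "early", "igg_pct": "det", "iga_pct": "low"},
    # rule 3 leaves IgG free; drawing it low keeps IgG from coinciding with
    # the very-severe block, so IgM carries the primary split signal
    3: {"igm_pct": "low_s", "age_ob": "late", "igg_pct": "low", "iga_pct": "mid"},
    4: {"igm_pct": "det_s", "age_ob": "early", "iga_pct": "low", "igg_pct": "det"},
    5: {"igm_pct": "det_ls", "age_ob": "early", "iga_pct": "mid", "igg_pct": "det"},
    6: {"igm_pct": "det_s", "age_ob": "early", "iga_pct": "high", "igg_pct": "det"},
    7: {"igm_pct": "det_ls", "age_ob": "late", "igg_pct": "det", "iga_pct": "mid"},
}

#: Conclusion of each kb1 rule (rule 1 = "extremely severe" printed, mapped
#: to "very severe"; rules 5 and 6 swap the printed order because leaves are
#: enumerated left to right).
_RULE_CONCLUSION = {
    1: "very severe",
    2: "severe",
    3: "severe",
    4: "severe",
    5: "less severe",
    6: "severe",
    7: "less severe",
}

#: Within-course allocation of generating rules (proportions).  Chosen so
#: every rule region receives enough patients at the default n=51 for the
#: region structure to be recoverable by a tree with minsplit 8.
_RULES_PER_COURSE = {
    "very severe": {1: 1.0},
    "severe": {2: 7 / 22, 3: 9 / 22, 4: 3 / 22, 6: 3 / 22},
    "less severe": {5: 0.5, 7: 0.5},
}


#: Per-flag baseline probabilities of a past disease.
_FLAG_BASE_RATES = {
    "sepsis": 0.12,
    "meningitis": 0.10,
    "pneumonia": 0.45,
    "bronchitis": 0.30,
    "otitis": 0.40,
    "diarrhea": 0.30,
    "urti": 0.35,
    "uti": 0.08,
    "sinusitis": 0.30,
    "bronchiectasis": 0.12,
    "abscess": 0.10,
    "hemophilia_a": 0.02,
    "ascariasis": 0.05,
    "conjunctivitis": 0.20,
    "arthritis": 0.10,
    "stomatitis": 0.10,
    "furunculosis": 0.06,
    "encephalitis": 0.05,
    "guillain_barre": 0.02,
    "laryngitis": 0.10,
    "ibd": 0.04,
}

_COURSE_SEVERE_FLAG_MULT = {"very severe": 1.8, "severe": 1.0, "less severe": 0.4}
_MUTATION_FLAG_MULT = {"severe": 1.4, "less severe": 0.7}
#: Relative odds of carrying a severe mutation, by course (worse course,
#: higher odds).  At the default marginals this makes essentially every
#: very-severe-course patient carry a severe mutation, about half of the
#: severe-course patients, and almost none of the less-severe ones.
_MUTATION_WEIGHT_BY_COURSE = {"very severe": 50.0, "severe": 3.0, "less severe": 0.3}


def _largest_remainder(proportions: Mapping[int, float], total: int) -> dict[int, int]:
    quotas = {k: p * total for k, p in proportions.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    leftover = total - sum(counts.values())
    for k in sorted(quotas, key=lambda k: (quotas[k] - np.floor(quotas[k])), reverse=True)[:leftover]:
        counts[k] += 1
    return counts


def generate_cohort(
    config: CohortConfig,
    catalog: ThresholdCatalog = DEFAULT_CATALOG,
    ranges: ReferenceRanges | None = None,
    return_rules: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, np.ndarray]:
    """Generate one raw-schema cohort.  Identical config -> identical output.

    With ``return_rules=True`` also returns the id of the course rule each
    record's Ig/onset features were drawn from (the generating rule; under
    noise it may disagree with the course label).
    """
    rng = np.random.default_rng(config.seed)
    ranges = ranges if ranges is not None else default_reference_ranges()
    samplers = _Samplers(catalog)
    n = config.n_patients
    if n == 0:
        empty = pd.DataFrame(columns=list(RAW_COLUMNS))
        return (empty, np.array([], dtype=int)) if return_rules else empty

    # course labels, exact counts, shuffled order
    course = np.array(
        [lab for lab in COURSE_ORDER for _ in range(config.course_counts.get(lab, 0))],
        dtype=object,
    )
    rng.shuffle(course)

    # mutation labels: exact counts, allocated with course-dependent weights
    mutation = np.array(["less severe"] * n, dtype=object)
    n_severe = config.mutation_counts.get("severe", 0)
    if n_severe:
        weights = np.array([_MUTATION_WEIGHT_BY_COURSE[c] for c in course])
        chosen = rng.choice(n, size=n_severe, replace=False, p=weights / weights.sum())
        mutation[chosen] = "severe"

    # generating course rule per record
    gen_rule = np.zeros(n, dtype=int)
    for lab in COURSE_ORDER:
        idx = np.flatnonzero(course == lab)
        if idx.size == 0:
            continue
        alloc = _largest_remainder(_RULES_PER_COURSE[lab], idx.size)
        pool = [r for r, c in alloc.items() for _ in range(c)]
        rng.shuffle(idx)
        gen_rule[idx] = pool

    # label-inconsistent records: redraw the generating rule from a rule
    # whose conclusion differs from the course label
    if config.noise_level > 0:
        noisy = rng.random(n) < config.noise_level
        for i in np.flatnonzero(noisy):
            others = [r for r, c in _RULE_CONCLUSION.items() if c != course[i]]
            gen_rule[i] = others[rng.integers(len(others))]

    severe_set = default_severe_set()
    rows = []
    for i in range(n):
        bands = _RULE_BANDS[gen_rule[i]]
        feats = {
            attr: samplers.draw(rng, attr, bands[attr])
            for attr in ("igm_pct", "igg_pct", "iga_pct", "age_ob")
        }
        age_ob = int(round(feats["age_ob"]))
        age_dg = age_ob + int(round(_trunc_normal(rng, 8, 6, 1, 36)))

        mut = mutation[i]
        # the noise fraction also applies to mutation-linked features
        feature_mut = mut
        if config.noise_level > 0 and rng.random() < config.noise_level:
            feature_mut = "less severe" if mut == "severe" else "severe"
        mut_bands = (
            ("low", "absent") if feature_mut == "severe" else ("high", "present")
        )
        # within its mutation band, Btk expression in B cells also grades
        # with course (lower expression, more severe course)
        course_shift = {"very severe": -3.0, "severe": 0.0, "less severe": 3.0}[course[i]]
        mean, sd, lo, hi = samplers.bands[("btk_lib", mut_bands[0])]
        btk_lib = _trunc_normal(rng, mean + course_shift, sd, lo, hi)
        bcells_pct = samplers.draw(rng, "bcells_pct", mut_bands[1])
        # monocyte Btk expression tracks the mutation only weakly, so Btk in
        # B lymphocytes stays the primary mutation marker
        btk_monocytes = (
            _trunc_normal(rng, 45, 15, 5, 90)
            if feature_mut == "severe"
            else _trunc_normal(rng, 58, 15, 10, 95)
        )

        # invert percent-of-norm at the diagnosis age to get raw g/L values
        raw = {
            "igg": feats["igg_pct"] / 100.0 * ranges.reference("igg", age_dg),
            "iga": feats["iga_pct"] / 100.0 * ranges.reference("iga", age_dg),
            "igm": feats["igm_pct"] / 100.0 * ranges.reference("igm", age_dg),
            "b_cells": bcells_pct / 100.0 * ranges.reference("b_cells", age_dg),
        }

        flags = {}
        for flag in DISEASE_FLAGS:
            p = _FLAG_BASE_RATES[flag] * _MUTATION_FLAG_MULT[feature_mut]
            if flag in severe_set:
                p *= _COURSE_SEVERE_FLAG_MULT[course[i]]
            flags[flag] = "yes" if rng.random() < min(p, 0.95) else ""

        rows.append(
            {
                "age_of_onset": age_ob,
                "age_of_dg": age_dg,
                "igg": raw["igg"],
                "iga": raw["iga"],
                "igm": raw["igm"],
                "b_cells": raw["b_cells"],
                "btk_monocytes": btk_monocytes,
                "btk_lib": btk_lib,
                "family_history": "present" if rng.random() < 0.2 else "",
                **flags,
                "mutation": mut,
                "xla": course[i],
                "exon": f"exon {rng.integers(2, 19)}",
                "nucleotide_change": "c.synthetic",
                "protein_change": "p.synthetic",
                "other": "",
                "n_a": "",
            }
        )

    df = pd.DataFrame(rows, columns=list(RAW_COLUMNS))

    # missing-value injection in the two configured numeric columns
    if config.missing_fraction > 0:
        n_blank = int(np.floor(config.missing_fraction * n))
        for col in config.missing_columns:
            if n_blank:
                blank_rows = rng.choice(n, size=n_blank, replace=False)
                df.loc[blank_rows, col] = np.nan

    return (df, gen_rule) if return_rules else df


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def export_raw(cohort: pd.DataFrame, path) -> None:
    """Write a raw cohort to CSV or XLSX (by suffix), one row per patient,
    empty string for the schema's empty cells."""
    if cohort.empty:
        raise ValueError("cannot export an empty cohort")
    path = Path(path)
    if path.suffix.lower() == ".csv":
        cohort.to_csv(path, index=False)
    elif path.suffix.lower() in (".xlsx", ".xls"):
        cohort.to_excel(path, index=False, sheet_name="patients")
    else:
        raise ValueError(f"unsupported export format {path.suffix!r}; use .csv or .xlsx")


def read_raw(path) -> pd.DataFrame:
    """Read a raw cohort written by :func:`export_raw` (lossless round trip)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, dtype=object, keep_default_na=False)
    elif path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, dtype=object, keep_default_na=False)
    else:
        raise ValueError(f"unsupported format {path.suffix!r}; use .csv or .xlsx")
    missing = sorted(set(RAW_COLUMNS) - set(df.columns))
    if missing:
        raise ValueError(f"file lacks raw-schema columns: {missing}")
    df = df[list(RAW_COLUMNS)]
    for col in ("age_of_onset", "age_of_dg"):
        df[col] = pd.to_numeric(df[col]).astype(int)
    for col in ("igg", "iga", "igm", "b_cells", "btk_monocytes", "btk_lib"):
        df[col] = pd.to_numeric(df[col].mask(df[col] == ""))
    text_cols = [
        c
        for c in RAW_COLUMNS
        if c not in ("age_of_onset", "age_of_dg", "igg", "iga", "igm", "b_cells", "btk_monocytes", "btk_lib")
    ]
    for col in text_cols:
        df[col] = df[col].astype(object).fillna("").astype(str)
    return df
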