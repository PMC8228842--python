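"""Raw-to-modelling table transformation.

Turns a 37-column raw patient table (ages, raw immunoglobulin levels in g/L,
B-cell and Btk measurements, 21 yes/empty disease flags, labels, genotype
text) into the 18-column modelling table: ages in months, laboratory values
as percent of the age-specific norm, disease flags folded into per-system
counts and severe/less-severe counts, yes/empty recoded as 1/0.  Missing
numeric values are imputed with the column median before any derived
quantity is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: The 21 past-disease yes/empty flags, in raw-table column order.
DISEASE_FLAGS: tuple[str, ...] = (
    "sepsis",
    "meningitis",
    "pneumonia",
    "bronchitis",
    "otitis",
    "diarrhea",
    "urti",
    "uti",
    "sinusitis",
    "bronchiectasis",
    "abscess",
    "hemophilia_a",
    "ascariasis",
    "conjunctivitis",
    "arthritis",
    "stomatitis",
    "furunculosis",
    "encephalitis",
    "guillain_barre",
    "laryngitis",
    "ibd",
)

#: Raw 37-column schema, in column order.
RAW_COLUMNS: tuple[str, ...] = (
    "age_of_onset",
    "age_of_dg",
    "igg",
    "iga",
    "igm",
    "b_cells",
    "btk_monocytes",
    "btk_lib",
    "family_history",
    *DISEASE_FLAGS,
    "mutation",
    "xla",
    "exon",
    "nucleotide_change",
    "protein_change",
    "other",
    "n_a",
)

#: Processed 18-column modelling schema, in column order.
PROCESSED_COLUMNS: tuple[str, ...] = (
    "age_ob",
    "age_dg",
    "igg_pct",
    "igm_pct",
    "iga_pct",
    "bcells_pct",
    "btk_lib",
    "btk_monocytes",
    "family",
    "severe_diseases",
    "less_severe_diseases",
    "rheumatology",
    "pulmonology",
    "otorhinolaryngology",
    "gastroenterology",
    "resistance",
    "mutation_severity",
    "course",
)

SYSTEM_GROUPS: tuple[str, ...] = (
    "rheumatology",
    "pulmonology",
    "otorhinolaryngology",
    "gastroenterology",
    "resistance",
)

_RAW_NUMERIC: tuple[str, ...] = (
    "age_of_onset",
    "age_of_dg",
    "igg",
    "iga",
    "igm",
    "b_cells",
    "btk_monocytes",
    "btk_lib",
)


@dataclass(frozen=True)
class ReferenceRanges:
    """Age-banded reference values per analyte.

    ``bands`` are half-open ``[low, high)`` intervals in months partitioning
    [0, inf); ``references[analyte][i]`` is the reference value on band i.
    """

    bands: tuple[tuple[float, float], ...]
    references: dict[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        if not self.bands or self.bands[0][0] != 0:
            raise ValueError("age bands must start at 0 months")
        for (lo, hi), (nlo, _) in zip(self.bands[:-1], self.bands[1:]):
            if hi != nlo:
                raise ValueError("age bands must partition [0, inf) without gaps")
            if not lo < hi:
                raise ValueError(f"empty age band [{lo}, {hi})")
        if not np.isinf(self.bands[-1][1]):
            raise ValueError("last age band must be open-ended")
        for analyte, values in self.references.items():
            if len(values) != len(self.bands):
                raise ValueError(f"{analyte}: one reference per band required")
            if any(v <= 0 for v in values):
                raise ValueError(f"{analyte}: reference values must be positive")

    def band_index(self, age_months: float) -> int:
        if age_months < 0:
            raise ValueError(f"age must be non-negative, got {age_months}")
        for i, (lo, hi) in enumerate(self.bands):
            if lo <= age_months < hi:
                return i
        raise ValueError(f"age {age_months} months matches no band")  # pragma: no cover

    def reference(self, analyte: str, age_months: float) -> float:
        if analyte not in self.references:
            raise ValueError(
                f"analyte {analyte!r} not in ranges; known: {sorted(self.references)}"
            )
        return self.references[analyte][self.band_index(age_months)]

    @classmethod
    def from_dict(cls, doc: dict) -> "ReferenceRanges":
        bands = tuple(
            (float(lo), float("inf") if hi is None else float(hi))
            for lo, hi in doc["age_bands_months"]
        )
        refs = {k: tuple(float(x) for x in v) for k, v in doc["references"].items()}
        return cls(bands, refs)

    @classmethod
    def from_yaml(cls, path) -> "ReferenceRanges":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_reference_ranges() -> ReferenceRanges:
    path = resources.files("xlapipe.data").joinpath("reference_ranges.yaml")
    return ReferenceRanges.from_dict(yaml.safe_load(path.read_text()))


def default_disease_mapping() -> dict[str, str]:
    """Flag -> organ-system mapping from the bundled grouping file."""
    path = resources.files("xlapipe.data").joinpath("disease_groups.yaml")
    doc = yaml.safe_load(path.read_text())
    mapping: dict[str, str] = {}
    for system, flags in doc["groups"].items():
        for flag in flags:
            mapping[flag] = system
    return mapping


def default_severe_set() -> frozenset[str]:
    """Diseases counted as severe invasive infections."""
    path = resources.files("xlapipe.data").joinpath("disease_groups.yaml")
    doc = yaml.safe_load(path.read_text())
    return frozenset(doc["severe"])


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def normalize_age(years: int, months: int) -> int:
    """Convert a (years, months) age to months only."""
    if years < 0 or months < 0:
        raise ValueError("years and months must be non-negative")
    if months >= 12:
        raise ValueError(f"months must be below 12, got {months}")
    return 12 * years + months


def percent_of_norm(
    value: float, age_months: float, analyte: str, ranges: ReferenceRanges
) -> float:
    """Laboratory value as a percentage of the age-band reference."""
    if value < 0:
        raise ValueError(f"value must be non-negative, got {value}")
    return 100.0 * value / ranges.reference(analyte, age_months)


def _flag_set(value: object) -> bool:
    return isinstance(value, str) and value.strip().lower() == "yes"


def group_diseases(
    record: Mapping[str, object], mapping: Mapping[str, str] | None = None
) -> dict[str, int]:
    """Count set disease flags per organ system."""
    mapping = mapping if mapping is not None else default_disease_mapping()
    unmapped = [f for f in DISEASE_FLAGS if f not in mapping]
    if unmapped:
        raise ValueError(f"disease flags not covered by mapping: {unmapped}")
    counts = {system: 0 for system in SYSTEM_GROUPS}
    for system in set(mapping.values()):
        counts.setdefault(system, 0)
    for flag in DISEASE_FLAGS:
        if _flag_set(record.get(flag)):
            counts[mapping[flag]] += 1
    return counts


def count_severity(
    record: Mapping[str, object], severe_set: frozenset[str] | None = None
) -> tuple[int, int]:
    """(severe, less severe) counts of set disease flags."""
    severe_set = severe_set if severe_set is not None else default_severe_set()
    unknown = set(severe_set) - set(DISEASE_FLAGS)
    if unknown:
        raise ValueError(f"severe set contains unknown diseases: {sorted(unknown)}")
    severe = sum(1 for f in DISEASE_FLAGS if f in severe_set and _flag_set(record.get(f)))
    less = sum(1 for f in DISEASE_FLAGS if f not in severe_set and _flag_set(record.get(f)))
    return severe, less


def impute_missing(table: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Replace blanks in the named numeric columns with the column median."""
    out = table.copy()
    for col in columns:
        if col not in out.columns:
            raise ValueError(f"column {col!r} not in table")
        values = pd.to_numeric(out[col], errors="coerce")
        n_missing = int(values.isna().sum())
        if n_missing == len(out) and len(out) > 0:
            raise ValueError(f"column {col!r} is entirely missing; cannot impute")
        if n_missing:
            median = float(values.median())
            values = values.fillna(median)
            logger.info("imputed %d value(s) in %r with median %g", n_missing, col, median)
        out[col] = values
    return out


# ---------------------------------------------------------------------------
# full-table preprocessing
# ---------------------------------------------------------------------------

def preprocess_cohort(
    raw: pd.DataFrame,
    ranges: ReferenceRanges | None = None,
    mapping: Mapping[str, str] | None = None,
    severe_set: frozenset[str] | None = None,
) -> pd.DataFrame:
    """Raw 37-column table -> processed 18-column modelling table.

    Percent-of-norm uses the age at diagnosis (when the laboratory panel is
    drawn).  Refuses an already-processed table instead of silently
    re-applying the transform.
    """
    if set(raw.columns) == set(PROCESSED_COLUMNS):
        raise ValueError("table already uses the processed schema; refusing to re-process")
    missing = sorted(set(RAW_COLUMNS) - set(raw.columns))
    extra = sorted(set(raw.columns) - set(RAW_COLUMNS))
    if missing or extra:
        raise ValueError(
            f"raw schema mismatch; missing columns: {missing}, unexpected: {extra}"
        )
    ranges = ranges if ranges is not None else default_reference_ranges()
    mapping = mapping if mapping is not None else default_disease_mapping()
    severe_set = severe_set if severe_set is not None else default_severe_set()

    if raw.empty:
        return pd.DataFrame(columns=list(PROCESSED_COLUMNS))

    with_imputed = impute_missing(
        raw, [c for c in _RAW_NUMERIC if pd.to_numeric(raw[c], errors="coerce").isna().any()]
    )
    for col in _RAW_NUMERIC:
        with_imputed[col] = pd.to_numeric(with_imputed[col])

    rows = []
    for _, rec in with_imputed.iterrows():
        age_dg = float(rec["age_of_dg"])
        systems = group_diseases(rec, mapping)
        severe, less = count_severity(rec, severe_set)
        rows.append(
            {
                "age_ob": int(rec["age_of_onset"]),
                "age_dg": int(age_dg),
                "igg_pct": percent_of_norm(rec["igg"], age_dg, "igg", ranges),
                "igm_pct": percent_of_norm(rec["igm"], age_dg, "igm", ranges),
                "iga_pct": percent_of_norm(rec["iga"], age_dg, "iga", ranges),
                "bcells_pct": percent_of_norm(rec["b_cells"], age_dg, "b_cells", ranges),
                "btk_lib": float(rec["btk_lib"]),
                "btk_monocytes": float(rec["btk_monocytes"]),
                "family": int(_present(rec["family_history"])),
                "severe_diseases": severe,
                "less_severe_diseases": less,
                **{s: systems[s] for s in SYSTEM_GROUPS},
                "mutation_severity": rec["mutation"],
                "course": rec["xla"],
            }
        )
    out = pd.DataFrame(rows, columns=list(PROCESSED_COLUMNS))
    logger.info("preprocessed %d record(s): %d -> %d columns", len(out), len(RAW_COLUMNS), len(PROCESSED_COLUMNS))
    return out


def _present(value: object) -> bool:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return False
    return str(value).strip() != ""
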