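"""Annotation tables, context strata and phenotype-profile construction.

A concept mention extracted from a visit's clinical text arrives as one
:class:`AnnotationRecord` carrying two independent context flags: *negated*
("no chest pain") and *uncertain* ("possible sepsis"). Profiles are built per
visit under one of four strata that keep or drop flagged mentions; each
stratum defines its own annotation corpus, and downstream information content
must be recomputed on it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .ontology import Ontology

__all__ = [
    "AnnotationRecord",
    "Stratum",
    "ProfileSet",
    "read_annotations",
    "read_diagnoses",
    "count_annotations",
    "apply_stratum",
    "build_profiles",
]


@dataclass(frozen=True)
class AnnotationRecord:
    """One concept mention: visit, term, and its negation/uncertainty flags."""

    visit_id: str
    term: str
    negated: bool
    uncertain: bool


class Stratum(enum.Enum):
    """Context-filter stratum for an annotation corpus.

    ``ALL`` keeps every mention; ``NO_NEG`` drops negated mentions;
    ``NO_UNC`` drops uncertain mentions; ``NO_NEG_NO_UNC`` drops both.
    """

    ALL = "all"
    NO_NEG = "no-neg"
    NO_UNC = "no-unc"
    NO_NEG_NO_UNC = "no-neg-no-unc"

    @classmethod
    def from_label(cls, label: "str | Stratum") -> "Stratum":
        if isinstance(label, cls):
            return label
        key = str(label).strip().lower().replace("_", "-")
        for s in cls:
            if s.value == key or s.name.lower().replace("_", "-") == key:
                return s
        raise ValueError(
            f"unknown stratum {label!r}; expected one of "
            f"{[s.value for s in cls]}"
        )

    def keeps(self, record: AnnotationRecord) -> bool:
        if self is Stratum.ALL:
            return True
        if self is Stratum.NO_NEG:
            return not record.negated
        if self is Stratum.NO_UNC:
            return not record.uncertain
        return not (record.negated or record.uncertain)


@dataclass
class ProfileSet:
    """Per-visit term sets for one stratum, with their diagnosis labels.

    ``kept_annotation_count`` is the number of annotation records surviving
    the stratum filter before per-visit deduplication into sets. Visits whose
    profile becomes empty after filtering are retained with an empty set so
    that every stratum ranks the same cohort.
    """

    profiles: dict[str, frozenset[str]]
    diagnosis: dict[str, str]
    stratum: Stratum
    kept_annotation_count: int

    @property
    def visits(self) -> list[str]:
        return sorted(self.profiles)

    def __len__(self) -> int:
        return len(self.profiles)


_TRUTHY = {"1": True, "true": True, "0": False, "false": False}


def _parse_flag(cell: object, column: str, row: int) -> bool:
    val = _TRUTHY.get(str(cell).strip().lower())
    if val is None:
        raise ValueError(
            f"unparseable {column} flag {cell!r} at data row {row} "
            "(expected 0/1/true/false)"
        )
    return val


def read_annotations(source: str | Path) -> list[AnnotationRecord]:
    """Read a headered TSV ``visit_id  term  negated  uncertain`` table.

    Flag cells accept 0/1/true/false, case-insensitively. Row order is
    preserved. Missing columns or unparseable flags are hard errors.
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    for col in ("visit_id", "term", "negated", "uncertain"):
        if col not in df.columns:
            raise ValueError(f"annotation table {source} is missing column {col!r}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        records.append(
            AnnotationRecord(
                visit_id=str(row.visit_id),
                term=str(row.term),
                negated=_parse_flag(row.negated, "negated", i),
                uncertain=_parse_flag(row.uncertain, "uncertain", i),
            )
        )
    return records


def read_diagnoses(source: str | Path) -> dict[str, str]:
    """Read a headered TSV ``visit_id  diagnosis`` table into a mapping."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    for col in ("visit_id", "diagnosis"):
        if col not in df.columns:
            raise ValueError(f"diagnosis table {source} is missing column {col!r}")
    return dict(zip(df["visit_id"].astype(str), df["diagnosis"].astype(str)))


def count_annotations(records: Iterable[AnnotationRecord]) -> dict[str, int]:
    """Marginal counts ``{total, negated, uncertain, both}`` over mentions.

    Dual-flagged records count toward both the negated and uncertain
    marginals as well as ``both``.
    """
    total = negated = uncertain = both = 0
    for r in records:
        total += 1
        if r.negated:
            negated += 1
        if r.uncertain:
            uncertain += 1
        if r.negated and r.uncertain:
            both += 1
    return {"total": total, "negated": negated, "uncertain": uncertain, "both": both}


def apply_stratum(
    records: Iterable[AnnotationRecord], stratum: Stratum
) -> list[AnnotationRecord]:
    """Filter mentions under ``stratum``, preserving relative order."""
    stratum = Stratum.from_label(stratum)
    return [r for r in records if stratum.keeps(r)]


def build_profiles(
    records: Iterable[AnnotationRecord],
    diagnoses: Mapping[str, str],
    ont: Ontology,
    stratum: Stratum,
) -> ProfileSet:
    """Filter annotations under ``stratum`` and collapse them to term sets.

    Every visit appearing in ``records`` is retained — with an empty profile
    if the filter removed all of its mentions — so all strata cover the same
    cohort and their metrics are comparable.

    Raises
    ------
    ValueError
        If an annotated term is absent from the ontology or a visit has no
        diagnosis label.
    """
    stratum = Stratum.from_label(stratum)
    records = list(records)
    for r in records:
        if r.term not in ont:
            raise ValueError(f"annotation term {r.term!r} absent from ontology")
        if r.visit_id not in diagnoses:
            raise ValueError(f"visit {r.visit_id!r} has no diagnosis label")
    kept = apply_stratum(records, stratum)
    profiles: dict[str, set[str]] = {r.visit_id: set() for r in records}
    for r in kept:
        profiles[r.visit_id].add(r.term)
    visit_dx = {v: diagnoses[v] for v in profiles}
    return ProfileSet(
        profiles={v: frozenset(ts) for v, ts in profiles.items()},
        diagnosis=visit_dx,
        stratum=stratum,
        kept_annotation_count=len(kept),
    )
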