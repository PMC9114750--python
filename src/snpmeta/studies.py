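"""Study roster data model, readers and subgroup machinery.

A *study roster* is the tabular backbone of a case-control SNP
meta-analysis: one row per primary study carrying the metadata used for
stratification (cancer type, organ system, ethnicity, control source),
the arm sizes, the control-group Hardy-Weinberg p-value as reported, and
— when the primary publication prints them — the per-arm genotype
counts.  The packaged example roster (``data/study_roster.tsv``)
transcribes 87 case-control studies of the CTLA-4 rs231775 A/G
polymorphism and cancer risk (29,464 cases / 35,858 controls); its
genotype-count columns are empty because the source table does not print
them, so effect estimation on it is count-only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "GenotypeCounts",
    "StudyRecord",
    "SubgroupKey",
    "StudyTableError",
    "SchemaError",
    "RowError",
    "VocabularyError",
    "ETHNICITIES",
    "SOURCES",
    "SUBGROUP_AXES",
    "read_study_table",
    "write_study_table",
    "load_example_roster",
    "load_system_map",
    "classify_system",
    "group_cancer_types",
    "filter_subgroup",
    "aggregate_counts",
]

ETHNICITIES = frozenset({"Asian", "Caucasian", "African"})
SOURCES = frozenset({"HB", "PB"})
SUBGROUP_AXES = ("total", "hwe_subset", "cancer_type", "system", "ethnicity", "source")

#: Placeholder stored when a control-HWE p is reported only as "<0.001".
BELOW_DETECTION_HWE_P = 0.0005

_REQUIRED_COLUMNS = (
    "study_id", "first_author", "year", "origin", "cancer_type", "system",
    "ethnicity", "source", "n_case", "n_control", "hwe_p", "method",
)
_COUNT_COLUMNS = ("case_AA", "case_AG", "case_GG", "ctrl_AA", "ctrl_AG", "ctrl_GG")


class StudyTableError(ValueError):
    """Base class for roster validation failures."""


class SchemaError(StudyTableError):
    """A required column is missing from the input file."""


class RowError(StudyTableError):
    """A data row failed to parse or violated a record invariant."""


class VocabularyError(StudyTableError):
    """A closed-vocabulary field holds an unknown token."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one arm, in ascending G dosage (AA, AG, GG)."""

    n_AA: int
    n_AG: int
    n_GG: int

    def __post_init__(self) -> None:
        for name in ("n_AA", "n_AG", "n_GG"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise RowError(f"genotype count {name}={v!r} must be a nonnegative integer")

    @property
    def total(self) -> int:
        return self.n_AA + self.n_AG + self.n_GG

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_AA, self.n_AG, self.n_GG)


@dataclass(frozen=True)
class StudyRecord:
    """One roster row: study metadata, arm sizes, optional genotype counts."""

    study_id: str
    first_author: str
    year: int
    origin: str
    cancer_type: str
    system: Optional[str]
    ethnicity: str
    source: str
    n_case: int
    n_control: int
    hwe_p: float
    method: str
    case_counts: Optional[GenotypeCounts] = None
    control_counts: Optional[GenotypeCounts] = None
    hwe_below_detection: bool = False
    true_params: Optional[Mapping[str, float]] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.study_id:
            raise RowError("study_id must be non-empty")
        if self.n_case < 1 or self.n_control < 1:
            raise RowError(f"{self.study_id}: arm sizes must be >= 1 "
                           f"(n_case={self.n_case}, n_control={self.n_control})")
        if self.ethnicity not in ETHNICITIES:
            raise VocabularyError(f"{self.study_id}: unknown ethnicity {self.ethnicity!r}; "
                                  f"expected one of {sorted(ETHNICITIES)}")
        if self.source not in SOURCES:
            raise VocabularyError(f"{self.study_id}: unknown source {self.source!r}; "
                                  f"expected one of {sorted(SOURCES)}")
        if not (0.0 <= self.hwe_p <= 1.0):
            raise RowError(f"{self.study_id}: hwe_p={self.hwe_p} outside [0, 1]")
        if self.case_counts is not None and self.case_counts.total != self.n_case:
            raise RowError(f"{self.study_id}: case genotype counts sum to "
                           f"{self.case_counts.total}, expected n_case={self.n_case}")
        if self.control_counts is not None and self.control_counts.total != self.n_control:
            raise RowError(f"{self.study_id}: control genotype counts sum to "
                           f"{self.control_counts.total}, expected n_control={self.n_control}")

    @property
    def has_genotype_counts(self) -> bool:
        return self.case_counts is not None and self.control_counts is not None


@dataclass(frozen=True)
class SubgroupKey:
    """Addresses one stratum of the subgroup taxonomy.

    ``axis`` is one of ``total``, ``hwe_subset``, ``cancer_type``,
    ``system``, ``ethnicity``, ``source``; ``level`` names the stratum on
    the filtering axes and must be absent for ``total``/``hwe_subset``.
    """

    axis: str
    level: Optional[str] = None

    def __post_init__(self) -> None:
        if self.axis not in SUBGROUP_AXES:
            raise ValueError(f"unknown subgroup axis {self.axis!r}")
        if self.axis in ("total", "hwe_subset"):
            if self.level is not None:
                raise ValueError(f"axis {self.axis!r} carries no level")
        elif not self.level:
            raise ValueError(f"axis {self.axis!r} requires a level")

    def __str__(self) -> str:
        return self.axis if self.level is None else f"{self.axis}={self.level}"


def _parse_hwe_p(token: str, study_id: str) -> tuple[float, bool]:
    token = token.strip()
    if token.startswith("<"):
        # reported below detection, e.g. "<0.001": store an inert placeholder
        return BELOW_DETECTION_HWE_P, True
    try:
        p = float(token)
    except ValueError as exc:
        raise RowError(f"{study_id}: cannot parse hwe_p {token!r}") from exc
    return p, False


def _parse_counts(row: Mapping[str, str], prefix: str, study_id: str) -> Optional[GenotypeCounts]:
    cells = [row.get(f"{prefix}_{g}", "").strip() for g in ("AA", "AG", "GG")]
    if all(c == "" for c in cells):
        return None
    if any(c == "" for c in cells):
        raise RowError(f"{study_id}: partial {prefix} genotype counts {cells}")
    try:
        ints = [int(c) for c in cells]
    except ValueError as exc:
        raise RowError(f"{study_id}: non-numeric {prefix} genotype count in {cells}") from exc
    return GenotypeCounts(*ints)


def read_study_table(path: str | Path, delimiter: str = "\t") -> list[StudyRecord]:
    """Read and validate a roster file into :class:`StudyRecord` objects.

    The file is UTF-8 delimited text with a header row; empty string
    means missing.  Genotype-count columns are optional per arm but an
    arm's three counts must be jointly present or jointly absent.
    Row order is preserved.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [c for c in _REQUIRED_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
        records: list[StudyRecord] = []
        for idx, row in enumerate(reader, start=2):  # line number incl. header
            sid = (row.get("study_id") or "").strip() or f"row{idx}"
            try:
                year = int(row["year"])
                n_case = int(row["n_case"])
                n_control = int(row["n_control"])
            except ValueError as exc:
                raise RowError(f"{path} line {idx} ({sid}): non-numeric field: {exc}") from exc
            hwe_p, below = _parse_hwe_p(row["hwe_p"], sid)
            rec = StudyRecord(
                study_id=sid,
                first_author=row["first_author"].strip(),
                year=year,
                origin=row["origin"].strip(),
                cancer_type=row["cancer_type"].strip(),
                system=row["system"].strip() or None,
                ethnicity=row["ethnicity"].strip(),
                source=row["source"].strip(),
                n_case=n_case,
                n_control=n_control,
                hwe_p=hwe_p,
                method=row["method"].strip(),
                case_counts=_parse_counts(row, "case", sid),
                control_counts=_parse_counts(row, "ctrl", sid),
                hwe_below_detection=below,
            )
            records.append(rec)
    ids = [r.study_id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise RowError(f"{path}: duplicate study_id(s) {dup}")
    return records


def write_study_table(records: Iterable[StudyRecord], path: str | Path,
                      delimiter: str = "\t") -> None:
    """Write records in the same dialect :func:`read_study_table` accepts."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(list(_REQUIRED_COLUMNS) + list(_COUNT_COLUMNS))
        for r in records:
            hwe = f"<0.001" if r.hwe_below_detection else repr(r.hwe_p)
            counts = (list(r.case_counts.as_tuple()) if r.case_counts else ["", "", ""]) + \
                     (list(r.control_counts.as_tuple()) if r.control_counts else ["", "", ""])
            writer.writerow([
                r.study_id, r.first_author, r.year, r.origin, r.cancer_type,
                r.system or "", r.ethnicity, r.source, r.n_case, r.n_control,
                hwe, r.method, *counts,
            ])


def _data_path(name: str) -> Path:
    return Path(str(resources.files("snpmeta").joinpath("data", name)))


def load_example_roster() -> list[StudyRecord]:
    """Load the packaged 87-study CTLA-4 rs231775 cancer roster."""
    return read_study_table(_data_path("study_roster.tsv"))


def load_system_map() -> dict[str, str]:
    """Load the cancer-type -> organ-system mapping shipped as data."""
    mapping: dict[str, str] = {}
    with _data_path("system_map.tsv").open(encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            mapping[row["cancer_type"]] = row["system"]
    return mapping


def classify_system(cancer_type: str,
                    system_map: Optional[Mapping[str, str]] = None) -> Optional[str]:
    """Map a cancer type to its organ system, or ``None`` when unmapped.

    The five-system vocabulary (digestive tract, orthopedic, urinary
    tract, gynecological, hematological) lives in an editable data file;
    types such as breast or lung belong to no system and return ``None``.
    """
    if not cancer_type:
        raise ValueError("cancer_type must be non-empty")
    if system_map is None:
        system_map = load_system_map()
    return system_map.get(cancer_type)


def group_cancer_types(records: Sequence[StudyRecord],
                       others_label: str = "others") -> dict[str, list[StudyRecord]]:
    """Group records by cancer type, lumping singleton types into "others".

    Each cancer type contributing at least two studies keeps its own
    group; all types represented by exactly one study are merged into a
    single group labelled ``others_label``.  Every record lands in
    exactly one group.
    """
    by_type: dict[str, list[StudyRecord]] = {}
    for r in records:
        by_type.setdefault(r.cancer_type, []).append(r)
    groups: dict[str, list[StudyRecord]] = {}
    others: list[StudyRecord] = []
    for ctype in by_type:
        if len(by_type[ctype]) >= 2:
            groups[ctype] = list(by_type[ctype])
        else:
            others.extend(by_type[ctype])
    if others:
        groups[others_label] = others
    return groups


def filter_subgroup(records: Sequence[StudyRecord], key: SubgroupKey,
                    hwe_threshold: float = 0.05) -> list[StudyRecord]:
    """Return the records belonging to one subgroup, order preserved.

    ``total`` is the identity; ``hwe_subset`` keeps studies whose
    control-HWE p is at or above ``hwe_threshold``; the remaining axes
    filter on the named metadata field.
    """
    if key.axis == "total":
        return list(records)
    if key.axis == "hwe_subset":
        return [r for r in records if r.hwe_p >= hwe_threshold]
    if key.axis == "cancer_type":
        groups = group_cancer_types(records)
        if key.level not in groups:
            known = sorted(groups)
            raise ValueError(f"no cancer-type group {key.level!r}; known groups: {known}")
        return groups[key.level]
    if key.axis == "system":
        return [r for r in records if r.system == key.level]
    if key.axis == "ethnicity":
        if key.level not in ETHNICITIES:
            raise ValueError(f"invalid ethnicity level {key.level!r}")
        return [r for r in records if r.ethnicity == key.level]
    if key.axis == "source":
        if key.level not in SOURCES:
            raise ValueError(f"invalid source level {key.level!r}")
        return [r for r in records if r.source == key.level]
    raise AssertionError("unreachable: SubgroupKey validated its axis")


def aggregate_counts(records: Sequence[StudyRecord]) -> tuple[int, int, int]:
    """(number of studies, total cases, total controls)."""
    return (len(records),
            sum(r.n_case for r in records),
            sum(r.n_control for r in records))
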