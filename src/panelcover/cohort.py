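"""Domain types, validation, and tabular I/O for IHC tissue-microarray cohorts.

A cohort is a set of invasive breast cancer patients, each with
clinicopathological fields and, per membrane marker, up to three tissue-core
staining scores (DAKO 0/1+/2+/3+ ordinal categories, or percent of stained
tumor cells for Mammaglobin).  Missing stainings are first-class: a core can
be MISSING (encoded as an empty CSV cell), and a whole assay can be absent.

The marker registry records, per marker, whether it is highly tumor-specific
(no/low staining of normal breast epithelium) or less tumor-specific, its
tumor-to-normal signal ratio when measured, and which positivity rule applies
when aggregating core scores.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Optional

__all__ = [
    "CoreScore",
    "MarkerAssay",
    "MarkerInfo",
    "TumorRecord",
    "Cohort",
    "CohortValidationError",
    "CohortParseError",
    "HISTOLOGIES",
    "SIZE_CLASSES",
    "POSITIVITY_RULES",
    "SPECIFICITY_CLASSES",
    "TUMOR_SPECIFIC_MARKERS",
    "LESS_SPECIFIC_MARKERS",
    "default_registry",
    "read_cohort",
    "write_cohort",
    "read_registry",
    "write_registry",
]

HISTOLOGIES = ("ductal", "lobular_classical", "lobular_pleomorphic", "other")
SIZE_CLASSES = ("<=2cm", ">2-<=5cm", ">5cm")
NODE_STATUSES = ("negative", "positive")
POSITIVITY_RULES = ("default_dako", "her2_strict", "any_core", "percent_cells")
SPECIFICITY_CLASSES = ("tumor_specific", "less_specific")

#: Highly tumor-specific membrane targets: no or low intensity staining of the
#: normal breast epithelium.
TUMOR_SPECIFIC_MARKERS = ("GLUT1", "EGFR", "IGF1R", "HER2", "CAIX", "MET")

#: Less tumor-specific targets, with moderate/high normal-epithelium staining;
#: useful only where the tumor-to-normal ratio is high enough.
LESS_SPECIFIC_MARKERS = ("MUC1", "CD44v6", "Mammaglobin", "TfR", "CAXII")


class CohortValidationError(ValueError):
    """A cohort, record, or registry violates a structural invariant."""


class CohortParseError(ValueError):
    """A tabular cohort file contains a malformed value; names row and column."""


@dataclass(frozen=True)
class CoreScore:
    """One tissue core's staining score.

    Exactly one of ``dako`` (ordinal category 0-3) or ``percent`` (fraction of
    membrane-stained tumor cells, 0-100, used for Mammaglobin) is set; both
    ``None`` encodes a MISSING staining.
    """

    dako: Optional[int] = None
    percent: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dako is not None and self.percent is not None:
            raise CohortValidationError("a core score is DAKO or percent, not both")
        if self.dako is not None and self.dako not in (0, 1, 2, 3):
            raise CohortValidationError(
                f"DAKO core score must be one of 0,1,2,3 or missing, got {self.dako!r}"
            )
        if self.percent is not None and not (0.0 <= self.percent <= 100.0):
            raise CohortValidationError(
                f"percent-cells core score must lie in [0, 100], got {self.percent!r}"
            )

    @property
    def is_missing(self) -> bool:
        return self.dako is None and self.percent is None

    @staticmethod
    def missing() -> "CoreScore":
        return CoreScore()


@dataclass(frozen=True)
class MarkerAssay:
    """Up to three core scores for one marker on one tumor (3 cylinders arrayed)."""

    marker_id: str
    cores: tuple[CoreScore, ...]

    def __post_init__(self) -> None:
        if not (1 <= len(self.cores) <= 3):
            raise CohortValidationError(
                f"{self.marker_id}: a marker assay holds 1-3 cores, got {len(self.cores)}"
            )
        object.__setattr__(self, "cores", tuple(self.cores))

    @property
    def all_missing(self) -> bool:
        return all(c.is_missing for c in self.cores)


@dataclass(frozen=True)
class MarkerInfo:
    """Registry entry: specificity class, tumor-to-normal ratio, positivity rule.

    ``tn_ratio`` is ``None`` when unknown; tumor-specific markers have no
    normal-tissue signal to ratio against and conventionally carry ``None``,
    which any T/N gate treats as passing.
    """

    marker_id: str
    specificity_class: str
    tn_ratio: Optional[float] = None
    positivity_rule: str = "default_dako"

    def __post_init__(self) -> None:
        if self.specificity_class not in SPECIFICITY_CLASSES:
            raise CohortValidationError(
                f"{self.marker_id}: unknown specificity class {self.specificity_class!r}"
            )
        if self.positivity_rule not in POSITIVITY_RULES:
            raise CohortValidationError(
                f"{self.marker_id}: unknown positivity rule {self.positivity_rule!r}"
            )
        if self.tn_ratio is not None and self.tn_ratio <= 0:
            raise CohortValidationError(
                f"{self.marker_id}: tn_ratio must be positive, got {self.tn_ratio}"
            )


@dataclass(eq=False)
class TumorRecord:
    """One patient/tumor: clinicopathological fields plus per-marker assays.

    ER/PR status enters as booleans (nuclear hormone-receptor calls are made
    upstream of this pipeline; no membrane-DAKO cut-off applies to them).

    Equality is semantic with respect to missingness: an absent assay equals
    a fully-missing one, and assays with fewer than 3 cores equal their
    missing-padded form (tabular round trips preserve neither distinction,
    and scoring treats them identically).
    """

    patient_id: str
    age: float
    histology: str
    grade: Optional[int]
    size_class: Optional[str]
    node_status: Optional[str]
    er_positive: bool
    pr_positive: bool
    assays: dict[str, MarkerAssay] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise CohortValidationError(f"{self.patient_id}: age must be > 0")
        if self.histology not in HISTOLOGIES:
            raise CohortValidationError(
                f"{self.patient_id}: unknown histology {self.histology!r}"
            )
        if self.grade is not None and self.grade not in (1, 2, 3):
            raise CohortValidationError(
                f"{self.patient_id}: grade must be 1, 2, 3 or NA, got {self.grade!r}"
            )
        if self.size_class is not None and self.size_class not in SIZE_CLASSES:
            raise CohortValidationError(
                f"{self.patient_id}: unknown size class {self.size_class!r}"
            )
        if self.node_status is not None and self.node_status not in NODE_STATUSES:
            raise CohortValidationError(
                f"{self.patient_id}: unknown node status {self.node_status!r}"
            )

    @property
    def lobular(self) -> bool:
        """Combined lobular view (classical + pleomorphic); derived, never stored."""
        return self.histology in ("lobular_classical", "lobular_pleomorphic")

    def _normalized_assays(self) -> dict[str, tuple[CoreScore, ...]]:
        out = {}
        for mid, assay in self.assays.items():
            cores = assay.cores + (CoreScore.missing(),) * (3 - len(assay.cores))
            if not all(c.is_missing for c in cores):
                out[mid] = cores
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TumorRecord):
            return NotImplemented
        scalar = (
            "patient_id", "age", "histology", "grade",
            "size_class", "node_status", "er_positive", "pr_positive",
        )
        return all(getattr(self, f) == getattr(other, f) for f in scalar) and (
            self._normalized_assays() == other._normalized_assays()
        )


@dataclass
class Cohort:
    """Validated collection of tumor records plus the marker registry."""

    records: list[TumorRecord]
    registry: dict[str, MarkerInfo]

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise CohortValidationError(f"duplicate patient_id {dup!r}")
        for rec in self.records:
            for mid in rec.assays:
                if mid not in self.registry:
                    raise CohortValidationError(
                        f"{rec.patient_id}: assay marker {mid!r} not in registry"
                    )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def markers(self) -> list[str]:
        return list(self.registry)

    def subset(self, predicate: Callable[[TumorRecord], bool]) -> "Cohort":
        return Cohort([r for r in self.records if predicate(r)], self.registry)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return self.records == other.records and self.registry == other.registry


def default_registry() -> dict[str, MarkerInfo]:
    """The eleven-marker registry of the reference study.

    GLUT1 and CAIX are hypoxia markers expressed focally; a single positive
    core calls the tumor positive (any_core).  HER2 follows the strict
    clinical convention (3+ only).  Mammaglobin is scored as percent of
    stained cells.  T/N ratios of the less-specific markers come from
    immunofluorescence quantification (TfR from IHC; not detectable by IF).
    """
    from .reference import reference_tn_ratios

    tn = reference_tn_ratios()
    reg: dict[str, MarkerInfo] = {}
    for mid in TUMOR_SPECIFIC_MARKERS:
        rule = "any_core" if mid in ("GLUT1", "CAIX") else (
            "her2_strict" if mid == "HER2" else "default_dako"
        )
        reg[mid] = MarkerInfo(mid, "tumor_specific", None, rule)
    for mid in LESS_SPECIFIC_MARKERS:
        rule = "percent_cells" if mid == "Mammaglobin" else "default_dako"
        reg[mid] = MarkerInfo(mid, "less_specific", tn.get(mid), rule)
    return reg


# ---------------------------------------------------------------------------
# Tabular I/O.  Comma- (or tab-) separated, UTF-8, "." decimal mark; the empty
# string encodes MISSING.  Columns: patient_id, age, histology, grade,
# size_class, node_status, er, pr, then <marker>_core<1|2|3> per registry
# marker.
# ---------------------------------------------------------------------------

_FIXED_COLUMNS = (
    "patient_id",
    "age",
    "histology",
    "grade",
    "size_class",
    "node_status",
    "er",
    "pr",
)


def _delim(fmt: str) -> str:
    if fmt == "csv":
        return ","
    if fmt == "tsv":
        return "\t"
    raise ValueError(f"format must be 'csv' or 'tsv', got {fmt!r}")


def _parse_core(cell: str, percent_rule: bool, row: int, col: str) -> CoreScore:
    cell = cell.strip()
    if cell == "":
        return CoreScore.missing()
    try:
        value = float(cell)
    except ValueError:
        raise CohortParseError(
            f"row {row}, column {col}: malformed score {cell!r}"
        ) from None
    try:
        if percent_rule:
            return CoreScore(percent=value)
        if value != int(value):
            raise CohortValidationError("fractional DAKO score")
        return CoreScore(dako=int(value))
    except CohortValidationError as exc:
        raise CohortParseError(f"row {row}, column {col}: {exc}") from None


def _parse_bool(cell: str, row: int, col: str) -> bool:
    cell = cell.strip().lower()
    if cell in ("1", "true", "yes", "pos", "positive"):
        return True
    if cell in ("0", "false", "no", "neg", "negative"):
        return False
    raise CohortParseError(f"row {row}, column {col}: malformed boolean {cell!r}")


def read_cohort(
    path: str | Path,
    format: str = "csv",
    registry: Optional[dict[str, MarkerInfo]] = None,
) -> Cohort:
    """Read a cohort table; marker columns are inferred from ``<marker>_core<k>``.

    Raises :class:`CohortParseError` naming the offending row and column on
    malformed cells, and :class:`CohortValidationError` on duplicate patient
    ids or enum violations.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=_delim(format))
        rows = list(reader)
    if not rows:
        raise CohortParseError(f"{path}: empty file, header row required")
    header = rows[0]
    for col in _FIXED_COLUMNS:
        if col not in header:
            raise CohortParseError(f"{path}: missing required column {col!r}")

    marker_cols: dict[str, dict[int, int]] = {}
    for j, col in enumerate(header):
        if "_core" in col:
            mid, _, k = col.rpartition("_core")
            if mid and k in ("1", "2", "3"):
                marker_cols.setdefault(mid, {})[int(k)] = j
    if registry is None:
        registry = {
            mid: (default_registry().get(mid) or MarkerInfo(mid, "less_specific"))
            for mid in marker_cols
        }
    idx = {col: j for j, col in enumerate(header)}

    records: list[TumorRecord] = []
    for i, row in enumerate(rows[1:], start=2):
        if not any(cell.strip() for cell in row):
            continue
        get = lambda col: row[idx[col]].strip() if idx[col] < len(row) else ""
        try:
            grade_cell = get("grade")
            size_cell = get("size_class")
            node_cell = get("node_status")
            rec = TumorRecord(
                patient_id=get("patient_id"),
                age=float(get("age")),
                histology=get("histology"),
                grade=int(grade_cell) if grade_cell else None,
                size_class=size_cell or None,
                node_status=node_cell or None,
                er_positive=_parse_bool(get("er"), i, "er"),
                pr_positive=_parse_bool(get("pr"), i, "pr"),
            )
        except CohortParseError:
            raise
        except (ValueError, CohortValidationError) as exc:
            raise CohortParseError(f"row {i}: {exc}") from None
        for mid, cols in marker_cols.items():
            percent_rule = registry[mid].positivity_rule == "percent_cells"
            cores = tuple(
                _parse_core(
                    row[j] if j < len(row) else "", percent_rule, i, header[j]
                )
                for _, j in sorted(cols.items())
            )
            rec.assays[mid] = MarkerAssay(mid, cores)
        records.append(rec)
    return Cohort(records, registry)


def _format_core(core: CoreScore) -> str:
    if core.is_missing:
        return ""
    if core.dako is not None:
        return str(core.dako)
    assert core.percent is not None
    return repr(core.percent)  # full precision so read(write(C)) == C


def write_cohort(cohort: Cohort, path: str | Path, format: str = "csv") -> None:
    """Write a cohort table re-readable by :func:`read_cohort` into an equal cohort."""
    path = Path(path)
    markers = cohort.markers
    header = list(_FIXED_COLUMNS) + [
        f"{mid}_core{k}" for mid in markers for k in (1, 2, 3)
    ]
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=_delim(format), lineterminator="\n")
        writer.writerow(header)
        for rec in cohort.records:
            row = [
                rec.patient_id,
                repr(float(rec.age)),
                rec.histology,
                "" if rec.grade is None else str(rec.grade),
                rec.size_class or "",
                rec.node_status or "",
                "1" if rec.er_positive else "0",
                "1" if rec.pr_positive else "0",
            ]
            for mid in markers:
                assay = rec.assays.get(mid)
                cores = list(assay.cores) if assay else []
                cores += [CoreScore.missing()] * (3 - len(cores))
                row.extend(_format_core(c) for c in cores)
            writer.writerow(row)


def read_registry(path: str | Path) -> dict[str, MarkerInfo]:
    """Read a marker registry from JSON (list of marker entries)."""
    with Path(path).open(encoding="utf-8") as fh:
        data = json.load(fh)
    entries = data["markers"] if isinstance(data, dict) else data
    reg = {}
    for e in entries:
        info = MarkerInfo(
            marker_id=e["marker_id"],
            specificity_class=e["specificity_class"],
            tn_ratio=e.get("tn_ratio"),
            positivity_rule=e.get("positivity_rule", "default_dako"),
        )
        reg[info.marker_id] = info
    return reg


def write_registry(registry: dict[str, MarkerInfo], path: str | Path) -> None:
    entries = [
        {
            "marker_id": info.marker_id,
            "specificity_class": info.specificity_class,
            "tn_ratio": info.tn_ratio,
            "positivity_rule": info.positivity_rule,
        }
        for info in registry.values()
    ]
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump({"markers": entries}, fh, indent=2)
        fh.write("\n")
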