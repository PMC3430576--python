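"""Tumor-level positivity calls from core-level IHC scores, plus frequency tables.

Scoring rules
-------------
Membranous staining is graded per core on the DAKO 0/1+/2+/3+ scale.  To
absorb between-core tumor heterogeneity, the average score over the available
(non-missing) cores is taken per tumor, rounded half-away-from-zero to the
nearest category, and the tumor is called positive when that category is
2 or 3 — except:

* **HER2** — only a (rounded) score of 3+ counts as positive, the strict
  clinical convention.
* **GLUT1 / CAIX** — hypoxia markers with focal expression; a *single*
  positive core (2+/3+) suffices to call the tumor positive.
* **Mammaglobin** — strong intra-tumor heterogeneity makes intensity grading
  unreliable; the percentage of membrane-stained tumor cells is estimated
  instead, and the tumor is positive when the mean percentage strictly
  exceeds 35.

A marker whose cores are all missing is scored **negative** (conservative:
this can only underestimate positivity).  Patients with more than three
fully-missing markers are excluded by :func:`qc_filter` before any analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import pandas as pd

from .cohort import Cohort, MarkerAssay, MarkerInfo, TumorRecord

__all__ = [
    "PositivityCall",
    "FrequencyTable",
    "ConfigurationError",
    "EmptyStratumWarning",
    "aggregate_cores",
    "qc_filter",
    "score_cohort",
    "calls_matrix",
    "tabulate_frequencies",
    "tabulate_clinical",
    "round_half_away",
    "round1",
]


class ConfigurationError(ValueError):
    """Positivity rule and assay data kind do not match."""


class EmptyStratumWarning(UserWarning):
    """A frequency or rate was requested for an empty stratum."""


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (2.5 -> 3)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def round1(x: float) -> float:
    """Round to one decimal, halves away from zero (table-style percentages)."""
    return round_half_away(x * 10) / 10.0


@dataclass(frozen=True)
class PositivityCall:
    """Tumor-level call for one marker.

    ``tumor_score`` is the mean DAKO score (real in [0, 3]) or mean percent of
    stained cells, or ``None`` when every core is missing.  ``basis`` records
    which rule produced the call.
    """

    marker_id: str
    tumor_score: Optional[float]
    positive: bool
    basis: str

    @property
    def call(self) -> str:
        return "positive" if self.positive else "negative"


def aggregate_cores(assay: MarkerAssay, info: MarkerInfo) -> PositivityCall:
    """Aggregate 1-3 core scores into a tumor-level positivity call.

    Missing single cores are dropped from the mean (not imputed); only a
    fully-missing assay forces a negative call with basis
    ``missing_as_negative``.
    """
    if assay.marker_id != info.marker_id:
        raise ConfigurationError(
            f"assay is for {assay.marker_id!r}, registry entry for {info.marker_id!r}"
        )
    rule = info.positivity_rule

    if rule == "percent_cells":
        vals = [c.percent for c in assay.cores if not c.is_missing]
        if any(v is None for v in vals):
            raise ConfigurationError(
                f"{assay.marker_id}: percent_cells rule but DAKO-scored cores"
            )
        if not vals:
            return PositivityCall(assay.marker_id, None, False, "missing_as_negative")
        mean = sum(vals) / len(vals)  # type: ignore[arg-type]
        return PositivityCall(assay.marker_id, mean, mean > 35.0, "percent_cells")

    vals_i = [c.dako for c in assay.cores if not c.is_missing]
    if any(v is None for v in vals_i):
        raise ConfigurationError(
            f"{assay.marker_id}: DAKO rule {rule!r} but percent-scored cores"
        )
    if not vals_i:
        return PositivityCall(assay.marker_id, None, False, "missing_as_negative")
    mean = sum(vals_i) / len(vals_i)  # type: ignore[arg-type]

    if rule == "any_core":
        positive = any(v >= 2 for v in vals_i)  # type: ignore[operator]
        return PositivityCall(assay.marker_id, mean, positive, "any_core")
    category = round_half_away(mean)
    if rule == "her2_strict":
        return PositivityCall(assay.marker_id, mean, category == 3, "her2_strict")
    if rule == "default_dako":
        return PositivityCall(assay.marker_id, mean, category in (2, 3), "mean_dako")
    raise ConfigurationError(f"unknown positivity rule {rule!r}")


def _n_fully_missing(rec: TumorRecord, registry: dict[str, MarkerInfo]) -> int:
    n = 0
    for mid in registry:
        assay = rec.assays.get(mid)
        if assay is None or assay.all_missing:
            n += 1
    return n


def qc_filter(cohort: Cohort, max_missing: int = 3) -> tuple[Cohort, list[str]]:
    """Drop patients with more than ``max_missing`` fully-missing markers.

    Returns the filtered cohort and the excluded patient ids.  Retained
    patients keep their missing markers, which score negative downstream.
    """
    kept, excluded = [], []
    for rec in cohort.records:
        if _n_fully_missing(rec, cohort.registry) > max_missing:
            excluded.append(rec.patient_id)
        else:
            kept.append(rec)
    return Cohort(kept, cohort.registry), excluded


def score_cohort(cohort: Cohort) -> pd.DataFrame:
    """Tidy per-(patient, marker) calls: tumor_score, call, basis."""
    rows = []
    for rec in cohort.records:
        for mid, info in cohort.registry.items():
            assay = rec.assays.get(mid)
            if assay is None:
                call = PositivityCall(mid, None, False, "missing_as_negative")
            else:
                call = aggregate_cores(assay, info)
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "marker_id": mid,
                    "tumor_score": call.tumor_score,
                    "call": call.call,
                    "basis": call.basis,
                }
            )
    return pd.DataFrame(rows)


def calls_matrix(cohort: Cohort) -> pd.DataFrame:
    """Boolean patient x marker positivity matrix (missing scores negative)."""
    data = {}
    index = [rec.patient_id for rec in cohort.records]
    for mid, info in cohort.registry.items():
        col = []
        for rec in cohort.records:
            assay = rec.assays.get(mid)
            col.append(False if assay is None else aggregate_cores(assay, info).positive)
        data[mid] = col
    return pd.DataFrame(data, index=pd.Index(index, name="patient_id"), dtype=bool)


@dataclass(frozen=True)
class FrequencyTable:
    """Positive / negative / missing partition of a (sub)cohort for one marker.

    Percentages use the full stratum size as denominator (missing included),
    rounded to one decimal.  ``empty`` flags a zero-size stratum, in which
    case all percentages are reported as 0.
    """

    marker_id: str
    n_positive: int
    n_negative: int
    n_missing: int
    pct_positive: float
    pct_negative: float
    pct_missing: float
    empty: bool = False

    @property
    def n_total(self) -> int:
        return self.n_positive + self.n_negative + self.n_missing


def tabulate_frequencies(
    cohort: Cohort,
    marker_id: str,
    stratum_filter: Optional[Callable[[TumorRecord], bool]] = None,
) -> FrequencyTable:
    """Count positive/negative/missing tumors for one marker in a stratum.

    Missing means a fully-missing assay (the marker never stained for that
    patient); such tumors count as *missing* here even though they score
    negative in detection-rate analyses.
    """
    if marker_id not in cohort.registry:
        raise KeyError(f"marker {marker_id!r} not in registry")
    info = cohort.registry[marker_id]
    records = cohort.records
    if stratum_filter is not None:
        records = [r for r in records if stratum_filter(r)]
    n_pos = n_neg = n_miss = 0
    for rec in records:
        assay = rec.assays.get(marker_id)
        if assay is None or assay.all_missing:
            n_miss += 1
        elif aggregate_cores(assay, info).positive:
            n_pos += 1
        else:
            n_neg += 1
    n = n_pos + n_neg + n_miss
    if n == 0:
        warnings.warn(
            f"empty stratum for marker {marker_id!r}: percentages undefined",
            EmptyStratumWarning,
            stacklevel=2,
        )
        return FrequencyTable(marker_id, 0, 0, 0, 0.0, 0.0, 0.0, empty=True)
    return FrequencyTable(
        marker_id,
        n_pos,
        n_neg,
        n_miss,
        round1(100.0 * n_pos / n),
        round1(100.0 * n_neg / n),
        round1(100.0 * n_miss / n),
    )


def tabulate_clinical(cohort: Cohort, field: str) -> dict[str, tuple[int, float]]:
    """Counts and one-decimal percentages of a clinicopathological field.

    ``field`` is one of histology, histology_combined (classical+pleomorphic
    lobular merged), grade, size_class, node_status.  ``None`` values appear
    under the key ``"NA"``.  Denominator is the full cohort.
    """
    n = len(cohort)
    counts: dict[str, int] = {}
    for rec in cohort.records:
        if field == "histology_combined":
            key = "lobular" if rec.lobular else rec.histology
        else:
            value = getattr(rec, field)
            key = "NA" if value is None else str(value)
        counts[key] = counts.get(key, 0) + 1
    return {
        k: (c, round1(100.0 * c / n) if n else 0.0) for k, c in counts.items()
    }
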