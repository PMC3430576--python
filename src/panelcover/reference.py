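"""Reference-study counts and fixture cohorts built from them.

``data/reference_counts.json`` transcribes the published frequency tables of
the 483-patient invasive breast cancer TMA study the package defaults mirror:
per-marker positive/negative/missing counts overall, positive counts per
histological type (ductal / lobular / other) and per molecular subtype of
ductal cancers (luminal / HER2-driven / basal+triple-negative), the
clinicopathological margins, and the measured tumor-to-normal ratios of the
less tumor-specific markers.  Three printed cells are internally inconsistent
(count vs percentage vs totals) and are corrected as noted inline in the JSON.

The builders construct deterministic cohorts that *encode those counts
exactly*, marker by marker, so the scoring and tabulation pipeline can be
checked against the printed percentages.  Markers are assigned independently
of each other, so these fixtures carry no meaningful joint (co-expression)
structure and must not be used for panel detection rates.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

from .cohort import (
    Cohort,
    CoreScore,
    MarkerAssay,
    MarkerInfo,
    TumorRecord,
    default_registry,
)

__all__ = [
    "reference_counts",
    "reference_tn_ratios",
    "build_overall_cohort",
    "build_histology_cohort",
    "build_subtype_cohort",
    "build_clinical_cohort",
]


@lru_cache(maxsize=1)
def reference_counts() -> dict:
    with resources.files("panelcover.data").joinpath("reference_counts.json").open(
        encoding="utf-8"
    ) as fh:
        return json.load(fh)


def reference_tn_ratios() -> dict[str, float]:
    return {k: v for k, v in reference_counts()["tn_ratios"].items() if k != "comment"}


def _positive_assay(marker: str, info: MarkerInfo) -> MarkerAssay:
    if info.positivity_rule == "percent_cells":
        cores = (CoreScore(percent=80.0),) * 3
    else:
        cores = (CoreScore(dako=3),) * 3
    return MarkerAssay(marker, cores)


def _negative_assay(marker: str, info: MarkerInfo) -> MarkerAssay:
    if info.positivity_rule == "percent_cells":
        cores = (CoreScore(percent=0.0),) * 3
    else:
        cores = (CoreScore(dako=0),) * 3
    return MarkerAssay(marker, cores)


def _missing_assay(marker: str) -> MarkerAssay:
    return MarkerAssay(marker, (CoreScore.missing(),) * 3)


def _blank_records(n: int, histology: str = "ductal", prefix: str = "R") -> list[TumorRecord]:
    return [
        TumorRecord(
            patient_id=f"{prefix}{i + 1:04d}",
            age=60.0,
            histology=histology,
            grade=None,
            size_class=None,
            node_status=None,
            er_positive=False,
            pr_positive=False,
        )
        for i in range(n)
    ]


def build_overall_cohort() -> Cohort:
    """483 tumors encoding the overall positive/negative/missing marker counts.

    Missing assays rotate across patients so no patient exceeds the 3-missing
    QC limit (total missing count < cohort size guarantees at most one
    missing marker per patient).
    """
    ref = reference_counts()
    n = ref["cohort_size"]
    registry = default_registry()
    records = _blank_records(n)
    cursor = 0
    for marker, (n_pos, n_neg, n_miss) in ref["overall"]["counts"].items():
        assert n_pos + n_neg + n_miss == n, marker
        info = registry[marker]
        missing_idx = {(cursor + j) % n for j in range(n_miss)}
        cursor += n_miss
        assigned_pos = 0
        for i, rec in enumerate(records):
            if i in missing_idx:
                rec.assays[marker] = _missing_assay(marker)
            elif assigned_pos < n_pos:
                rec.assays[marker] = _positive_assay(marker, info)
                assigned_pos += 1
            else:
                rec.assays[marker] = _negative_assay(marker, info)
    return Cohort(records, registry)


def _stratified_cohort(
    sizes: dict[str, int],
    positive: dict[str, list[int]],
    histology_of: dict[str, str],
    er_of: dict[str, bool],
) -> Cohort:
    registry = default_registry()
    records: list[TumorRecord] = []
    offsets: dict[str, tuple[int, int]] = {}
    start = 0
    for stratum, size in sizes.items():
        offsets[stratum] = (start, start + size)
        for i in range(size):
            records.append(
                TumorRecord(
                    patient_id=f"S{start + i + 1:04d}",
                    age=60.0,
                    histology=histology_of[stratum] if not histology_of[stratum].startswith(
                        "lobular_mix"
                    ) else ("lobular_classical" if i < 58 else "lobular_pleomorphic"),
                    grade=None,
                    size_class=None,
                    node_status=None,
                    er_positive=er_of[stratum],
                    pr_positive=False,
                )
            )
        start += size
    for marker, counts in positive.items():
        info = registry[marker]
        for (stratum, size), n_pos in zip(sizes.items(), counts):
            lo, hi = offsets[stratum]
            assert 0 <= n_pos <= size, (marker, stratum)
            for i in range(lo, hi):
                if i - lo < n_pos:
                    records[i].assays[marker] = _positive_assay(marker, info)
                else:
                    records[i].assays[marker] = _negative_assay(marker, info)
    return Cohort(records, registry)


def build_histology_cohort() -> Cohort:
    """483 tumors encoding per-histology marker positive counts (no missing).

    The 126 lobular cases split 58 classical / 68 pleomorphic; the combined
    lobular stratum carries the printed counts.
    """
    ref = reference_counts()
    return _stratified_cohort(
        sizes=ref["by_histology"]["sizes"],
        positive=ref["by_histology"]["positive"],
        histology_of={"ductal": "ductal", "lobular": "lobular_mix", "other": "other"},
        er_of={"ductal": False, "lobular": False, "other": False},
    )


def build_subtype_cohort() -> Cohort:
    """319 ductal tumors encoding per-subtype marker counts.

    ER is set positive for the luminal stratum and negative elsewhere;
    HER2/EGFR positivity comes from the marker assignment itself, so running
    the subtype classifier on this cohort recovers the stratum sizes
    (242 luminal, 20 HER2-driven, 57 basal+TN).
    """
    ref = reference_counts()
    return _stratified_cohort(
        sizes=ref["by_subtype"]["sizes"],
        positive=ref["by_subtype"]["positive"],
        histology_of={"luminal": "ductal", "her2_driven": "ductal", "basal_tn": "ductal"},
        er_of={"luminal": True, "her2_driven": False, "basal_tn": False},
    )


def build_clinical_cohort() -> Cohort:
    """483 records encoding the clinicopathological margins (no assays)."""
    ref = reference_counts()
    clin = ref["clinical"]
    n = ref["cohort_size"]
    records: list[TumorRecord] = []
    hist_seq: list[str] = []
    for hist, count in clin["histology"].items():
        if hist == "lobular":
            hist_seq += ["lobular_classical"] * 58 + ["lobular_pleomorphic"] * (count - 58)
        else:
            hist_seq += [hist] * count

    def seq(counts: dict[str, int], cast) -> list:
        out: list = []
        for key, count in counts.items():
            out += [None if key == "NA" else cast(key)] * count
        return out

    grades = seq(clin["grade"], int)
    sizes = seq(clin["size_class"], str)
    nodes = seq(clin["node_status"], str)
    lo, hi = clin["age_range"]
    for i in range(n):
        age = float(clin["age_mean"]) if i > 1 else float((lo, hi)[i])
        records.append(
            TumorRecord(
                patient_id=f"C{i + 1:04d}",
                age=age,
                histology=hist_seq[i],
                grade=grades[i],
                size_class=sizes[i],
                node_status=nodes[i],
                er_positive=False,
                pr_positive=False,
            )
        )
    return Cohort(records, default_registry())
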