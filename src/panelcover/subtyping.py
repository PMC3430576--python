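"""IHC-surrogate molecular subtype classification.

The surrogate of the expression-profiling (intrinsic) subtypes, from four
binary calls:

* **luminal** — ER and/or PR positive, regardless of HER2/EGFR;
* **HER2-driven** — ER-, PR-, HER2+;
* **basal** — ER-, PR-, HER2-, EGFR+;
* **triple negative** — ER-, PR-, HER2-, EGFR-.

The definitions are nested complements, so the only consistent reading is the
precedence luminal > HER2-driven > basal > triple negative; classification is
total on the 16 boolean input combinations.  Basal and triple negative merge
into the combined stratum ``basal_tn`` for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import pandas as pd

from .cohort import Cohort
from .scoring import PositivityCall, aggregate_cores

__all__ = ["Subtype", "SUBTYPE_LABELS", "COMBINED_LABELS", "classify_subtype", "subtype_cohort"]

SUBTYPE_LABELS = ("luminal", "her2_driven", "basal", "triple_negative")
COMBINED_LABELS = ("luminal", "her2_driven", "basal_tn")


@dataclass(frozen=True)
class Subtype:
    label: str

    @property
    def combined_label(self) -> str:
        """basal and triple_negative collapse into the basal_tn stratum."""
        if self.label in ("basal", "triple_negative"):
            return "basal_tn"
        return self.label


def _as_bool(call: Union[bool, PositivityCall]) -> bool:
    if isinstance(call, PositivityCall):
        return call.positive
    return bool(call)


def classify_subtype(
    er_positive: bool,
    pr_positive: bool,
    her2_call: Union[bool, PositivityCall],
    egfr_call: Union[bool, PositivityCall],
) -> Subtype:
    """Classify one tumor; HER2/EGFR accept raw booleans or scoring-module calls."""
    her2 = _as_bool(her2_call)
    egfr = _as_bool(egfr_call)
    if er_positive or pr_positive:
        return Subtype("luminal")
    if her2:
        return Subtype("her2_driven")
    if egfr:
        return Subtype("basal")
    return Subtype("triple_negative")


def subtype_cohort(cohort: Cohort) -> pd.DataFrame:
    """Classify every tumor in a cohort using its HER2/EGFR scoring calls.

    Missing HER2/EGFR assays score negative (per the scoring rules), so every
    tumor is classifiable.  Returns patient_id-indexed label and
    combined_label columns; subtype-stratified reports conventionally restrict
    to ductal histology.
    """
    rows = {}
    for rec in cohort.records:
        calls = {}
        for mid in ("HER2", "EGFR"):
            assay = rec.assays.get(mid)
            if assay is None or mid not in cohort.registry:
                calls[mid] = False
            else:
                calls[mid] = aggregate_cores(assay, cohort.registry[mid]).positive
        st = classify_subtype(rec.er_positive, rec.pr_positive, calls["HER2"], calls["EGFR"])
        rows[rec.patient_id] = {"label": st.label, "combined_label": st.combined_label}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "patient_id"
    return df
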