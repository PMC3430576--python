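"""Detection-rate combinatorics and minimal-panel search.

A tumor counts as *detected* by a marker panel when at least one panel marker
is positive on it; the detection rate of a panel is the detected fraction of
the cohort (the surrogate for imaging sensitivity).  Because no single
membrane marker covers all invasive breast cancers, panel construction is a
maximum-coverage problem: among candidate markers — pre-filtered by the
tumor-to-normal ratio gate (a marker whose T/N signal ratio is not above ~3
gives insufficient contrast for optical imaging) — find the smallest ordered
panel reaching a target detection rate.

The search is the standard greedy set-cover heuristic (repeatedly add the
marker with the largest marginal gain), which guarantees at least a
(1 - 1/e) fraction of the optimal coverage at equal panel size; an exhaustive
enumeration oracle is provided for small candidate sets.

The :class:`PanelSelection` model / :class:`PanelSelectionResults` pair wraps
these operations in a fit-and-summarize workflow; the module-level functions
remain the primitive API.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, MarkerInfo
from .scoring import EmptyStratumWarning, qc_filter, calls_matrix

__all__ = [
    "PanelResult",
    "ChiSquareResult",
    "DegenerateTableError",
    "detection_rate",
    "sequential_curve",
    "marginal_gain",
    "greedy_minimal_panel",
    "exhaustive_best_panel",
    "stratified_rates",
    "strata_from_cohort",
    "chi_square",
    "PanelSelection",
    "PanelSelectionResults",
]

EXHAUSTIVE_BOUND = 15


class DegenerateTableError(ValueError):
    """Contingency table has a zero row or column marginal."""


@dataclass
class PanelResult:
    """An ordered marker panel with cumulative and stratified detection rates."""

    markers: list[str]
    cumulative_rates: list[float]
    n_detected: int
    n_total: int
    stratified_rates: Optional[dict[str, float]] = None
    reason: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.markers) != len(self.cumulative_rates):
            raise ValueError("one cumulative rate per panel prefix required")
        if any(b < a - 1e-12 for a, b in zip(self.cumulative_rates, self.cumulative_rates[1:])):
            raise ValueError("cumulative detection rates must be non-decreasing")
        if self.cumulative_rates and self.n_total:
            final = self.n_detected / self.n_total
            if abs(self.cumulative_rates[-1] - final) > 1e-9:
                raise ValueError("last cumulative rate must equal n_detected/n_total")

    @property
    def detection_rate(self) -> float:
        return self.cumulative_rates[-1] if self.cumulative_rates else 0.0

    def to_dict(self) -> dict:
        return {
            "markers": self.markers,
            "cumulative_rates": self.cumulative_rates,
            "n_detected": self.n_detected,
            "n_total": self.n_total,
            "stratified_rates": self.stratified_rates,
            "reason": self.reason,
        }


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def _check_calls(calls: pd.DataFrame, panel: Iterable[str]) -> list[str]:
    panel = list(panel)
    missing = [m for m in panel if m not in calls.columns]
    if missing:
        raise KeyError(f"panel markers not in calls matrix: {missing}")
    return panel


def detection_rate(
    calls: pd.DataFrame,
    panel: Iterable[str],
    mask: Optional[pd.Series] = None,
) -> float:
    """Fraction of tumors with >= 1 positive panel marker.

    ``calls`` is a boolean patient x marker matrix; ``mask`` restricts to a
    stratum.  An empty panel detects nothing (rate 0); an empty stratum is
    flagged with :class:`EmptyStratumWarning` and yields NaN.
    """
    panel = _check_calls(calls, panel)
    sub = calls if mask is None else calls.loc[np.asarray(mask, dtype=bool)]
    n = len(sub)
    if n == 0:
        warnings.warn("empty stratum: detection rate undefined", EmptyStratumWarning, stacklevel=2)
        return float("nan")
    if not panel:
        return 0.0
    return float(sub[panel].any(axis=1).sum()) / n


def marginal_gain(calls: pd.DataFrame, panel: Sequence[str], marker: str) -> float:
    """Detection-rate gain from adding ``marker`` to ``panel`` (always >= 0)."""
    if marker in panel:
        raise ValueError(f"marker {marker!r} already in panel")
    base = detection_rate(calls, panel)
    return detection_rate(calls, list(panel) + [marker]) - base


def sequential_curve(calls: pd.DataFrame, ordered_markers: Sequence[str]) -> PanelResult:
    """Cumulative detection rates under sequential marker addition.

    The final rate is order-invariant (a union); the curve itself shows each
    marker's incremental contribution on top of all preceding ones.
    """
    ordered = list(ordered_markers)
    if not ordered:
        raise ValueError("at least one marker required")
    if len(set(ordered)) != len(ordered):
        raise ValueError("duplicate markers in sequential curve")
    _check_calls(calls, ordered)
    n = len(calls)
    covered = np.zeros(n, dtype=bool)
    rates = []
    for m in ordered:
        covered |= calls[m].to_numpy(dtype=bool)
        rates.append(float(covered.sum()) / n if n else 0.0)
    return PanelResult(ordered, rates, int(covered.sum()), n)


def _eligible(
    candidates: Sequence[str],
    registry: Optional[Mapping[str, MarkerInfo]],
    tn_gate: Optional[float],
) -> list[str]:
    if tn_gate is None:
        return list(candidates)
    if registry is None:
        raise ValueError("a marker registry is required when a T/N gate is active")
    out = []
    for m in candidates:
        info = registry[m]
        # Unknown T/N ratio: tumor-specific markers have no normal-tissue
        # signal to ratio against; they pass the gate by definition.
        if info.tn_ratio is None or info.tn_ratio > tn_gate:
            out.append(m)
    return out


def _tie_key(marker: str, registry: Optional[Mapping[str, MarkerInfo]]) -> tuple:
    ratio = math.inf
    if registry is not None and marker in registry and registry[marker].tn_ratio is not None:
        ratio = registry[marker].tn_ratio
    return (-ratio, marker)


def greedy_minimal_panel(
    calls: pd.DataFrame,
    candidates: Sequence[str],
    registry: Optional[Mapping[str, MarkerInfo]] = None,
    tn_gate: Optional[float] = 3.0,
    max_size: Optional[int] = None,
    target_rate: Optional[float] = None,
) -> PanelResult:
    """Greedy set-cover panel search under the tumor-to-normal ratio gate.

    Candidates whose known T/N ratio is <= ``tn_gate`` are excluded before the
    search (insufficient imaging contrast).  Markers are then added by largest
    marginal detection gain until ``target_rate`` is reached, ``max_size`` is
    hit, or no marker adds coverage.  Ties break by higher T/N ratio (unknown
    = tumor-specific ranks highest), then lexicographic marker id.
    """
    candidates = _check_calls(calls, candidates)
    if len(set(candidates)) != len(candidates):
        raise ValueError("duplicate candidate markers")
    eligible = _eligible(candidates, registry, tn_gate)
    if not eligible:
        return PanelResult([], [], 0, len(calls), reason="no eligible candidates")
    n = len(calls)
    covered = np.zeros(n, dtype=bool)
    cols = {m: calls[m].to_numpy(dtype=bool) for m in eligible}
    panel: list[str] = []
    rates: list[float] = []
    remaining = set(eligible)
    while remaining:
        if max_size is not None and len(panel) >= max_size:
            break
        if target_rate is not None and n and covered.sum() / n >= target_rate:
            break
        gains = {m: int((cols[m] & ~covered).sum()) for m in remaining}
        best_gain = max(gains.values())
        # ties: largest gain, then higher tn_ratio (unknown = +inf), then id
        tied = [m for m, g in gains.items() if g == best_gain]
        best = min(tied, key=lambda m: _tie_key(m, registry))
        if best_gain == 0:
            break
        covered |= cols[best]
        panel.append(best)
        rates.append(float(covered.sum()) / n if n else 0.0)
        remaining.discard(best)
    return PanelResult(panel, rates, int(covered.sum()), n)


def exhaustive_best_panel(
    calls: pd.DataFrame, candidates: Sequence[str], k: int
) -> PanelResult:
    """Best panel of size <= k by full enumeration (oracle for the greedy search).

    Refuses more than 15 candidates — enumeration over 2^|candidates| subsets;
    shrink the candidate set or use :func:`greedy_minimal_panel`.
    """
    candidates = sorted(_check_calls(calls, candidates))
    if len(candidates) > EXHAUSTIVE_BOUND:
        raise ValueError(
            f"{len(candidates)} candidates exceed the enumeration bound "
            f"({EXHAUSTIVE_BOUND}); use greedy_minimal_panel for larger sets"
        )
    n = len(calls)
    cols = {m: calls[m].to_numpy(dtype=bool) for m in candidates}
    best_subset: tuple[str, ...] = ()
    best_count = 0
    for size in range(1, min(k, len(candidates)) + 1):
        for subset in itertools.combinations(candidates, size):
            covered = np.zeros(n, dtype=bool)
            for m in subset:
                covered |= cols[m]
            count = int(covered.sum())
            # ties: larger coverage, else smaller size (outer loop order), else
            # lexicographic (combinations order) — first strict improvement wins
            if count > best_count:
                best_count = count
                best_subset = subset
    if not best_subset:
        return PanelResult([], [], 0, n, reason="no candidate adds coverage")
    return sequential_curve(calls, list(best_subset))


def strata_from_cohort(cohort: Cohort, by: str, age_split: float = 60.0) -> pd.Series:
    """Patient-id-indexed stratum labels for a clinicopathological feature.

    ``by`` is one of subtype, histology, histology_combined, grade,
    size_class, node_status, age_group.  Age dichotomizes at ``age_split``
    (default 60; patients exactly at the split go to the upper group).
    Undefined values map to the "NA" stratum.
    """
    if by == "subtype":
        from .subtyping import subtype_cohort

        return subtype_cohort(cohort)["combined_label"].rename("stratum")
    labels = {}
    for rec in cohort.records:
        if by == "age_group":
            labels[rec.patient_id] = (
                f"<{age_split:g}" if rec.age < age_split else f">={age_split:g}"
            )
        elif by == "histology_combined":
            labels[rec.patient_id] = "lobular" if rec.lobular else rec.histology
        else:
            value = getattr(rec, by)
            labels[rec.patient_id] = "NA" if value is None else str(value)
    s = pd.Series(labels, name="stratum")
    s.index.name = "patient_id"
    return s


def stratified_rates(
    calls: pd.DataFrame, panel: Sequence[str], strata: pd.Series
) -> dict[str, float]:
    """Per-stratum detection rate of a fixed panel.

    ``strata`` maps each patient in ``calls`` to a stratum label; the rates
    satisfy the conservation identity
    sum(stratum_size * rate) = overall detected count.
    """
    strata = strata.reindex(calls.index)
    if strata.isna().any():
        raise ValueError("every tumor needs a stratum label (use 'NA' explicitly)")
    return {
        str(level): detection_rate(calls, panel, mask=(strata == level))
        for level in sorted(strata.unique())
    }


def chi_square(table: Sequence[Sequence[float]] | np.ndarray) -> ChiSquareResult:
    """Pearson chi-square test of association, no continuity correction.

    statistic = sum (observed - expected)^2 / expected over an r x c table of
    non-negative counts, referred to the chi-square distribution with
    (r-1)(c-1) degrees of freedom.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise DegenerateTableError("zero row or column marginal")
    res = stats.chi2_contingency(arr, correction=False)
    return ChiSquareResult(float(res.statistic), int(res.dof), float(res.pvalue))


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------


class PanelSelection:
    """Panel-selection model over a positivity calls matrix.

    Parameters
    ----------
    calls : DataFrame
        Boolean patient x marker positivity matrix.
    registry : mapping, optional
        marker_id -> MarkerInfo; required when a T/N gate is used.
    cohort : Cohort, optional
        Kept for stratified reporting when built via :meth:`from_cohort`.

    Examples
    --------
    >>> model = PanelSelection.from_cohort(cohort)
    >>> res = model.fit(tn_gate=3.0, target_rate=0.8)
    >>> print(res.summary())
    """

    def __init__(
        self,
        calls: pd.DataFrame,
        registry: Optional[Mapping[str, MarkerInfo]] = None,
        cohort: Optional[Cohort] = None,
    ) -> None:
        self.calls = calls.astype(bool)
        self.registry = registry
        self.cohort = cohort

    @classmethod
    def from_cohort(cls, cohort: Cohort, qc: bool = True) -> "PanelSelection":
        """Score a cohort (after the missing-staining QC filter) into a model."""
        if qc:
            cohort, _ = qc_filter(cohort)
        return cls(calls_matrix(cohort), cohort.registry, cohort)

    def fit(
        self,
        method: str = "greedy",
        candidates: Optional[Sequence[str]] = None,
        tn_gate: Optional[float] = 3.0,
        max_size: Optional[int] = None,
        target_rate: Optional[float] = None,
        k: Optional[int] = None,
    ) -> "PanelSelectionResults":
        cand = list(candidates) if candidates is not None else list(self.calls.columns)
        if method == "greedy":
            panel = greedy_minimal_panel(
                self.calls, cand, self.registry, tn_gate, max_size, target_rate
            )
        elif method == "exhaustive":
            eligible = _eligible(cand, self.registry, tn_gate)
            if not eligible:
                panel = PanelResult([], [], 0, len(self.calls), reason="no eligible candidates")
            else:
                panel = exhaustive_best_panel(
                    self.calls, eligible, k if k is not None else len(eligible)
                )
        else:
            raise ValueError("method must be 'greedy' or 'exhaustive'")
        return PanelSelectionResults(self, panel, method=method, tn_gate=tn_gate)


class PanelSelectionResults:
    """Fitted panel: ordered markers, cumulative rates, stratified reporting."""

    def __init__(
        self,
        model: PanelSelection,
        panel: PanelResult,
        method: str,
        tn_gate: Optional[float],
    ) -> None:
        self.model = model
        self.panel = panel
        self.method = method
        self.tn_gate = tn_gate

    @property
    def markers(self) -> list[str]:
        return self.panel.markers

    @property
    def cumulative_rates(self) -> list[float]:
        return self.panel.cumulative_rates

    @property
    def detection_rate(self) -> float:
        return self.panel.detection_rate

    def stratified(self, by: str = "subtype", ductal_only: Optional[bool] = None) -> dict[str, float]:
        """Per-stratum detection rates; subtype reports default to ductal-only."""
        if self.model.cohort is None:
            raise ValueError("stratified reporting needs the model built from_cohort")
        cohort = self.model.cohort
        if ductal_only is None:
            ductal_only = by == "subtype"
        if ductal_only:
            cohort = cohort.subset(lambda r: r.histology == "ductal")
        strata = strata_from_cohort(cohort, by)
        calls = self.model.calls.loc[strata.index]
        return stratified_rates(calls, self.markers, strata)

    def summary(self) -> str:
        n = self.panel.n_total
        lines = [
            "Panel selection results",
            "=" * 56,
            f"method: {self.method}    T/N gate: "
            + (f"> {self.tn_gate:g}" if self.tn_gate is not None else "none"),
            f"tumors: {n}    detected: {self.panel.n_detected} "
            f"({100 * self.detection_rate:.1f}%)",
            "-" * 56,
            f"{'step':>4}  {'marker':<12}{'gain':>8}{'cumulative':>12}",
        ]
        prev = 0.0
        for i, (m, r) in enumerate(zip(self.markers, self.cumulative_rates), 1):
            lines.append(f"{i:>4}  {m:<12}{100 * (r - prev):>7.1f}%{100 * r:>11.1f}%")
            prev = r
        if self.panel.reason:
            lines.append(f"note: {self.panel.reason}")
        lines.append("=" * 56)
        return "\n".join(lines)

    def plot_curve(self, ax=None):
        """Step plot of cumulative detection rate vs panel size."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs = range(1, len(self.markers) + 1)
        ax.step(xs, [100 * r for r in self.cumulative_rates], where="post", marker="o")
        ax.set_xticks(list(xs))
        ax.set_xticklabels(self.markers, rotation=45, ha="right")
        ax.set_ylabel("cumulative detection rate (%)")
        ax.set_ylim(0, 100)
        return ax
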