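"""Seeded generators for synthetic IHC cohorts and stained-tissue tile pairs.

The cohort generator emulates the statistical structure of a 483-patient
invasive breast cancer tissue-microarray study: histology mix (ductal /
lobular / other), molecular-subtype mix within ductal cancers, per-stratum
marker positivity marginals, per-marker missing-staining rates, 3-core
sampling with a configurable between-core heterogeneity probability, and
clinicopathological margins (grade, size, nodal status, age).  Every draw is
a pure function of the config (including its seed), and the generator returns
its own ground truth so that downstream scoring can be checked call-for-call.

Markers are drawn independently of each other *within* a stratum: only
marginal positivity frequencies are published for the reference study, so any
joint (co-expression) structure would be invention.  Joint quantities
computed from simulated cohorts (e.g. panel detection rates) are therefore
model-based sanity values, not reproductions.

The tile generator places cells by a homogeneous spatial Poisson process and
renders each as a dim nuclear disc plus a bright membrane annulus with
Gaussian intensity noise, so the membrane quantifier can be validated against
a known tumor-to-normal ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import (
    Cohort,
    CoreScore,
    MarkerAssay,
    MarkerInfo,
    TumorRecord,
    default_registry,
)
from .tn import MEMBRANE_R_INNER, MEMBRANE_R_OUTER, UndefinedRatioError

__all__ = [
    "CohortConfig",
    "TileConfig",
    "TilePair",
    "ConfigError",
    "default_marker_probs",
    "generate_cohort",
    "generate_tile",
    "generate_tile_pair",
]


class ConfigError(ValueError):
    """A generator configuration violates a probability or geometry constraint."""


MARKER_STRATA = (
    "ductal_luminal",
    "ductal_her2_driven",
    "ductal_basal_tn",
    "lobular_classical",
    "lobular_pleomorphic",
    "other",
)


def _pleomorphic_split(p_base: float, weight_classical: float, odds_mult: float) -> tuple[float, float]:
    """Split a lobular marginal into classical/pleomorphic probabilities.

    Pleomorphic lobular cancers express membrane targets more often than
    classical ones; the split applies a fixed odds multiplier to the
    pleomorphic group while keeping the weighted lobular marginal exactly at
    ``p_base``.
    """
    if p_base <= 0.0:
        return 0.0, 0.0
    if p_base >= 1.0:
        return 1.0, 1.0
    w_c, w_p = weight_classical, 1.0 - weight_classical

    def pleo(p_c: float) -> float:
        odds = odds_mult * p_c / (1.0 - p_c)
        return odds / (1.0 + odds)

    f = lambda p_c: w_c * p_c + w_p * pleo(p_c) - p_base
    lo, hi = 1e-12, 1.0 - 1e-12
    p_c = optimize.brentq(f, lo, hi)
    return float(p_c), float(pleo(p_c))


def default_marker_probs(pleomorphic_odds_multiplier: float = 3.0) -> dict[str, dict[str, float]]:
    """Per-stratum marker positivity defaults from the reference study tables."""
    from .reference import reference_counts

    ref = reference_counts()
    markers = list(ref["overall"]["counts"])
    probs: dict[str, dict[str, float]] = {s: {} for s in MARKER_STRATA}
    sub_sizes = ref["by_subtype"]["sizes"]
    for j, sub in enumerate(("luminal", "her2_driven", "basal_tn")):
        for m in markers:
            probs[f"ductal_{sub}"][m] = ref["by_subtype"]["positive"][m][j] / sub_sizes[sub]
    hist_sizes = ref["by_histology"]["sizes"]
    w_classical = 58.0 / 126.0
    for m in markers:
        p_lob = ref["by_histology"]["positive"][m][1] / hist_sizes["lobular"]
        p_c, p_p = _pleomorphic_split(p_lob, w_classical, pleomorphic_odds_multiplier)
        probs["lobular_classical"][m] = p_c
        probs["lobular_pleomorphic"][m] = p_p
        probs["other"][m] = ref["by_histology"]["positive"][m][2] / hist_sizes["other"]
    return probs


def _default_missing_probs() -> dict[str, float]:
    from .reference import reference_counts

    ref = reference_counts()
    n = ref["cohort_size"]
    return {m: c[2] / n for m, c in ref["overall"]["counts"].items()}


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort; defaults mirror the reference study."""

    n_patients: int = 483
    seed: int = 0
    histology_probs: dict[str, float] = field(
        default_factory=lambda: {"ductal": 0.660, "lobular": 0.261, "other": 0.079}
    )
    #: classical vs pleomorphic fraction among lobular cancers (58/68 split).
    lobular_classical_frac: float = 58.0 / 126.0
    #: odds multiplier for pleomorphic vs classical marker positivity.
    pleomorphic_odds_multiplier: float = 3.0
    ductal_subtype_probs: dict[str, float] = field(
        default_factory=lambda: {
            "luminal": 242.0 / 319.0,
            "her2_driven": 20.0 / 319.0,
            "basal_tn": 57.0 / 319.0,
        }
    )
    #: stratum -> marker -> P(tumor truly positive); None = study defaults.
    marker_probs: Optional[dict[str, dict[str, float]]] = None
    #: marker -> P(assay fully missing); None = study defaults.
    missing_probs: Optional[dict[str, float]] = None
    grade_probs: dict[str, float] = field(
        default_factory=lambda: {"1": 89 / 483, "2": 169 / 483, "3": 219 / 483, "NA": 6 / 483}
    )
    size_probs: dict[str, float] = field(
        default_factory=lambda: {
            "<=2cm": 206 / 483,
            ">2-<=5cm": 219 / 483,
            ">5cm": 49 / 483,
            "NA": 9 / 483,
        }
    )
    node_probs: dict[str, float] = field(
        default_factory=lambda: {"negative": 225 / 483, "positive": 232 / 483, "NA": 26 / 483}
    )
    age_mean: float = 60.0
    age_sd: float = 12.0
    age_range: tuple[float, float] = (28.0, 88.0)
    # hormone-receptor marginals; luminal tumors are forced to ER and/or PR
    # positive, non-luminal ductal tumors to both negative
    er_prob_lobular: float = 0.90
    er_prob_other: float = 0.70
    er_prob_luminal: float = 0.95
    pr_prob_luminal: float = 0.70
    pr_prob_lobular: float = 0.65
    pr_prob_other: float = 0.55
    # core-score model
    p_core3_pos: float = 0.6  # P(core = 3 | tumor positive), DAKO markers
    p_core1_neg: float = 0.2  # P(core = 1 | tumor negative)
    heterogeneity: float = 0.05  # P(a core is drawn from the discordant class)
    percent_pos_range: tuple[float, float] = (40.0, 95.0)
    percent_neg_range: tuple[float, float] = (0.0, 30.0)

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        for name, vec in (
            ("histology_probs", self.histology_probs),
            ("ductal_subtype_probs", self.ductal_subtype_probs),
            ("grade_probs", self.grade_probs),
            ("size_probs", self.size_probs),
            ("node_probs", self.node_probs),
        ):
            total = sum(vec.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1 (got {total})")
            if any(not (0.0 <= p <= 1.0) for p in vec.values()):
                raise ConfigError(f"{name} entries must lie in [0, 1]")
        if self.marker_probs is None:
            self.marker_probs = default_marker_probs(self.pleomorphic_odds_multiplier)
        if self.missing_probs is None:
            self.missing_probs = _default_missing_probs()
        for stratum, mp in self.marker_probs.items():
            for m, p in mp.items():
                if not (0.0 <= p <= 1.0):
                    raise ConfigError(f"marker prob {stratum}/{m} = {p} outside [0, 1]")
        for m, p in self.missing_probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"missing prob {m} = {p} outside [0, 1]")
        for name, p in (
            ("heterogeneity", self.heterogeneity),
            ("p_core3_pos", self.p_core3_pos),
            ("p_core1_neg", self.p_core1_neg),
        ):
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")

    @property
    def markers(self) -> list[str]:
        assert self.marker_probs is not None
        first = next(iter(self.marker_probs.values()))
        return list(first)


def _choice(rng: np.random.Generator, probs: dict[str, float]) -> str:
    keys = list(probs)
    return keys[rng.choice(len(keys), p=np.array([probs[k] for k in keys]) / sum(probs.values()))]


def _draw_cores(
    rng: np.random.Generator,
    cfg: CohortConfig,
    info: MarkerInfo,
    positive: bool,
) -> tuple[CoreScore, ...]:
    """Three cores consistent with the drawn tumor-level truth.

    With heterogeneity 0 the cores always re-score to the drawn truth under
    the marker's positivity rule: positive default/any-core tumors draw cores
    in {2, 3}, HER2-positive tumors draw 3 on every concordant core (the
    strict rule), negative tumors draw {0, 1}; Mammaglobin draws percentages
    strictly above/below the 35% cut.  A heterogeneous core is drawn from the
    discordant class instead.
    """
    cores = []
    for _ in range(3):
        discordant = rng.random() < cfg.heterogeneity
        if info.positivity_rule == "percent_cells":
            lo, hi = (
                cfg.percent_neg_range if positive == discordant else cfg.percent_pos_range
            )
            cores.append(CoreScore(percent=float(rng.uniform(lo, hi))))
            continue
        concordant_positive = positive != discordant
        if concordant_positive:
            if info.positivity_rule == "her2_strict" and not discordant:
                val = 3
            else:
                val = 3 if rng.random() < cfg.p_core3_pos else 2
        else:
            val = 1 if rng.random() < cfg.p_core1_neg else 0
        cores.append(CoreScore(dako=int(val)))
    return tuple(cores)


def generate_cohort(
    config: CohortConfig,
    registry: Optional[dict[str, MarkerInfo]] = None,
) -> tuple[Cohort, pd.DataFrame]:
    """Draw a synthetic cohort plus its per-tumor ground-truth positivity matrix.

    Ground truth columns: one boolean per marker (the drawn tumor-level
    positivity), plus histology, marker stratum, subtype, er, pr.  The same
    config (same seed) yields a byte-identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    if registry is None:
        registry = default_registry()
    markers = config.markers
    for m in markers:
        if m not in registry:
            raise ConfigError(f"marker {m!r} has probabilities but no registry entry")

    lo, hi = config.age_range
    a, b = (lo - config.age_mean) / config.age_sd, (hi - config.age_mean) / config.age_sd
    ages = stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=config.n_patients, random_state=rng
    )

    records: list[TumorRecord] = []
    truth_rows: list[dict] = []
    width = max(4, len(str(max(config.n_patients, 1))))
    for i in range(config.n_patients):
        hist_group = _choice(rng, config.histology_probs)
        if hist_group == "lobular":
            histology = (
                "lobular_classical"
                if rng.random() < config.lobular_classical_frac
                else "lobular_pleomorphic"
            )
            stratum = histology
        elif hist_group == "ductal":
            histology = "ductal"
            subtype = _choice(rng, config.ductal_subtype_probs)
            stratum = f"ductal_{subtype}"
        else:
            histology = "other"
            stratum = "other"

        # tumor-level marker truths, independent across markers within stratum
        truth = {m: bool(rng.random() < config.marker_probs[stratum][m]) for m in markers}

        # hormone receptors, consistent with the drawn ductal subtype
        if histology == "ductal":
            if subtype == "luminal":
                er = rng.random() < config.er_prob_luminal
                pr = rng.random() < config.pr_prob_luminal
                if not (er or pr):
                    er = True
            else:
                er = pr = False
        elif hist_group == "lobular":
            er = rng.random() < config.er_prob_lobular
            pr = rng.random() < config.pr_prob_lobular
        else:
            er = rng.random() < config.er_prob_other
            pr = rng.random() < config.pr_prob_other

        grade_key = _choice(rng, config.grade_probs)
        size_key = _choice(rng, config.size_probs)
        node_key = _choice(rng, config.node_probs)
        rec = TumorRecord(
            patient_id=f"P{i + 1:0{width}d}",
            age=float(round(ages[i], 1)),
            histology=histology,
            grade=None if grade_key == "NA" else int(grade_key),
            size_class=None if size_key == "NA" else size_key,
            node_status=None if node_key == "NA" else node_key,
            er_positive=bool(er),
            pr_positive=bool(pr),
        )
        for m in markers:
            if rng.random() < config.missing_probs.get(m, 0.0):
                rec.assays[m] = MarkerAssay(m, (CoreScore.missing(),) * 3)
            else:
                rec.assays[m] = MarkerAssay(m, _draw_cores(rng, config, registry[m], truth[m]))
        records.append(rec)
        row = {"patient_id": rec.patient_id, "histology": histology, "stratum": stratum,
               "er": bool(er), "pr": bool(pr)}
        row.update(truth)
        truth_rows.append(row)

    cohort = Cohort(records, {m: registry[m] for m in markers})
    truth_df = pd.DataFrame(
        truth_rows,
        columns=["patient_id", "histology", "stratum", "er", "pr"] + markers,
    )
    if len(truth_df):
        truth_df = truth_df.set_index("patient_id")
    else:
        truth_df.index.name = "patient_id"
    return cohort, truth_df


# ---------------------------------------------------------------------------
# Stained-tissue tiles
# ---------------------------------------------------------------------------


@dataclass
class TileConfig:
    """Geometry and intensity model of one synthetic stained-tissue tile.

    Scale is 0.5 um/px; a cell is a dim nuclear disc plus a bright membrane
    annulus of radii [r_inner, r_outer] px.  Intensities are 8-bit after
    clipping.
    """

    width: int = 256
    height: int = 256
    cell_density: float = 8e-4  # cells per px^2 (~52 cells on a 256x256 tile)
    ring_intensity_mean: float = 200.0
    ring_intensity_sd: float = 15.0
    background_mean: float = 10.0
    background_sd: float = 3.0
    nucleus_radius: float = 2.0
    nucleus_intensity: float = 60.0
    r_inner: float = MEMBRANE_R_INNER
    r_outer: float = MEMBRANE_R_OUTER
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ConfigError("tile dimensions must be positive")
        if self.cell_density <= 0:
            raise ConfigError("cell_density must be positive")
        if self.cell_density * np.pi * self.r_outer**2 >= 1.0:
            raise ConfigError(
                "cell_density so high that cells cannot be placed without total overlap"
            )
        if not (0 < self.r_inner < self.r_outer):
            raise ConfigError("need 0 < r_inner < r_outer")
        for name, v in (("ring_intensity_mean", self.ring_intensity_mean),
                        ("background_mean", self.background_mean)):
            if not (0.0 <= v <= 255.0):
                raise ConfigError(f"{name} must lie in the 8-bit range")


@dataclass
class TilePair:
    tumor: np.ndarray
    normal: np.ndarray
    true_ratio: float
    tumor_centers: np.ndarray
    normal_centers: np.ndarray


def generate_tile(config: TileConfig, rng: Optional[np.random.Generator] = None):
    """Render one tile; returns (uint8 image, (n, 2) array of cell centers)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    img = rng.normal(config.background_mean, config.background_sd, size=(h, w))

    n_cells = int(rng.poisson(config.cell_density * h * w))
    # keep whole rings inside the tile (+1 guards the rounding of centers)
    margin = float(int(np.ceil(config.r_outer)) + 1)
    if h <= 2 * margin or w <= 2 * margin:
        raise ConfigError("tile too small for the membrane radius")
    centers = np.column_stack(
        [
            rng.uniform(margin, h - margin, size=n_cells),
            rng.uniform(margin, w - margin, size=n_cells),
        ]
    )

    r_out_i = int(np.ceil(config.r_outer))
    yy, xx = np.mgrid[-r_out_i : r_out_i + 1, -r_out_i : r_out_i + 1]
    d2 = yy**2 + xx**2
    ring_stamp = (d2 >= config.r_inner**2) & (d2 <= config.r_outer**2)
    nuc_stamp = d2 <= config.nucleus_radius**2
    for cy, cx in centers:
        cy_i, cx_i = int(round(cy)), int(round(cx))
        y0, x0 = cy_i - r_out_i, cx_i - r_out_i
        sl = np.s_[y0 : y0 + ring_stamp.shape[0], x0 : x0 + ring_stamp.shape[1]]
        patch = img[sl]
        nucleus = rng.normal(config.nucleus_intensity, config.background_sd, size=patch.shape)
        ring = rng.normal(config.ring_intensity_mean, config.ring_intensity_sd, size=patch.shape)
        patch[:] = np.where(nuc_stamp, np.maximum(patch, nucleus), patch)
        patch[:] = np.where(ring_stamp, np.maximum(patch, ring), patch)
    return np.clip(img, 0, 255).astype(np.uint8), centers


def generate_tile_pair(tumor_cfg: TileConfig, normal_cfg: TileConfig) -> TilePair:
    """Paired tumor/normal tiles with a known ground-truth T/N ratio.

    The true ratio applies the (intensity x cellularity / area) formula to the
    configured ring intensities and the realized cell counts, i.e. it is the
    value a perfect membrane quantifier would recover from these very tiles.
    """
    tumor, t_centers = generate_tile(tumor_cfg)
    normal, n_centers = generate_tile(normal_cfg)
    area_t = float(tumor_cfg.width * tumor_cfg.height)
    area_n = float(normal_cfg.width * normal_cfg.height)
    num = tumor_cfg.ring_intensity_mean * len(t_centers) / area_t
    den = normal_cfg.ring_intensity_mean * len(n_centers) / area_n
    if den <= 0:
        raise UndefinedRatioError("normal tile has no cells; true ratio undefined")
    return TilePair(tumor, normal, num / den, t_centers, n_centers)
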