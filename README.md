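# panelcover

**Minimal membrane-marker panels for molecular imaging of invasive breast
cancer.**

No single membrane protein is expressed by all invasive breast cancers, so
antibody-based optical imaging (e.g. near-infrared fluorescent tracers) needs
a *panel* of targeted probes. Because every additional tracer is expensive to
develop, the question is combinatorial: what is the smallest panel of
membrane markers such that the largest possible fraction of tumors expresses
at least one of them — counting only markers whose signal in tumor
sufficiently exceeds the normal-breast background?

`panelcover` implements that screening pipeline for
immunohistochemistry (IHC) data from tissue microarrays (TMAs), for
pathologists and imaging researchers who want to evaluate candidate tracer
panels on their own cohorts:

1. **Scoring** (`panelcover.scoring`) — per-core DAKO 0/1+/2+/3+ membrane
   scores are averaged per tumor (3 cores each) and called positive at 2+/3+,
   with the strict 3+ rule for HER2, a single-positive-core rule for the
   focally expressed hypoxia markers GLUT1 and CAIX, and a >35 %
   stained-cells rule for Mammaglobin. Missing stainings score negative;
   patients missing more than 3 markers are excluded.
2. **Subtyping** (`panelcover.subtyping`) — the IHC surrogate of the
   molecular subtypes: luminal (ER and/or PR+), HER2-driven (ER−, PR−,
   HER2+), basal (ER−, PR−, HER2−, EGFR+), triple negative (all negative).
3. **Tumor-to-normal quantification** (`panelcover.tn`) — per tissue region,
   T/N = (membrane intensity × cellularity / area)_tumor over the same
   quantity in normal breast; a mean ratio strictly above 3 is taken as
   sufficient imaging contrast. A reproducible membrane quantifier extracts
   the triple from single-channel tiles by annulus matched filtering.
4. **Panel search** (`panelcover.panel`) — detection rate of a panel =
   fraction of tumors positive for ≥1 panel marker. Candidates failing the
   T/N gate are excluded; the panel is then grown by greedy set cover
   (guaranteed ≥ (1 − 1/e) of the optimal coverage at equal size), with an
   exhaustive oracle for ≤15 candidates, stratified reporting, and Pearson
   chi-square comparisons.
5. **Synthetic data** (`panelcover.simulate`) — seeded generators for
   cohorts with the reference study's marginal structure (483 patients, 66 %
   ductal / 26 % lobular, subtype mix 242:20:57 within ductal, per-stratum
   marker positivity, per-marker missingness, 3-core heterogeneity) and for
   paired stained-tissue tiles with known ground-truth T/N ratio.

## Worked example

```python
from panelcover import CohortConfig, PanelSelection, generate_cohort

cohort, truth = generate_cohort(CohortConfig(n_patients=483, seed=1))
model = PanelSelection.from_cohort(cohort)     # QC + scoring
res = model.fit(tn_gate=3.0)                   # greedy search under the T/N gate
print(res.summary())
```

```
Panel selection results
========================================================
method: greedy    T/N gate: > 3
tumors: 483    detected: 407 (84.3%)
--------------------------------------------------------
step  marker          gain  cumulative
   1  CD44v6         55.7%       55.7%
   2  GLUT1          13.0%       68.7%
   3  CAIX            6.8%       75.6%
   4  EGFR            4.8%       80.3%
   5  IGF1R           1.9%       82.2%
   6  HER2            1.4%       83.6%
   7  MET             0.6%       84.3%
========================================================
```

CD44v6 — the only less tumor-specific marker whose measured T/N ratio
(3.93) clears the gate — covers over half the cohort on its own; the highly
tumor-specific markers (no normal-breast staining, so they pass the gate by
definition) add the rest, with sharply diminishing returns. Note the
simulator draws markers independently within a stratum, so joint detection
rates are model-based sanity values, not reproductions of any real cohort
(see `docs/methods.md`). Stratified rates come from the same results object:

```python
res.stratified("subtype")   # ductal-only by default
# {'basal_tn': 0.948, 'her2_driven': 1.0, 'luminal': 0.838}
```

The same workflow is available from the shell: `panelcover simulate`,
`score`, `subtype`, `panel`, `tnr`, and `simulate-tiles` (see `--help`).

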