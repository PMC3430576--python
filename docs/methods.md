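# Methods

This note documents the models, rules and numerical choices behind
`panelcover`, in the package's own terms: what is computed, under which
assumptions, and what the synthetic-data validation does and does not show.

## Scoring model

Membranous staining is graded per tissue core on the ordinal DAKO scale
(0, 1+, 2+, 3+). Each tumor contributes up to 3 cores (0.6 mm TMA
cylinders); between-core heterogeneity is absorbed by averaging the
available core scores per tumor.

The average of ordinal categories is generally fractional, and a categorical
call is needed, so the mean is mapped back to a category by rounding
half-away-from-zero. The package's positivity rules are then:

* **default** — rounded category ∈ {2, 3} is positive. Tumors at 1+ are
  deliberately negative: that staining level is assumed to give insufficient
  signal-to-noise for imaging.
* **HER2** — rounded category = 3 only (the strict clinical convention).
  A documented consequence of mean-then-round: cores (3, 3, 2) average 2.67,
  round to 3, and call positive.
* **GLUT1, CAIX** — hypoxia-driven markers expressed focally; a tumor is
  positive when *any single* core is 2+/3+. (Mean-based rules would dilute
  focal expression across cores.)
* **Mammaglobin** — intensity grading is unreliable under its strong
  intra-tumor heterogeneity, so the per-core estimate is the percentage of
  membrane-stained tumor cells; the tumor is positive when the mean
  percentage is strictly greater than 35.

Missing handling: single missing cores are dropped from the mean, not
imputed. A marker with all cores missing is called negative (conservative —
can only underestimate positivity), and patients with more than 3 fully
missing markers are excluded before analysis. An alternative reading of the
per-tumor "average score" as a mode rather than a mean cannot be excluded;
mean-then-round is declared as this package's operationalization and the one
its tests pin down.

## Subtype surrogate

From four binary inputs (ER, PR, HER2, EGFR — the latter two produced by the
scoring rules above): luminal if ER and/or PR positive; otherwise HER2-driven
if HER2 positive; otherwise basal if EGFR positive; otherwise triple
negative. The definitions are nested complements, so this precedence is the
only consistent reading, and classification is total on all 16 input
combinations. Basal and triple negative are merged into one reporting
stratum (`basal_tn`). ER/PR enter the pipeline as booleans: hormone-receptor
calls are nuclear, made upstream, and no membrane-DAKO cut-off applies to
them. Because missing HER2/EGFR score negative, every tumor is classifiable.
Subtype-stratified reports default to ductal histology only, the stratum for
which reference subtype margins exist.

## Detection rate and panel search

A panel "detects" a tumor when at least one panel marker is positive — the
IHC surrogate for imaging sensitivity, deliberately ignoring tracer
pharmacokinetics. Panel construction is maximum coverage: candidates whose
measured T/N ratio is ≤ 3 are removed first (insufficient contrast), then
markers are added greedily by largest marginal detection gain until a target
rate, a size cap, or zero gain. Ties break by higher T/N ratio, then
lexicographic marker id; markers with *unknown* T/N ratio are the highly
tumor-specific ones (no normal-breast signal to ratio against), which pass
the gate by definition and rank above any finite ratio in ties. An
exhaustive enumeration oracle (≤ 15 candidates) backs the greedy search in
tests; greedy coverage is guaranteed ≥ (1 − 1/e) of the optimum at equal
size. Registry defaults for the T/N ratios of the less-specific markers use
the immunofluorescence quantitation (CD44v6 3.93, MUC1 2.74, Mammaglobin
1.54, CAXII 1.66) — preferred because chromogenic IHC amplification is
non-linear — and the IHC value for TfR (2.4; undetectable by IF). Under
these defaults CD44v6 is the only less-specific marker clearing the gate.

Associations between categorical variables use the uncorrected Pearson
chi-square statistic (no Yates continuity correction), with
df = (rows−1)(cols−1); tables with a zero marginal are rejected as
degenerate rather than patched.

The age dichotomy in stratified reporting is at exactly 60 years, with
patients aged exactly 60 in the upper group.

## Tumor-to-normal quantification

Per tissue region, signal density = mean membrane intensity × cell count /
area; the T/N ratio divides the tumor region's signal density by the normal
region's. It is homogeneous of degree +1 in tumor intensity and −1 in normal
intensity, invariant to area units, and undefined (an error, not infinity)
when the normal region has zero signal. Per-marker results are summarized as
mean ± SEM (sample n−1 standard deviation over √n), and the imaging gate is
strict: mean ratio > 3.

The tile quantifier works on 8-bit single-channel tiles at 0.5 µm/px where
"intensity" means stain signal (higher = more stain; no brightfield
inversion). The membrane compartment is a union of annuli with inner radius
3 px and outer radius 6 px around cell centers; mean intensity is taken over
that mask and area is the full tile. Cell centers are detected, when a
nuclear channel is available, as local maxima of the σ = 2 px
Gaussian-smoothed channel above an Otsu threshold. When only the membrane
channel exists, Gaussian smoothing fails structurally: a blurred 3–6 px ring
remains crater-shaped at small σ (maxima on the ring, over-counting) and
merges near-neighbor cells at large σ (~20 % undercount at the default cell
density, worse at higher density). Membrane-channel detection therefore uses
normalized cross-correlation against an ideal annulus template (a matched
filter), whose response peaks sharply at each cell center; peaks ≥ 0.4
correlation with minimum separation 3 px are accepted. On synthetic tiles
this recovers 93–100 % of cells and a median T/N relative error of ~2–3 %.

## Synthetic data

The cohort generator reproduces the *marginal* structure of a 483-patient
invasive breast cancer TMA study: histology probabilities 0.660 / 0.261 /
0.079 (ductal / lobular / other), subtype mix 242:20:57 within ductal,
per-stratum marker positivity equal to the reference tables' proportions,
per-marker missing-staining probabilities from the overall table, and
grade / size / nodal margins. Age is truncated-normal, mean 60 years,
SD 12, clipped to 28–88 (the reference reports only mean and range; SD 12 is
a typical breast-cancer-cohort spread). Lobular cases split 58:68 into
classical vs pleomorphic, with a pleomorphic odds multiplier (default 3,
matching the roughly 3-fold higher observed detection of pleomorphic
tumors) applied so that the *combined* lobular marginal is preserved exactly
(the classical probability is solved by root-finding). ER/PR are drawn to be
consistent with the subtype strata: luminal tumors are forced ER and/or PR
positive; non-luminal ductal tumors are both negative; lobular/other use
marginal ER probabilities of 0.90 / 0.70 (lobular cancers are predominantly
hormone-receptor positive).

Core scores are drawn conditionally on the tumor-level truth so that, with
heterogeneity h = 0 and no missingness, re-scoring recovers the truth
exactly for every rule: positive tumors draw cores in {2, 3} (all 3s for
HER2), negative tumors in {0, 1}, Mammaglobin draws percentages strictly
above/below the 35 cut. With probability h (default 0.05) a core is drawn
from the discordant class instead, emulating intra-tumor heterogeneity; a
rounded mean can then flip the call, which is the intended noise.

**Key modelling limitation:** markers are independent within a stratum. Only
marginal frequencies are published for the reference cohort; any
co-expression model would be invention. Real membrane markers are positively
correlated (shared hypoxia and proliferation programs), so simulated *joint*
quantities — union detection rates, greedy panel compositions — are
systematically optimistic and serve as sanity bands only. Passing tests
validate the pipeline mechanics and marginal calibration, not the joint
detection rates of any real cohort; the published headline rates are not
reproducible from printed marginals and are not asserted anywhere.

The tile generator places cells by a homogeneous spatial Poisson process
(margin-inset so rings stay inside the tile; configurations where mean ring
coverage per cell ≥ 1 are rejected as total overlap), renders dim nuclear
discs (intensity 60) and bright membrane annuli (default 200 ± 15 over
background 10 ± 3), and reports as ground truth the ratio a perfect
quantifier would recover: configured ring intensity × realized cell count /
area, tumor over normal. Generators are pure functions of their configs:
same seed, byte-identical output.

## Fixture cohorts

For exact frequency checks the package ships the reference study's printed
counts (`panelcover/data/reference_counts.json`) and builds deterministic
cohorts encoding them marker by marker. Three printed cells are internally
inconsistent and corrected as documented in the JSON (a negative count
exceeding the row total by 2; a positive count contradicting both its
percentage and the subtype subtotals; and two percentages that disagree with
their own printed counts at one decimal — the counts are kept and the
count-derived percentages asserted). Because markers are assigned
independently, fixture cohorts have no meaningful joint structure and are
never used for detection rates. The per-histology and per-subtype tables are
mutually inconsistent for TfR and CD44v6 (subtype subtotals do not sum to
the histology column), so separate fixture cohorts encode each table.

## Problem sizes in tests

The default suite uses cohorts of 250–5000 patients (5000 for the 99 %
binomial-CI calibration check), 200 random panel instances of ≤ 12 markers ×
≤ 40 tumors for the combinatorial guarantees, and 20 seeded 256 × 256 tile
pairs spanning true ratios 1–5 for T/N recovery; the whole suite runs in
well under a minute.
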