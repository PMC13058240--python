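# Methods

This note documents the models, estimators, numerical choices and default
parameters behind `dyetrack`, and what the synthetic-data tests do and do
not establish about real instrument data.

## Assay model

Two bacterial competitors are mixed in coculture after one of them has been
stained with a transient membrane dye. The dye is partitioned between
daughter cells, so the expected per-cell fluorescence of the stained
lineage halves once per division; unstained cells show only cellular
autofluorescence. An imaging flow cytometer records per-cell intensities
(dye channel, autofluorescence channel) and brightfield area for a fixed
number of events per sample. Monocultures of each competitor — stained and
unstained — run in parallel and provide labelled controls.

## Gating

Cells are separated from other objects by a polygon gate on the
(dye, autofluorescence) intensity plane and from much larger ciliate
predators by a closed brightfield-area window (default 2–150 a.u.). The
shipped default polygon is the seven-vertex cell gate used with the
default channel layout; both gates can be replaced from a config file.

Membership is boundary-inclusive. The implementation is ray casting with an
explicit on-edge test at relative tolerance 1e-9 (scaled by the largest
vertex coordinate); the half-open crossing rule makes interior/exterior
classification exact for points off the boundary, and the edge test
resolves the boundary deterministically. The test suite checks the
predicate against an independent winding-number oracle on random point
clouds; only points lying exactly on an edge may legitimately differ, and
those are asserted inclusive.

Gating is idempotent, order-preserving, and logs in/out counts to each
table's provenance list. If the autofluorescence channel was not acquired,
the polygon gate is skipped (logged) and only the area gate applies.

## Threshold derivation

Candidate thresholds are the unique observed intensities pooled over the
stained and unstained control samples, plus one sentinel above the maximum.
This is exhaustive: any threshold strictly between two consecutive observed
values yields identical confusion counts. The classification rule is
inclusive (stained iff intensity ≥ threshold) everywhere in the package.
Negative and zero intensities — common after instrument background
subtraction — are legal candidate and data values throughout.

Two selection criteria are provided:

* `closest_topleft` (default): minimise √(FPR² + (1−TPR)²);
* `balanced_accuracy`: maximise (TPR + TNR)/2.

Ties are broken toward lower FPR, then toward the higher threshold,
i.e. toward not over-calling stained cells; with candidate sets built from
data, exact ties occur mostly in tiny or degenerate samples, but the rule
makes results reproducible bit-for-bit. The report carries TPR, TNR, FPR,
accuracy (proportion correct at the control class sizes), and the
TPR/TNR average, plus optional hold-out validation metrics.

Thresholds can be derived per time point or as a *general* threshold
pooling all time points of the controls (default). Because the pooled
sample spans the gradual dye decay, the general threshold sits lower than a
fresh-control threshold and tolerates later time points much better; the
per-time-point mode exists for diagnostic comparison. Similarly, separate
per-stained-competitor thresholds (each derived against the unstained
control of the coculture partner) are compared with a single unified
threshold by `compare_threshold_strategies`; with unequal competitor
autofluorescence the separate strategy dominates.

## Frequency estimation

The stained fraction of gated coculture events is a binomial proportion;
intervals are 95% Wilson score intervals (well-behaved at 0 and 1, unlike
Wald). The optional Rogan–Gladen correction
(p_obs − FPR)/(TPR − FPR), clipped to [0, 1], is reported alongside the raw
fraction and requires TPR > FPR. Frequencies are always reported for a
named focal competitor; when the focal competitor is the unstained one the
complement is taken, which avoids sign confusion in downstream trends.

Plate-based estimates use the dilution-series rule: plates with a total
colony count in the closed window [30, 300] are evaluable; among those the
plate with the highest total is used (deterministic tie-break toward the
lower dilution exponent, which makes the rule order-invariant). The window
is applied to the plate total rather than per morphotype, reading "30 to
300 colonies" as a property of the plate. A series with no evaluable plate
yields a flagged, logged empty estimate rather than an exception, so one
failed dilution series cannot abort a run.

Method agreement is summarised by Pearson's r with its two-sided t-test and
the least-squares slope; two correlations (e.g. with/without predation) are
compared by Fisher's r-to-z statistic
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)).

## Competition dynamics

Per replicate culture, two OLS slopes over time are fitted: frequency
(linear scale) and ln(f/(1−f)) (the selection-rate statistic `s_logit`).
Under discrete selection logit(f) is exactly linear with slope ln(w) per
generation, so `s_logit` per hour equals (generations/hour)·ln(w); the
generations-per-hour conversion factor must be supplied by the caller —
typically from OD doublings — and is never inferred silently. Boundary
frequencies use the Haldane–Anscombe pseudo-count (x+0.5)/(n+1) when event
counts are available, else clipping to [10⁻³, 1−10⁻³].

Replicate slopes are aggregated per condition (initial ratio × stained
competitor × predation) as mean, SE = sd/√k and a two-sided normal z-test
against zero; single-replicate conditions are flagged with undefined SE.
This deliberately replaces a random-intercept linear mixed model: the
scientific quantity is the per-condition temporal trend, and per-replicate
OLS with across-replicate aggregation delivers it transparently; the
mixed-model ANOVA machinery is out of scope by design. Carrying capacity is
simply the maximum OD a culture reaches, averaged across replicates per
condition.

## Synthetic data

The simulator generates the full factorial experiment with ground-truth
labels. Defaults (the `paperlike` preset) mirror the standard design:
2000 events per sample, time points 0–10 h every 2 h, initial ratios
0.1/0.5/0.9, both staining assignments, predation absent/present,
triplicates — 216 coculture event tables, 24 monoculture tables, one plate
series per coculture sample and one OD series per culture.

Mechanisms and default parameters:

* **Stained intensity**: dye = LogNormal(μ = 12.7, σ = 1.4) ·
  2^−(g + ε), ε ~ N(0, 0.25 generations), plus an independent
  autofluorescence draw added on the linear scale (detector counts add).
  The per-cell jitter ε stands in for asynchronous division and keeps the
  halving law exact in expectation; an explicit age-structured model is
  deliberately avoided.
* **Autofluorescence**: LogNormal(μ = 3.9, σ = 1.0), with a +0.4 log-mean
  offset for competitor B so that the two competitors differ — the regime
  in which per-competitor thresholds are worth their cost. These values
  put the fresh stained and unstained distributions in slight overlap
  (thresholds matter) and produce ROC thresholds of order 10²–10³ a.u.
  with accuracies ≈ 0.95–0.997, the qualitative regime a well-stained
  culture shows. They are synthetic, not fitted to an instrument.
* **Growth and selection**: 0.8 generations per 2-h interval per
  competitor (≈ 4 generations over the assay), focal relative fitness
  w = 0.85 per generation; with predation, per-interval survival
  multipliers (0.9 focal / 0.75 partner) that reverse the focal decline.
  Frequencies propagate by the discrete-selection recursion.
* **Plate counts**: per dilution (the default series 10^3.79 … 10^7.29),
  totals are Poisson with expectation 2·10⁷ · 10^−dilution, split
  binomially at the true frequency. This places one plate near 130
  expected colonies, so ≥ 95% of series have an evaluable plate.
* **OD**: logistic growth (od₀ = 0.01, r = 1.2 h⁻¹, K = 0.42 + 0.08·(1−f₀))
  plus N(0, 0.005) measurement noise, making carrying capacity depend on
  the initial ratio.

Everything derives from one `numpy` Generator seeded from the config, so a
seed reproduces the dataset byte-for-byte on disk.

What the simulator does **not** emulate: instrument-specific noise (focus,
saturation, spillover), biofilm or cell aggregation, mechanistic
predator–prey kinetics, staining heterogeneity between species, and
plate-medium growth biases between competitors. Passing the synthetic
recovery tests therefore shows the estimators are correct under the assay's
own assumptions — not that a particular instrument or species pair
satisfies those assumptions; the plate-count reconciliation exists
precisely to check that on real data.

## Verified properties (computed by the test suite and acceptance script)

* ROC sweep equals exhaustive candidate enumeration (500 random instances,
  with ties and negative values).
* Perfectly separated controls yield accuracy 1 under both criteria, with
  the threshold strictly above the unstained maximum.
* End-to-end frequency recovery: MAE ≤ 0.02 against ground truth within
  the first two generations over 50 seeds (measured ≈ 0.007).
* Rogan–Gladen correction inverts the misclassification forward map to
  machine precision.
* Mean fitted `s_logit` over 100 noisy trajectories within 2 SE of
  g·ln(w).
* Mean log₂ stained intensity declines by 1.0 ± 0.05 per generation.
* A fixed fresh-control threshold degrades monotonically with generations
  and drops below 95% accuracy after ≈ 4–5 generations — the practical
  applicability window of a transient dye.
* Plate selection matches a brute-force application of the
  30–300/highest-count rule on 1000 randomized series.

## Problem sizes and other choices

Simulation-heavy tests use the full default design (2000 events/sample)
with 20–50 seeds; structural pipeline tests use reduced event counts
(120–300 events) since they assert bookkeeping, not statistical precision.
FCS support is a minimal list-mode reader (3.0/3.1, uniform float/double/
integer data, naive TEXT-delimiter splitting); delimited feature exports
are the canonical format, matching how imaging cytometry pipelines hand
over per-object tables. All numeric output is written with shortest
round-trip float formatting and read back with round-trip parsing, so
write-then-read is exact.

## Known limitations

* Two competitors only; multi-population mixtures would need multi-class
  thresholds or mixture models (noted as an extension, not implemented).
* Thresholds derived from monocultures assume coculture conditions do not
  alter dye retention; the retention-curve diagnostic
  (`retention_curve`) exists to check this assumption on real data.
* The mixed-effects ANOVA tables of a full factorial analysis are out of
  scope; the per-condition trend estimates are the supported inference.
* `s_logit` is reported per hour; converting to per-generation fitness
  requires an externally supplied generation rate.
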