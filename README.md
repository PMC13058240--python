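# dyetrack

Tracking pairwise bacterial competition with a transient fluorescent dye.

## The problem

Pairwise growth assays are the workhorse for quantifying competition between
bacterial species or genotypes, but telling two competitors apart in
coculture is hard: cells are small, morphologically similar, and populations
are large. Genetic labelling alters physiology and is impractical for fresh
environmental or evolved isolates; sequencing is slow and expensive for
dense time series.

An alternative is to stain one competitor with a transient membrane dye
before mixing. The dye is not renewed after application, so its per-cell
signal halves with every division — staining is non-invasive but only
informative for a limited number of generations. `dyetrack` implements the
complete analysis chain for this assay, for imaging-flow-cytometry event
exports (or FCS 3.x files):

1. **Gating** — a polygon gate on (dye channel, autofluorescence channel)
   separates cells from debris, and a brightfield-area window separates
   bacteria from ciliate predators.
2. **Thresholding** — an ROC sweep over the observed dye intensities of
   stained and unstained monoculture controls yields a data-driven
   classification threshold per stained competitor.
3. **Frequency estimation** — the threshold classifies gated coculture
   events; the stained fraction (with a Wilson 95% CI, optionally a
   Rogan–Gladen misclassification correction) is the competitor's relative
   abundance.
4. **Plate reconciliation** — dilution-series colony counts (30–300
   colonies per evaluable plate, highest-count plate wins) give an
   independent frequency estimate; Pearson correlation and Fisher-z
   comparisons quantify method agreement.
5. **Dynamics** — per-replicate trends of frequency and of
   logit-frequency versus time (the selection-rate statistic `s_logit`),
   aggregated per condition, plus carrying capacity as maximum OD.
6. **Simulation** — a ground-truth generator (log-normal dye halving per
   division, autofluorescence background, discrete selection, Poisson plate
   counts, logistic OD) makes every stage testable without instrument data.

## The statistics in brief

With stained-cell intensities $s_i$ and unstained-control intensities
$u_j$, every observed intensity $t$ is a candidate threshold; classify
"stained" iff intensity $\ge t$, giving
$\mathrm{TPR}(t) = \Pr(s \ge t)$ and $\mathrm{FPR}(t) = \Pr(u \ge t)$.
The optimal threshold minimises the distance to the ROC corner,
$\sqrt{\mathrm{FPR}^2 + (1-\mathrm{TPR})^2}$ (or maximises balanced
accuracy $(\mathrm{TPR}+\mathrm{TNR})/2$). Under discrete selection the
focal frequency follows
$f_g = w^g f_0 / (w^g f_0 + 1 - f_0)$, so
$\mathrm{logit}(f)$ is linear in generations with slope $\ln w$ — the
basis of the selection-rate estimator.

## Worked example

```python
import numpy as np
from dyetrack import analyze_experiment, paperlike_config, simulate_experiment

config = paperlike_config(seed=1)          # 2000 events/sample, 6 time points,
dataset = simulate_experiment(config)      # 3 ratios x 2 stainings x 2 predator x 3 reps
report = analyze_experiment(
    dataset.monocultures, dataset.cocultures,
    dataset.plate_series, dataset.od_series,
)

for competitor, rep in report["thresholds"].items():
    print(f"threshold[{competitor}] = {rep.threshold:8.2f}  "
          f"TPR = {rep.tpr:.4f}  TNR = {rep.tnr:.4f}  accuracy = {rep.accuracy:.4f}")

merged = report["frequencies"].merge(dataset.truth, on="sample_id")
mae = np.abs(merged["freq_focal"] - merged["freq_focal_true"]).mean()
print(f"frequency MAE vs ground truth = {mae:.4f}")

corr = report["method_correlation"]
print(f"fluorescence vs plate: r = {corr.r:.3f} (n = {corr.n}, p = {corr.p_value:.2g})")

trends = report["condition_trends"]
declining = (trends["mean"] < 0) & (trends["p_value"] < 0.05)
print(f"conditions with significant focal decline: {declining.sum()} of {len(trends)}")
```

prints

```
threshold[A] =  1060.07  TPR = 0.9956  TNR = 0.9968  accuracy = 0.9962
threshold[B] =   879.65  TPR = 0.9977  TNR = 0.9979  accuracy = 0.9978
frequency MAE vs ground truth = 0.0067
fluorescence vs plate: r = 0.993 (n = 216, p = 1.2e-202)
conditions with significant focal decline: 6 of 12
```

The two thresholds are the competitor-specific general (pooled over time
points) ROC optima; classification accuracy near 0.997 translates into a
mean absolute frequency error under 0.01 against the simulator's ground
truth, and the fluorescence- and plate-based estimates agree almost
perfectly. The focal competitor was simulated with a per-generation fitness
of 0.85 without predation (it declines in those 6 conditions) and a
compensating predation advantage (it does not decline in the other 6).

The same workflow is scriptable from the shell:

```
dyetrack simulate --seed 1 --out run1
dyetrack run --manifest run1/manifest.yaml --out-dir run1/results
```

with subcommands `threshold`, `classify`, `analyze` and `validate` exposing
the individual stages.

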