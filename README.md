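# avidex

Rupture-event scoring and biomarker statistics for avidity-based capture of
PD-L1⁺ exosomes.

## What this package is for

Tumor-derived exosomes carrying PD-L1 are a candidate blood biomarker for
immune-checkpoint-inhibitor response, but capturing them selectively is
hard: a single peptide binds PD-L1 weakly. Presenting many copies of the
peptide on a generation-7 PAMAM dendrimer (G7-pPDL1) turns weak monovalent
affinity into strong multivalent *avidity*. Three kinds of quantitative
evidence support that design, and this package implements all three
analyses as tested, reproducible code for anyone working with similar
force-spectroscopy or biosensor data:

1. **AFM force-distance (FD) scoring.** On each retraction trace, abrupt
   force recoveries of at least 300 pN are counted as bond ruptures; a
   curve with ≥ 2 ruptures shows multivalent binding. Per curve the
   pipeline reports the event count, binding class, maximum adhesion force
   F_max = max(−F(z)), and adhesion energy E_adh = ∫|F| dz over the
   adhesive region; per 20×20 force-volume grid it reports class
   prevalences, moment summaries, and F_max/E_adh heatmaps.
2. **Biomarker statistics.** Normality-gated two-group tests
   (Kolmogorov-Smirnov gate → Welch t or Mann-Whitney U), enrichment
   ratios, empirical ROC AUC, Kaplan-Meier survival with the log-rank
   test, univariate Cox regression (HR = e^β, Breslow ties, Newton-Raphson),
   and the Schoenfeld power formula
   Φ(√(d·p(1−p))·|ln HR| − z₁₋α/₂).
3. **Sensor calibration.** Log-linear dose-response fits
   dΨ = a + b·log₁₀(c) for ellipsometric sensorgrams and the 3σ limit of
   detection, LOD = 10^((baseline mean + 3·baseline SD − a)/b).

The raw study data are not public, so the package ships a calibrated
synthetic-data generator: sawtooth retraction curves with 0…m sequential
bond ruptures (lognormal magnitudes, Gaussian noise, nonspecific adhesion
dip), with per-surface presets whose *scored* summaries match the published
per-surface statistics. Everything runs end to end with no external data.
See `docs/methods.md` for the model and its assumptions.

## Worked example

Reproduce the four-surface nanomechanical comparison (400 simulated curves
per surface, scored at the 300 pN threshold):

```sh
avidex repro-fig2 --seed 17 --outdir out/
```

prints

```
G7-pPDL1       multiple= 88.8%  F_max= 1503.9 pN  E_adh= 100.9 pN nm
aPD-L1         multiple= 70.0%  F_max=  792.6 pN  E_adh=  65.9 pN nm
pPDL1          multiple= 39.8%  F_max=  589.2 pN  E_adh=  49.0 pN nm
G7-pPDL1-scr   multiple=  5.8%  F_max=  310.5 pN  E_adh=  14.0 pN nm
report bundle -> out/
```

Read: the dendrimer-peptide surface shows multivalent binding on ~89% of
curves with a mean maximum adhesion force of ~1.5 nN — roughly 1.9× the
antibody surface and 2.5× the free peptide — while the scrambled-peptide
control binds multivalently on only ~6% of curves with forces near the
detection threshold, i.e. the avidity gain is specific. The bundle
contains `report.json` (per-surface summaries, seeds, and the six pairwise
Mann-Whitney comparisons on F_max; e.g. targeting vs scrambled control has
p ≈ 1e-98 at this sample size), per-curve `*_metrics.csv`, and heatmap CSV
matrices.

The same pipeline pieces are available individually:

```sh
avidex simulate --preset G7-pPDL1 --rows 20 --cols 20 --seed 17 --out g7.tsv
avidex fd-score --in g7.tsv --out metrics.csv --summary summary.json
avidex compare  --a metrics.csv --b scr_metrics.csv
avidex clinical --survival cohort.csv --out report.json
avidex lod      --sensorgram sis.csv --schedule schedule.csv --out fit.json
```

or from Python:

```python
from avidex import builtin_presets, simulate_grid, score_grid, summarize_surface

grid = simulate_grid(builtin_presets()["G7-pPDL1"], 20, 20, seed=17)
summary = summarize_surface(grid, score_grid(grid))
print(summary.prevalence_multiple, summary.f_max_mean)
```

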