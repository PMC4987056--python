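# asphyxomics

¹H-NMR metabolomics of asphyxiated, resuscitated newborn pigs — a tested,
reusable implementation of the complete computational chain used to profile
plasma and urine in a porcine model of perinatal asphyxia: newborn pigs
undergo progressive asphyxia until asystole, are resuscitated under one of
six protocols (varying FiO₂, initial ventilation time and chest-compression
to ventilation ratio), and are sampled at baseline (t1) and 2 h / 4 h after
return of spontaneous circulation (t2 / t3).

The package is aimed at metabolomics researchers and methodologists who
want to exercise, validate or extend this kind of pipeline without access
to the original animal data. A first-class synthetic cohort generator,
parameterized from the study's published summary tables (group sizes,
sample availability, per-metabolite median/IQR concentrations and pairwise
fold changes), produces ground-truth concentration trajectories and renders
them as realistic 1D ¹H-NMR spectra, so every stage of the analysis can be
tested against known truth.

## The chain

1. **Cohort simulation** (`asphyxomics.cohort`, `asphyxomics.render`) —
   per-metabolite log-normal baselines moment-matched to published
   median/IQR values (`σ = ln(q₃/q₁)/(2·z₀.₇₅)`), multiplicative
   within-animal trajectories `c(t+1) = c(t)·ratio(FC)·exp(ε)`, endpoint
   correlations, survival, and a Lorentzian-multiplet spectral renderer
   with TSP reference, phase/shift/gain errors, lipoprotein backgrounds
   and noise.
2. **Preprocessing** (`asphyxomics.preprocess`) — zero-order phase
   correction on the TSP signal; separate linear baselines up/downfield of
   the water artifact; chemical-shift referencing (plasma: glucose
   doublet ≈ 5.23 ppm, urine: TSP 0.0 ppm); clipping to −0.5…9.0 ppm;
   normalization to the TSP area; TSP FWHM measurement (a plasma
   lipoprotein proxy); adaptive nonlinear baseline subtraction; excision
   of the water, TSP and (urine) urea regions.
3. **Quantification** (`asphyxomics.quantify`) — window integrals
   converted to mM by `c = (A/nH) / (A_TSP/9) · c_TSP`, with analytic
   Lorentzian tail-capture corrections and urinary creatinine
   normalization.
4. **Chemometrics** (`asphyxomics.chemometrics`) — unit-variance scaling,
   PCA, NIPALS PLS/PLS-DA with segment-wise 7-fold cross-validation
   (R², Q² = 1 − PRESS/TSS), the number of misclassifications (NMC)
   summarized over repeated CV and compared with a permuted-label null,
   and backscaled loading weights (amplitude = weight × natural SD,
   color = correlation with the response).
5. **Univariate statistics** (`asphyxomics.unistats`) — log-transformed
   ANOVA and Welch t-tests, signed paired fold changes
   (FC = exp(d̄) if ≥ 1 else −exp(−d̄)) with Benjamini–Hochberg q-values,
   Pearson correlations with time-to-asystole / time-to-ROSC, survivor
   comparisons.
6. **Correlation structure** (`asphyxomics.corrstruct`) — all-pairs
   Pearson matrices of plasma and creatinine-normalized urine variables,
   hierarchical-cluster ordering (average linkage on 1 − r), per-material
   block clustering and |r| > 0.5 lower-triangle filtering.

## Worked example

```python
import numpy as np
from asphyxomics import (AcquisitionParams, default_concentration_model,
                         default_panel, render_cohort, sample_cohort,
                         sample_concentrations, simple_design)
from asphyxomics.preprocess import PreprocessConfig, preprocess_pipeline
from asphyxomics.quantify import peak_mask_windows, quantify_cohort

acq = AcquisitionParams()
panel = default_panel("plasma")
model = default_concentration_model("plasma")

design = simple_design(100, timepoints=("t1",))
animals, samples = sample_cohort(design, seed=101)
truth, nuisance = sample_concentrations(model, animals, samples, 102, panel)
spectra = render_cohort(truth, panel, acq, nuisance, 103)

cfg = PreprocessConfig(material="plasma",
                       peak_windows=peak_mask_windows(panel, acq))
processed = [preprocess_pipeline(s, cfg, excise=False) for s in spectra]
table = quantify_cohort(processed, panel, acq.tsp_conc, acq)

for m in ("Lactate", "Glucose"):
    print(m, round(float(table.values[m].median()), 2),
          "mM (truth", round(float(truth.values[m].median()), 2), "mM)")
```

prints

```
Lactate 2.68 mM (truth 2.68 mM)
Glucose 5.34 mM (truth 5.38 mM)
```

i.e. the full render → preprocess → quantify chain recovers the cohort
medians of a 100-animal synthetic baseline cohort to within a couple of
percent of their ground truth (the published baseline medians are 2.9 mM
lactate and 6.0 mM glucose; the residual gap is the sampling variability
of a 100-animal median).

The same machinery drives the multivariate layer: a baseline-vs-2h
PLS-DA on synthetic plasma profiles gives Q² ≈ 0.6 with a median NMC of
≈ 22 against a permuted-label null of ≈ 100 — the same qualitative
pattern the study reports — while a weak-effect 2h-vs-4h contrast is
correctly non-significant.

A `click` CLI wraps the stages
(`asphyxomics simulate|preprocess|quantify|plsda|unistats|correlate|run-all
--config config.yaml`), writing CSV tables, JSON model summaries, SVG
figures and a provenance manifest per stage.

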