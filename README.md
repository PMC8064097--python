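# breathflow

Analysis pipeline for **online breath sampling campaigns with PTR-ToF-MS**
(proton-transfer-reaction time-of-flight mass spectrometry). The package
takes raw 1 Hz traces — CO₂ percentage, trigger state and counts-per-second
per ion channel — and carries them through end-tidal extraction,
quantification, detection-limit filtering, and the repeated-measures
statistics needed to detect exercise- and medication-related changes in
exhaled volatile organic compounds (VOCs).

It is written for breath-research groups running field campaigns of the
"three groups × five timepoints × duplicate samples" kind: here, non-statin
users (St0), statin users without (St1) and with (St2) muscle complaints,
sampled before and after repeated days of prolonged walking. Because raw
instrument data from such campaigns are rarely deposited, the package ships
a first-class synthetic-data generator that reproduces the statistical
structure of the design (subject random effects, exercise and group×time
effects, technical noise, exogenous outliers) together with its ground
truth, so every stage of the pipeline is testable end to end.

## What the pipeline does

1. **Breath tracer** — detect the tick where exhaled CO₂ first reaches 4%
   (with re-arm hysteresis), average the ion signal over the window
   `[t+5 s, t+10 s)` — five 1 Hz spectra of the end-tidal fraction — pair
   duplicates, and flag short exhalations and sampling-line carryover.
   Duplicate repeatability is scored with Lin's concordance coefficient

   $$R_c = \frac{2 S_{YX}}{(\bar Y - \bar X)^2 + S_Y^2 + S_X^2}$$

   (population moments; $R_c > 0.9$ excellent, $0.6$–$0.9$ satisfactory).

2. **Quantification** — normalize cps to counts per 10⁶ primary ions via
   the reagent-ion isotopologues (m/z 21.02 × 500 and 39.03 × 250), then
   convert to ppbv by first-order proton-transfer kinetics,
   `[VOC] = I_RH+/(I_H3O+ · k · t)`, at the drift-tube operating point
   (600 V, 2.6 mbar, 60 °C ≈ 120 Td). Per-ion limits of detection are
   mean + 3σ of catalyzed-air blanks; sub-LoD values are replaced by the
   LoD, and an ion is retained only if above LoD in more than half of each
   group's samples.

3. **Identification** — candidate molecular formulas by accurate mass
   (monoisotopic mass minus one electron mass), and clustering of related
   ions (fragments, hydrates) by Pearson correlation at r² ≥ 0.85.

4. **Multilevel statistics** — log-transform and mean-centre, split into
   between-subject and within-subject parts (X = X_b + X_w, exactly), then
   M-PCA and M-PLS-DA (NIPALS PLS2 on X_w against one-hot class labels).
   Influential ions are selected by Variable Importance in Projection,
   `VIP_j = sqrt(p · Σ_a SS_a w_{aj}² / Σ_a SS_a)` with VIP > 1, and models
   are validated by subject-level 5-fold cross-validation with 10
   repetitions (balanced error rate; subjects never split across folds).

5. **Univariate follow-up** — Lilliefors normality (Monte-Carlo null)
   routes each variable to ANOVA + Tukey HSD or tie-corrected
   Kruskal–Wallis + Tukey–Kramer on mean ranks; plus the short-chain
   fatty-acid (SCFA) cluster series and the range-scaled relative-change
   matrix of cell medians.

## Worked example

```python
import breathflow as bf
from breathflow import synthetic, pipeline, univariate

design = synthetic.StudyDesignSpec(seed=0)          # 62 participants, 5 timepoints
sessions, dtab, truth = synthetic.simulate_study(design, synthetic.default_effects())
analysis = pipeline.analyze_study(sessions, dtab)   # extract, quantify, filter

m = analysis.matrix
print(len(m.values), "samples,", len(m.retained), "retained ions")
print("median duplicate Rc:", round(analysis.concordance["rc"].median(), 4))

model, vip = pipeline.timepoint_model(analysis, dtab, group="St0")
print(vip.sort_values(ascending=False).head(5).round(2))
```

prints

```
620 samples, 21 retained ions
median duplicate Rc: 0.9998
mz89.06    1.57
mz71.05    1.57
mz75.05    1.52
mz57.04    1.52
mz43.02    1.45
```

620 = 62 participants × 5 timepoints × 2 replicates; 21 of 23 analyte
channels survive the LoD filter (the two unassigned instrument-background
channels drop out). Duplicate breath samples agree almost perfectly under
the ~2% technical noise of the generator. The highest-VIP ions in the
non-statin timepoint model are butanoic acid (m/z 89.06), propanoic acid
(75.05) and their fragments (71.05, 57.04, 43.02) — exactly the SCFA
cluster the generator endows with the strongest exercise and group effects.
The pooled post-walking SCFA contrast between non-statin and statin users
is strongly significant (Kruskal–Wallis H = 50.4, p ≈ 1e-12), with Day 1
cell means of 89.4 ± 6.5 ppbv (St0) versus 54.5 ± 3.6 ppbv (St1).

A command-line interface wraps the same steps:

```sh
breathflow simulate --out fixtures/ --seed 0
breathflow extract --traces fixtures/traces.tsv --design fixtures/design.tsv \
    --delay 5 --window 5 --co2-threshold 4 --out samples.tsv
breathflow stats --samples samples.tsv --design fixtures/design.tsv --out stats.tsv
```

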