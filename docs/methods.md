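# Methods

## The measurement model

A PTR-ToF-MS instrument records one full mass spectrum per second while a
participant exhales through a CO₂-monitored sampler. Each session (one
participant at one timepoint) contains a catalyzed-air background segment,
followed by two complete exhalations separated by room-air flush gaps.
When the exhaled CO₂ concentration reaches 4% the sampler raises a trigger;
the alveolar (end-tidal) fraction of the breath is taken as the ion signal
averaged over the five spectra in `[t_trigger + 5 s, t_trigger + 10 s)`.
Averaging a fixed window, and rejecting (rather than shortening) windows
that overrun the exhalation, guarantees that every retained sample
describes the same fraction of breath with the same number of spectra.

Counts are normalized to 10⁶ primary (reagent) ions. The H₃O⁺ signal
itself saturates the detector, so it is reconstructed from isotopologues:
500 × cps(m/z 21.02, H₃¹⁸O⁺) + 250 × cps(m/z 39.03, ¹⁸O water cluster) —
the factors being the inverse natural abundance of ¹⁸O for one and two
oxygen atoms. Mixing ratios follow from first-order proton-transfer
kinetics,

    [VOC] = I_RH+ / (I_H3O+ · k · t),    ppbv = [VOC] / N · 1e9,

with N = p/(k_B·T) the drift-tube gas density. Defaults: k = 2×10⁻⁹ cm³/s
(compound-specific overrides for acetone 3.0, isoprene 1.94, methanol
2.33 ×10⁻⁹), t = 100 µs, 600 V / 2.6 mbar / 60 °C. The drift length is not
part of the kinetic equation and is exposed only through the E/N sanity
check (`compute_reduced_field`), whose default 8.85 cm reproduces the
nominal 120 Td operating point; a configuration far from nominal logs a
warning.

Detection limits are per-ion mean + 3·sd (sample sd, ddof = 1) of the
pooled catalyzed-air blank converted to the concentration scale — the
blank-based 3σ convention; no calibration slope exists in direct kinetic
quantification, so the σ/slope variant does not apply. Sub-LoD entries are
replaced by the LoD itself (keeping the matrix positive for the log
transform), and an ion is retained only when *strictly more than* 50% of
each group's samples lie above its LoD, each group evaluated separately on
all samples (not replicate means). "Strictly more than" and "strictly
below" are deliberate boundary choices, tested explicitly.

## Repeatability

Duplicate agreement uses Lin's concordance coefficient with population
(divisor-n) moments:

    Rc = 2·S_YX / ((Ȳ − X̄)² + S_Y² + S_X²)

computed per participant-timepoint across the retained-ion vector of the
two replicates, on the log scale so high-abundance ions (acetone at
hundreds of ppbv) do not dominate low-abundance acids. Bands: > 0.9
excellent, 0.6–0.9 satisfactory, < 0.6 unsatisfactory. Two constant
vectors make the denominator zero; this is reported as a degenerate
replicate error rather than a value. A raw-scale variant is available via
the `log` flag.

## Multilevel statistics

Concentrations are natural-log transformed and column mean-centred. The
repeated-measures structure is handled by the multilevel decomposition
X = X_between + X_within, where X_between repeats each subject's mean row;
the decomposition is exact by construction and X_within has zero column
means (each subject's deviations sum to zero), so each participant acts as
their own control. M-PCA is an SVD of X_within. M-PLS-DA is PLS2 of
X_within on the centred one-hot class matrix, fitted by NIPALS with:

* deterministic initialization from the dummy-Y column of maximal
  variance;
* convergence tolerance 1e-12 on the weight change, at most 1000
  iterations;
* X-only deflation (Y is left intact). Variants that also deflate Y change
  later components and hence VIP slightly; one scheme is fixed and
  documented here. Successive scores are mutually orthogonal.

Y-variance explained per component is SS_a = (c_aᵀc_a)(t_aᵀt_a) with c_a
the regression of centred Y on t_a. VIP scores use unit weight vectors, so
Σ_j VIP_j² = p holds as an algebraic identity; VIP > 1 marks influential
ions. Prediction maps new rows through W(PᵀW)⁻¹ and classifies by the
maximal predicted dummy column (the simplest, maximum-distance rule).

Cross-validation is subject-level: folds partition *subjects*, stratified
by each subject's most frequent label, so no subject contributes to both
training and test (a leakage guard asserts this). Held-out samples are
within-decomposed using their own subject means before prediction — for
exhaustive repeated-measures designs the test subject's mean is available
without their labels. The error metric is the balanced error rate, chosen
because the default group sizes (24/17/21) are unequal. If a class is
missing from some training split the repetition is repartitioned with the
next derived seed (logged). Score plots use 2 latent variables; for VIP
selection the component count can be CV-selected, capped at 5.

## Univariate follow-up

Lilliefors' test computes the Kolmogorov–Smirnov distance between the
studentized sample and the standard normal; because parameters are
estimated, the null distribution is simulated (10⁴ seeded draws per sample
size, cached) rather than read from the KS tail. The add-one Monte-Carlo
estimator keeps p in (0, 1]. Per variable, a non-normal verdict at α = 0.05
routes to the tie-corrected Kruskal–Wallis H (chi-square tail, df = g−1;
full-enumeration permutation p available for total n ≤ 10) followed by
Tukey–Kramer comparisons of group mean ranks against the studentized-range
distribution with infinite df — the standard post hoc companion to a
Kruskal–Wallis fit in common statistical software; Dunn's z tests with
Holm adjustment are available as an alternative. Normal data go to one-way
ANOVA with Tukey HSD. p-values are reported per test without cross-ion
FDR adjustment. The analysis unit for these tests is the replicate mean
per participant-timepoint, avoiding pseudo-replication of duplicates.

The SCFA cluster series sums the three parent acid ions (m/z 61.03, 75.05,
89.06 — fragments excluded to avoid double counting) per
participant-timepoint and summarises mean ± standard error per
group × timepoint cell. The relative-change matrix takes cell medians per
compound, centres them on the St0-Day0 reference cell and divides by the
range of the centred medians, so each row spans an interval of length 1
(anchored at 0 when the reference is the row minimum); zero-range rows are
flagged and reported as zero.

## The synthetic-data generator

The generator emulates the campaign the pipeline targets: three groups of
24/17/21 participants, five timepoints (Day0 baseline, post-walking Day1,
pre-walking Day2am, post-walking Day2 and Day3), duplicate exhalations per
session. On the log-concentration scale,

    ln c = baseline(ion) + subject_offset + exercise(ion, timepoint)
         + group_effect(ion, group, timepoint) + ε

with subject offsets ~ N(0, 0.35²) per subject × ion, sample noise
ε ~ N(0, 0.15²), and multiplicative technical noise of cv 2% per tick plus
Poisson counting noise on the simulated counts. Baselines are typical
breath levels (acetone 500 ppbv, methanol 150, isoprene 100, ethanol 100,
acetaldehyde 25, acetic acid 20, propanoic 6, butanoic 4 ppbv, …). The
default effect pattern is a recovery cycle — roughly +0.5 log units after
the first walking day, a dip to +0.1 at the rest sample, and an equal
+0.3–0.4 plateau on days 2 and 3 — mirrored with negative sign for
isoprene. The SCFA ions additionally carry a group × time effect: +0.45
log units for non-statin users on post-walking days, and a +0.22 residual
elevation for statin users at the rest sample. Day2 and Day3 effects are
equal by design, which is what produces the expected Day2/Day3 overlap in
the post-walking discriminant model. Ethanol and the exogenous channels
(monoterpene m/z 81.08/137.13, estragole 149.10) receive +2.5 log-unit
outliers at rate 5% per session, emulating unrestricted food and drink;
an ethanol outlier also leaves a 6× background residue in the following
flush gap so that carryover detection has real positives.

Each exhalation has a trapezoidal CO₂ profile: 2 s rise, 16 s plateau
drawn uniformly in 4.6–5.4%, 2 s fall (~20 s total, the typical minimum
exhalation length), so the 5 + 5 s extraction window always fits; a design
whose window exceeds the plateau is rejected as invalid. Ion counts during
breath scale linearly with the true concentration (ramped by the CO₂
profile), making extraction → quantification exactly invertible up to
noise; room-air and background phases revert to instrument background
(mean 2 cps, sd 0.6). The panel includes the nine exercise-responsive
compounds, four product-ion fragments generated at fixed fractions
(0.30–0.35) of their parents, five stable endogenous volatiles
(formaldehyde, acetonitrile, dimethyl sulfide, butanone, xylenes), the
exogenous channels, and two unassigned channels at background level.
The stable channels matter statistically: because Σ VIP² = p forces the
mean-square VIP to 1, a panel in which *every* modeled ion responds to
exercise could never place ≥ 80% of responsive ions above VIP 1; the
unresponsive channels provide the contrast that makes VIP selection
meaningful, as in real spectra where most of the retained ions are not
exercise-responsive. The two background-level channels exercise the
retention filter.

Setting `noise_cv = 0` disables the entire technical-noise model
(lognormal, Poisson, background and primary-ion jitter), giving exactly
reproducible traces — the degenerate mode used by identity tests. With a
fixed seed, fixtures are byte-identical across runs (readers parse floats
in round-trip mode for this reason).

What the generator does **not** emulate: drift of instrument sensitivity
and primary-ion signal over a campaign day, mass-calibration error and
peak-shape effects (channels are already integrated peaks), breath-to-breath
physiological variation within a session beyond technical noise,
correlated exogenous exposures across timepoints, humidity-dependent
fragmentation, and missing sessions/dropout. Passing recovery tests
therefore shows the pipeline is correct and well-calibrated under the
assumed data-generating process, not that the biological effect sizes are
those of any real cohort.

## Problem sizes and runtimes

The test suite runs the full default campaign (62 × 5 sessions, duplicate
exhalations, ~90 s of trace each) once as a shared fixture (~1 s to
simulate, ~1 s to analyze), plus 12 independently seeded campaigns for the
SCFA detection-rate check and 10⁴ replicates for Kruskal–Wallis type-I
calibration; the whole suite completes in under a minute on one CPU.

## Known limitations

* The exact Kruskal–Wallis path enumerates assignments and is limited to
  total n ≤ 10; larger samples use the chi-square tail.
* Tukey–Kramer on mean ranks uses the infinite-df studentized range, the
  large-sample convention; very small groups are better served by the
  Dunn–Holm alternative.
* The NIPALS implementation targets the tall-thin matrices of this domain
  (hundreds of samples × tens of ions); no kernel/wide-matrix variants.
* LoD computation pools background across sessions; per-session LoDs would
  require longer background segments than the 30 s the generator emits.
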