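# Methods

This note documents the models, the synthetic data conditions, the numerical
choices, and the design decisions behind `adrenomir`, in the spirit of the
methods documentation of packages like statsmodels or msprime. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Problem and data model

The pipeline discriminates adrenocortical carcinoma (ACC) from adenoma
(ACA), with normal adrenal cortex (NAC) as a third reference class in the
discovery phase. Input is a long-form RT-qPCR Ct table: one row per
(sample, assay, replicate) well, Ct in cycles, "Undetermined" wells marked
missing. Sixteen literature-selected target miRNAs are measured in
triplicate alongside two controls: RNU48 (endogenous reference) and
cel-miR-39 (exogenous spike-in added before RNA isolation).

## ΔCt normalization

Replicate wells are aggregated by the mean of the wells that amplified
(median available by configuration); a summary is missing only when all
replicates are missing. Per sample the control reference is the **geometric
mean of the two control Ct values**, √(c₁·c₂), following the wording of the
normalization convention this pipeline adopts; the arithmetic mean of Cts —
the convention of several qPCR normalization packages — is available as a
configuration switch (`control_mean="arithmetic"`). Expression is stored as
−ΔCt = −(Ct_target − reference): higher values mean higher expression, so
"up-regulated in ACC" corresponds to larger feature values.

Missing summaries are resolved by one of two policies:

- `omit_feature` (default): a marker with at least one missing summary in
  the analysis set is dropped entirely. This is the conservative rule for
  down-regulated markers that fall below the detection limit. It is applied
  per analysis set (per cohort matrix), not per pairwise comparison.
- `censor_fill`: missing values are replaced by expression at the detection
  floor, −(ct_max − reference), for analyses that prefer to keep the marker.

No efficiency correction (Pfaffl-type) and no inter-plate calibration are
modeled.

## Random-forest marker ranking

Marker importance is the classic out-of-bag permutation measure ("mean
decrease in accuracy"): per tree, the drop in out-of-bag accuracy after
permuting a feature's out-of-bag values, averaged over trees with non-empty
out-of-bag sets, using a fixed permutation seed. The forest is written in
this package (CART-style trees: Gini impurity, exhaustive threshold search
over a random feature subset per split, bootstrap resampling) because the
OOB-permutation semantics of the classical implementation are not exposed
by the scikit-learn forest; scikit-learn serves as an independent
cross-check in the tests, never as the implementation. Defaults: 500 trees,
⌊√p⌋ features per split, minimum leaf 1. Rank ties break by assay name. The
ranking defaults to the three-class (ACA/ACC/NAC) discovery task; the
two-class task is a parameter away. The forest is never used as the
diagnostic classifier.

## The neural network

Both the panel search and the ensemble validation train the same model: a
single-hidden-layer feed-forward network.

- Architecture: logistic (sigmoid) hidden layer, softmax output, one output
  unit per class.
- Input standardization is fit on the learner set only (mean/sd per
  feature; a zero-variance feature gets scale 1), so no tester information
  leaks into training.
- Loss: mean multinomial cross-entropy plus L2 weight decay on the weight
  matrices. Biases are not penalized — this is what makes the large-decay
  limit collapse to the learner-set class frequencies rather than to the
  uniform distribution.
- Optimization: full-batch gradient descent with a fixed epoch budget and
  no early stopping, for exact reproducibility. Defaults: 3 hidden units,
  decay 0.01, 200 epochs, learning rate 0.5, weights initialized
  Uniform(−0.5, 0.5) from a per-fit seed. Fixed-step descent is stable only
  while lr · 2 · decay < 1; tests probing the large-decay limit reduce the
  step accordingly.
- Determinism: training is a pure function of (features, labels, config,
  seed). Callers pre-sort samples by sample id, so presentation order never
  matters.

Because the surrounding procedures train this tiny network thousands of
times, the module exposes a batched engine that carries B independent
networks through identical arithmetic in stacked (B, n, p) arrays with
preallocated buffers; a single fit is the B = 1 case of the same code path,
and a test asserts batched/sequential agreement.

The original analysis's hidden-layer size, decay and iteration count are
not documented anywhere we could consult, so exact numeric reproduction of
per-panel metrics is not a design goal; the defaults echo common
conventions of the R `nnet` ecosystem.

## Panel search

All marker subsets of size 2–4 are enumerated (sizes ascending,
lexicographic within size) and scored independently. Per repetition a
stratified 90–10% split draws exactly 9 learners and 1 tester per group —
9-9-9/1-1-1 for the three-class analysis, 9-9/1-1 for the two-class
adenoma-vs-carcinoma analysis; both run on the same matrix without code
change. Each repetition uses fresh child seeds for both the split and the
weight initialization. **Classification capability** is defined as the mean
per-repetition tester accuracy over 1000 repetitions (default); pooled
per-sample accuracy is available by configuration and differs only when
more than one tester per group is drawn. Panels with capability ≥ 0.90 are
selected, ordered by capability, ties by label. All panels share the same
repetition seeds, so capabilities are paired across identical splits.

## Ensemble majority-vote validation

Each blinded sample is classified independently over 10,000 iterations
(default). What varies across iterations is a stratified 90% subsample of
the labeled samples *and* the weight initialization (`subsample_90`,
default); `full_refit` varies initialization only. Training uses the
ACA/ACC knowns only (final calls are binary); NAC samples can be included
by configuration. The final call requires a strict majority (> 50%); an
exact tie yields the explicit INDETERMINATE state. Per-sample child seeds
derived from the sample id make each sample's result independent of cohort
ordering. The carcinoma-vote fraction is used as the ROC score; it is not a
calibrated probability.

## Diagnostics

ACC is the positive ("patient") class, ACA the negative ("control") class,
in the standard epidemiological convention. (Study descriptions of this
design sometimes label a benign-called-malignant error the other way
around; this package keeps the standard convention and offers the swapped
orientation via `ConfusionMetrics.swapped()`.) INDETERMINATE calls are
counted separately and never enter the four confusion cells; an undefined
ratio (zero denominator) is reported as "not computed", never as 0. The ROC
curve sweeps all distinct score thresholds; the trapezoidal AUC equals the
tie-corrected Mann–Whitney statistic, which the tests verify against a
brute-force pairwise oracle. No confidence intervals or DeLong tests are
provided.

## Synthetic data generator

The generator emulates the study design, not the instrument: per sample s
in group g and assay a, the latent mean Ct is
baseline(a) − shift(g, a) + ε_bio, ε_bio ~ N(0, σ_bio²), and each replicate
adds N(0, σ_rep²). Shifts act on the Ct scale under the doubling assumption
(1 cycle ≡ 1 log2 unit): relative to NAC, ACA is shifted by a signed
`aca_vs_nac_log2` and ACC additionally by `effect_log2` in the direction of
the marker's known regulation. Controls get zero group effect but one third
of the biological variability, so normalization is genuinely exercised.
Replicates whose Ct exceeds 38 cycles are reported "Undetermined"
(per-replicate censoring, as instruments report it); censored wells remain
in the table as missing-valued records.

Default conditions (chosen once, as a field-realistic discovery scenario):

| parameter | default | rationale |
|---|---|---|
| effect_log2 | 2.0 | a 4-fold expression difference, typical of reported ACC markers |
| aca_vs_nac_log2 | 1.0 (signed) | adenomas intermediate between normal cortex and carcinoma |
| biological sd | 0.75 cycles | dominant noise source across FFPE samples |
| replicate sd | 0.25 cycles | technical triplicate scatter |
| baselines | 30 cycles (targets), 35 for miR-7/miR-511, 22/24 for controls | places the two lowest-abundance down-regulated markers near the censoring threshold |
| censoring | 38 cycles | late-cycle detection limit below the 40-cycle ceiling |
| cohorts | 10/10/10 discovery; 22 ACA / 21 ACC validation | the study design |

`spec_with_marker_effects` builds the mixed-effect conditions used by the
simulation studies: the named "strong" markers carry 2.0 log2 units and the
remaining targets 0.5 (markers with weaker literature evidence), with the
ACA-vs-NAC shift scaled proportionally (half the carcinoma effect) so the
strong markers dominate every group contrast.

What the generator does **not** emulate: isolation efficiency and RNA
quantity variation, amplification curves, inter-plate effects, marker–marker
correlation structure, and outlier samples. Passing simulation tests
therefore demonstrate that the pipeline recovers the signal it assumes —
group mean shifts with Gaussian noise and censoring — not that it would
reach the same numbers on real FFPE measurements.

## Simulation studies and problem sizes

The packaged studies (`adrenomir.workflows`, exercised by the test suite
and `scripts/acceptance.py`) use reduced repetition counts — 200
cross-validation repetitions and 500 voting iterations instead of
1000/10,000 — which keeps the full ten-replicate recovery study to minutes
while leaving the vote-fraction standard error near 0.02. The two-class
search mode is used for panel scoring there, since it is the analysis that
feeds the binary validation decision. The null study runs the 24 candidate
panels on cohorts with every group effect removed; note that a single
20-sample null cohort can be partly separable by chance, so chance-level
capability (50%) emerges on average over replicates, with wide scatter per
cohort.

## Reproducing the study's own numbers

The study's per-sample expression table (its supplementary appendix) is not
redistributed here. `adrenomir.reproduce` re-runs the ensemble validation
of the three best panels (models 9, 16, 17) on a user-transcribed copy of
that table and scores the calls; absent the transcription it refuses to run
rather than substituting synthetic data. Because the original network
configuration is unreported, even that reproduction is expected to match
headline bounds (sensitivity and specificity above 90% for the best
panels), not each table entry exactly.

## Known limitations

- Exhaustive enumeration is quadratic-to-quartic in the marker count; it is
  meant for panels of ≤ ~20 candidate markers (2500 combinations at 16).
- Capability estimates on 1-1(-1) testers are coarse (each repetition
  contributes 0/½/1); the 90% threshold behaves as a soft cut.
- The ΔCt model assumes perfect amplification efficiency.
- INDETERMINATE is possible only at an exact vote tie; with odd iteration
  counts it cannot occur.
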