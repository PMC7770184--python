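# Methods

## Study design and data model

The pipeline analyses a three-condition longitudinal design: a control
group (NC) scanned once, and a patient cohort scanned at baseline (IBSbs)
and again after a six-week intervention (IBS1st).  Default cohort sizes
are 23 controls and 24 patients (71 sessions).  Each session is a T×R
matrix of ROI-averaged signals; defaults are R = 116 (the AAL
cortical + cerebellar atlas, whose label list ships with the package) and
T = 200 time points (210 acquired volumes minus 10 discarded for signal
equilibrium).  Pre-processing of raw 4-D volumes (motion correction,
nuisance regression, normalisation) is out of scope; the pipeline starts
at ROI time series.

## Connectome construction

Edge weights are Fisher-z transformed Pearson correlations; the arctanh
transform stabilises the variance of r so the parametric t-test battery
is better calibrated.  Self-connections are removed (diagonal forced to
0), and a correlation of exactly ±1 off the diagonal is an error rather
than an infinite weight.  Binarisation keeps strictly positive weights
only (`z > 0`), treating anti-correlations and exact zeros as absent:
negative and weak links in correlation networks are commonly regarded as
spurious, and no further density thresholding is applied.  A
zero-variance ROI column (possible in synthetic edge cases) gets zero
correlations with a logged warning instead of NaN propagation, keeping
downstream binarisation total.

Group sparsity is summarised by frequency connection matrices (per-edge
subject counts) and the count of never-connected ROI pairs, optionally
within an ROI subset such as the cerebellar block.

## Node metrics

On the binary graph: degree (row sum), clustering coefficient
C_i = E_i / C(k_i, 2) with E_i the edge count among i's neighbours, and
local efficiency.  Conventions:

- C_i = 0 when k_i < 2 (no neighbour pairs), rather than NaN, so group
  statistics stay total.
- Unreachable pairs contribute 0 to efficiency sums (1/∞), the standard
  efficiency convention.
- Local efficiency has two modes because the source formula is ambiguous
  about the subnetwork it sums over.  The default `literal` mode computes
  (1/N) Σ_{j≠i} 1/L_ij over the whole graph with N the node count — the
  formula exactly as printed (note the prefactor is 1/N, not 1/(N−1), so
  values are bounded by (N−1)/N).  The `neighborhood` mode is the
  conventional local efficiency: the efficiency of the subgraph induced
  by i's neighbours, normalised by k_i(k_i−1), 0 when k_i < 2.  The mode
  tag travels with every output row.  Both modes are verified against
  exhaustive-loop reference implementations.

Shortest paths are unweighted hop counts (Dijkstra on the unweighted
graph via `scipy.sparse.csgraph`); the test suite checks them against a
Floyd–Warshall reference.

## Statistical battery and state taxonomy

Per feature (edge z-weights, or node metric values) three comparisons are
made: p1 = NC vs IBSbs (two-sample t), p2 = IBSbs vs IBS1st (paired t on
per-patient differences), p3 = NC vs IBS1st (two-sample t).  The default
two-sample variant is Welch (robust to unequal variances and reproducing
the published demographic p-values slightly more closely); the pooled
classical variant is available.  All tests are two-sided.  Bonferroni
correction is applied within each comparison family; the family size is
the number of simultaneous hypotheses — all tested edges for edge
statistics, all nodes for one metric for node statistics — and
`correction="none"` is supported since some findings are conventionally
reported uncorrected.

With S(p) = corrected p < α (default α = 0.05):

| state     | pattern                  |
|-----------|--------------------------|
| cured     | S1 ∧ S2 ∧ ¬S3            |
| disorder  | S1 ∧ ¬S2                 |
| activated | ¬S1 ∧ S2 ∧ S3            |
| unchanged | otherwise                |

"Returned to the normal level" is operationalised as non-significance of
NC vs IBS1st — the only testable reading.  The omnibus one-way ANOVA
across the three conditions is computed and stored per feature but does
not gate the decision: the state definitions are phrased purely pairwise,
and storing the ANOVA lets users impose an omnibus gate themselves.  The
direction tag comes from group-mean ordering (baseline vs NC for
disorder/cured; post vs NC for activated).  Degenerate zero-variance
paired differences are flagged rather than silently producing NaN.

Delta correlations are Pearson r between per-patient feature changes
(post − baseline) and clinical-score changes, p from the t-transform
t = r√(n−2)/√(1−r²) on n−2 degrees of freedom; n counts the fully
observed pairs.

`scipy.stats` provides the underlying test distributions and base tests;
the taxonomy, its vectorisation across features, and the correction
bookkeeping are implemented here.  Permutation tests serve as independent
oracles in the test suite, never in the pipeline.

## Synthetic cohort generator

The generator emulates the study conditions so that recovery of planted
structure is a meaningful end-to-end test.  Design choices:

- **Generative model**: stationary zero-mean multivariate normal time
  series — the simplest model whose sample Pearson correlations converge
  to a controllable target.  Temporal autocorrelation, hemodynamics,
  scanner noise spectra and motion artifacts are deliberately not
  modelled; passing tests therefore demonstrate correctness of the
  statistical machinery under the model's assumptions, not robustness to
  real fMRI noise structure.
- **Targets**: a base equicorrelation level (default 0.1, a typical mean
  positive FC level) with planted edges realising the state patterns.  A
  planted edge's control-side level defaults to the base value and can be
  set per edge; the abnormal conditions sit δ above or below it.
- **PSD repair** by symmetric eigenvalue clipping at floor 1e−6 followed
  by re-normalisation to unit diagonal: deterministic and
  structure-preserving for small δ.  If repair moves any planted entry by
  δ/10 or more the configuration is rejected with the offending edges
  named, rather than silently planting a different effect.
- **Sessions**: patient baseline and post series use independent noise
  (no within-subject FC stability across the interval is claimed by the
  emulated design; this independence is a modelling choice).  A single
  global seed expands into counter-based per-session substreams
  (`default_rng([seed, stream])`), so any subset of the cohort is
  reproducible and identical configs give byte-identical bundles.
- **Clinical scores**: normal draws with per-condition means/SDs
  defaulting to the published cohort values (IBS-SSS 245.5 ± 100 at
  baseline, 91.9 ± 49 after; IBS-QOL 132.46 ± 33.1 / 150.33 ± 13.6; HAMA
  2.48 ± 2.9 controls, 15.25 ± 7.9 / 8.17 ± 2.9 patients).  Controls
  carry the anxiety score only, mirroring the published table's empty
  cells.  The normal model can produce out-of-range values (e.g. a
  negative anxiety score) at these SDs; scores are used only as
  continuous covariates, so no truncation is applied.
- **Coupling**: a patient's change in a coupled score is
  ρ·(standardised realised Fisher-z change of the planted edge) +
  √(1−ρ²)·noise, rescaled to the configured between-session delta mean
  (post mean − baseline mean) and delta SD (√(sd_b² + sd_p²), the
  independent-sessions equivalent), then added to the baseline draw.  One
  planted edge per score; the sample correlation recovers ρ up to
  sampling noise ~(1−ρ²)/√n.

## Classifier verification

Selected edges' Fisher-z weights feed an RBF-kernel SVM trained on one
cohort and evaluated on a held-out cohort.  Features are standardised
with training-cohort mean/SD only (no leakage; verified by test).
Hyperparameters are a deliberately untuned baseline — C = 1, kernel width
1/(n_features × feature variance) — overridable via config.  The ROC is a
threshold sweep over decision scores with tied scores collapsed into one
operating point; AUC by trapezoid, equal to the Mann–Whitney U statistic
normalised by n₁n₂ (asserted in tests).  Published held-out accuracies
from the motivating study derive from unshared patient scans and are not
reproduction targets; the verification stage is validated by properties
(separable cohorts → accuracy 1, permuted labels → chance, planted-effect
cohorts → above the permutation null).

## Numerical and problem-size choices

- Correlations are clipped to [−1, 1] before arctanh to absorb
  floating-point excursions; test code clips at ±0.999999 when building
  z-stacks from finite samples.
- Calibration and power simulations run at R = 20 ROIs (190 edges) with
  the default group sizes: the taxonomy's behaviour is per-edge and
  family-size–driven, so a reduced atlas exercises the same machinery at
  simulation-friendly cost.  Null calibration uses 500 replicates at
  T = 200; the bound on the family-wise false-labelling rate is the
  one-sided 99% binomial envelope around the nominal 0.05.  Planted-edge
  power uses 100 replicates at T = 400 and δ = 0.4 (in correlation units,
  a large but plausible group effect), requiring ≥ 80% recovery of the
  cured label.  Coupling recovery uses n = 200 patients, ρ = 0.8,
  tolerance ±0.1.
- Output files are written with fixed float formats (`%.17g` for time
  series, lossless on reload; `%.10g` for derived tables), making reruns
  byte-identical.

## Known limitations

- The generator's multivariate-normal model has no temporal
  autocorrelation, so effective sample sizes per session are optimistic
  relative to real BOLD data; planted-effect power at a given T
  overstates what the same T of real data would give.
- The taxonomy is purely pairwise-significance-driven; a "cured" label
  partially reflects an accepted null (NC vs post), which is evidence of
  absence only in the power-calibrated sense.
- Only binary positive-weight networks are analysed; negative-weight and
  weighted-graph variants, FDR or permutation-based family-wise
  correction, covariate adjustment and mixed models are out of scope.
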