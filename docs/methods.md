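# Methods

## Quantification

PSI is computed per event per condition from replicate-pooled junction
counts: replicates are summed first ("merge" pooling), then
PSI = 100·I/(I+E). Pooling weights replicates by coverage, so a deep
replicate dominates a shallow one; this is the intended behavior for
junction-count data with uneven depth and is asserted as a property in the
tests (pooled PSI equals the coverage-weighted mean of per-replicate PSIs).
Events with pooled coverage below `min_coverage` (default 10 reads) get a
missing PSI in that condition and are dropped from any comparison that needs
it — per comparison, not globally, so each pairwise contrast keeps every
event it can support.

## Differential test

The per-event statistic is a two-sided Fisher exact test on the 2×2 table of
pooled inclusion/exclusion counts in the two conditions (scipy
implementation). No replicate-level dispersion is modeled: pooling discards
the replicate structure by construction, which makes the test exact for
binomial counts and anticonservative when counts are overdispersed across
replicates (see Limitations). The test name is recorded in every output
header so an alternative statistic can be slotted in behind the same
interface.

P-values are adjusted per comparison with Benjamini–Hochberg step-up
(statsmodels `fdr_bh`); adjustment never crosses comparisons, because each
comparison has its own event universe after coverage filtering. Significance
uses strict inequalities on both axes: |dPSI| > threshold (default 15
percentage points) and adjusted p < alpha (default 0.05). The dPSI sign
convention is test minus reference, with comparisons named "ref vs test".
The threshold sweep (default cut points 10, 15, 20, 25) computes the exact
tests once per comparison and re-applies the dPSI cut, so its counts are
exactly what independent per-threshold runs produce.

## Rescue classification

Events are classified from their significance pattern across CD
(control vs disease), DT (disease vs treated), and CT (control vs treated),
plus the relative direction of the CD and DT effects where the pattern is
(1,1,0): contrary directions mean the treatment reversed the disease change
and no residual difference remains (`fully_recovered`); same directions get
the neutral label `aggravated`. The named classes complete the 7-region Venn
diagram into a total partition of the feature universe (8 classes including
`not_altered`); only the fully-recovered and non-specific classes carry
biological weight, the rest are bookkeeping labels chosen to be descriptive
and direction-free. Events significant in all three comparisons are labeled
`non_specific` without a direction check; events significant in DT but not
CD are `treatment_only` regardless of CT, since both (0,1,0) and (0,1,1)
mean treatment-induced novelty.

Recovery percentages use the number of CD-significant features as the
denominator. Percentages are kept unrounded internally and rendered to one
decimal with half-away-from-zero rounding. With zero CD-significant features
the percentages are reported as undefined (`null` in JSON), never as a
division error. The classifier is generic over the effect measure: the same
code classifies splicing tables (effect = dPSI) and expression tables
(effect = log2 fold change, significant when |log2FC| > 1 and adjusted
p < 0.05).

The top-recovered ranking orders `fully_recovered` features by descending
|effect_CD| with lexicographic feature-id tie-breaks — a deterministic
convention, recorded in the output, since magnitude of the disease effect is
the natural salience measure when no other criterion is given.

## Synthetic data generator

The generator emulates a three-condition splicing study with known ground
truth. Each event has a baseline PSI drawn uniform on [5, 95] (avoiding
boundary saturation), and altered events receive a signed effect of
magnitude uniform on [min_true_dpsi, min(min_true_dpsi + 15, 50)], the sign
flipped when needed so the shifted PSI stays inside [0, 100]; the cap at 50
guarantees every requested effect is realizable, which is why
`min_true_dpsi` must lie in (0, 50]. Ground-truth classes are assigned
deterministically — rounded products of the configured fractions, placed
after a seeded shuffle — so class sizes are exact functions of the
configuration with no sampling variability in labels. Event types use the
same largest-remainder apportionment. Fully rescued events have treated PSI
equal to control; partially rescued events sit at the midpoint of control
and disease PSIs (the simplest distinct intermediate); unrescued events keep
the disease PSI; treatment-only events are perturbed only in the treated
condition.

Per-sample read depth is Poisson around `mean_depth` with floor 1 (mimicking
uneven junction coverage), and inclusion counts are binomial at the true PSI,
or beta-binomial with correlation parameter rho = `overdispersion` (the Beta
mixing distribution has mean PSI/100 and a+b = 1/rho − 1; rho = 0 reduces
exactly to binomial).

Defaults: 1000 events, 3 replicates per condition (the study design being
emulated), 20% of events disease-altered, 17% of those fully rescued
(matching the observed full-recovery fraction) and 10% halfway, 2% of
unaffected events perturbed by treatment alone, minimum true |dPSI| 20,
mean depth 100 reads per event per sample (per-event junction coverage is
a free choice; 100 is typical of moderately expressed genes at bulk
RNA-seq depth), rho 0.05 (mild biological overdispersion). Event-type mix
50% exon skipping, 20% intron retention, 15% each alternative 3'/5' sites.

What the generator does not emulate: correlated events within a gene,
library-size differences between samples, mappability or annotation errors,
event discovery itself, and dispersion that varies by expression level.
Passing tests therefore demonstrate the statistical machinery under the
stated noise model, not performance on real aligner output.

## Numerical and design choices

- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical configuration reproduces
  byte-identical output files (asserted end-to-end in the tests). Output
  headers carry the tool version and parameters; the run manifest adds
  SHA-256 checksums of any file inputs.
- Fisher p-values are exact and strictly positive, so p ∈ (0, 1] always
  holds; zero-coverage tables are rejected rather than patched, since the
  coverage filter upstream should have removed them.
- BH ties are handled by the standard min-cummin step-up formulation; no
  randomization anywhere in the pipeline.
- Scale of routine checks: the deep-coverage validation runs 1000 events ×
  3 replicates at mean depth 2000 with binomial noise and effects ≥ 30 dPSI
  over three seeds, where detection should be (and is) essentially
  noiseless; null calibration uses 2000 events at the default depth.

## Limitations

- The exact test on pooled counts ignores replicate-level overdispersion;
  with rho > 0 the raw p-values are anticonservative. The generator's
  default rho of 0.05 is deliberately mild; analyses of strongly
  overdispersed data should replace the test, not reinterpret the output.
- The pipeline starts from event-level inclusion/exclusion counts; read
  alignment, event discovery, and native output dialects of upstream
  splicing tools are out of scope.
- `aggravated` and the other bookkeeping classes are conventions of this
  package: a (1,1,0) same-direction pattern has no established name, and
  all-three-significant events are labeled non-specific without a direction
  test.
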