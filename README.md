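# splicerescue

Alternative-splicing rescue analysis for three-condition RNA-seq designs:
control, disease, and drug-treated disease. The motivating setting is
myotonic dystrophy type 1 (DM1), where expanded CUG-repeat RNA sequesters
MBNL splicing factors and causes genome-wide mis-splicing; a candidate
compound is judged by how many disease-altered splicing events it moves back
toward the control state. The package quantifies percent-spliced-in, calls
differential splicing in the three pairwise comparisons, classifies every
event's response to treatment, and reports recovery percentages. A synthetic
data generator with known ground truth stands in for raw sequencing data.

## Model

For a splice event with pooled inclusion reads *I* and exclusion reads *E*
in one condition, the percent-spliced-in is

    PSI = 100 · I / (I + E),

computed after summing counts over the condition's replicates ("merge"
pooling), and reported only when *I* + *E* ≥ `min_coverage` (default 10).
For two conditions the effect size is dPSI = PSI_test − PSI_ref, tested with
a two-sided Fisher exact test on the 2×2 pooled count table and adjusted per
comparison with Benjamini–Hochberg. An event is **significant** when
|dPSI| > 15 (strict) and adjusted p < 0.05 (strict).

Three comparisons are run — CD (control vs disease), DT (disease vs
treated), CT (control vs treated) — and each event is classified by its
significance pattern (sig_CD, sig_DT, sig_CT) and effect directions:

| pattern            | class                 |
|--------------------|-----------------------|
| (1,1,0), contrary  | `fully_recovered`     |
| (1,1,0), same sign | `aggravated`          |
| (1,1,1)            | `non_specific`        |
| (1,0,1)            | `disease_persistent`  |
| (1,0,0)            | `disease_unresponsive`|
| (0,1,·)            | `treatment_only`      |
| (0,0,1)            | `residual_only`       |
| (0,0,0)            | `not_altered`         |

The full-recovery percentage is 100 · |fully_recovered| / |sig_CD|, likewise
for the non-specific percentage; `treatment_specific_count` is
|fully_recovered| + |non_specific|.

## Worked example

```python
import splicerescue as sr

cfg = sr.PipelineConfig(
    outdir="run1",
    simulation=sr.SimulationConfig(
        n_events=300, mean_depth=2000.0, overdispersion=0.0,
        min_true_dpsi=30.0, seed=3,
    ),
    seed=3,
)
report = sr.run_pipeline(cfg)
print(report.to_dict())
```

prints (reformatted):

```
n_features 300, n_cd_significant 60
class_counts: fully_recovered 11, non_specific 5, disease_persistent 44,
              treatment_only 5, not_altered 235, others 0
full_recovery_pct 18.3, non_specific_pct 8.3, treatment_specific_count 16
```

Of the 300 simulated events, 60 are altered in disease (frac_disease = 0.2)
and all are detected (`n_cd_significant` = 60). The generator fully restores
about 17% of them (10 events) plus 6 halfway; the classifier labels 11
`fully_recovered` (the 10 full rescues plus one partial rescue whose
residual control-vs-treated difference falls under the 15-point cut), the
remaining partials and all unrescued events `disease_persistent` or
`non_specific`, and treatment-only perturbations `treatment_only`.
`full_recovery_pct` = 100·11/60 = 18.3.

The same pipeline is available from the shell:

```sh
splicerescue simulate --outdir sim --seed 3
splicerescue psi --counts sim/counts.tsv --design sim/design.tsv --out psi.tsv
splicerescue diff --psi psi.tsv --ref CTRL --test DM1 --out cd.tsv
splicerescue sweep --psi psi.tsv --thresholds 10,15,20,25 --out sweep.tsv
splicerescue classify --cd cd.tsv --dt dt.tsv --ct ct.tsv \
    --out-labels labels.tsv --out-report report.json
splicerescue run --config pipeline.yaml --seed 3
```

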