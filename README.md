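# hippodx

Hippocampal volumetry diagnostics for temporal lobe epilepsy with
hippocampal sclerosis (HS).

MRI volumetry of the hippocampus and its subfields is routinely used to
support the diagnosis of unilateral HS: the sclerotic hippocampus is
atrophic, and the loss is most visible after adjusting for head size and
when the two hemispheres are compared against each other. `hippodx` turns
that workup into a tested pipeline for clinical researchers and imaging
scientists:

* parse FreeSurfer-style plain-text stats outputs (with an eTIV header
  line) and volBrain-HIPS-style CSV reports into one canonical
  subjects-by-features table;
* compute the derived statistics: percent-of-TIV normalized volumes,
  the laterality asymmetry index, z-scores against a healthy-control
  reference, and mean/95%-CI reference ranges per group;
* fit ROC curves for any scalar discriminator and report the optimal
  diagnostic cutoff;
* validate the morphometric signal with a random-forest classifier under
  Monte-Carlo cross-validation, with progressive feature elimination by
  Gini importance;
* simulate cohorts whose group distributions match published reference
  values for healthy controls and right-/left-HS patients, so the whole
  pipeline is testable without access to patient data.

## The statistics

For a structure with volume `V` (mm³) and estimated total intracranial
volume `TIV`:

* normalized volume (percent of TIV): `%TIV = V × 100 / TIV`
* asymmetry index (percent, positive = right larger):
  `AI = (R − L) / ((R + L)/2) × 100`, bounded in (−200, 200)
* patient z-score against the control reference:
  `z = (%TIV − mean(%TIV_HC)) / sd(%TIV_HC)`
* reference range: `mean ± t_{n−1,0.975} · sd / √n`

ROC AUC is the Mann–Whitney pair-ordering probability (ties count ½), and
the reported cutoff maximizes Youden's `J = sens + spec − 1`, placed midway
between the adjacent distinct scores. The random-forest validation runs
stratified 80/20 shuffle-splits; progressive feature elimination drops the
feature with the lowest mean Gini importance across splits, the working
feature count is the smallest one within one standard error of the best
mean accuracy, and a final, larger set of splits yields the accuracy,
accumulated confusion matrix, per-subject class probabilities, one-vs-rest
ROC curves, and importances normalized to the trivial level `1/N`.

## Worked example

```python
import hippodx as h
from hippodx.derived import derived_features
from hippodx.pipeline import standard_roc_tasks
from hippodx.roc import diagnostic_table

table, labels = h.simulate_cohort(h.CohortSpec(seed=7))   # 61 HC, 22 RHS, 35 LHS
feats = derived_features(table)
print(diagnostic_table(feats, table.groups, standard_roc_tasks(table)).round(3))
```

```
           discriminator  ref_value  sens  spec_1   auc      task          direction
FS_Hippocampus_right_pct      0.194 0.727   0.066 0.898 RHS_vs_HC  lower_is_positive
    FS_Hippocampus_right   2925.085 0.727   0.180 0.820 RHS_vs_HC  lower_is_positive
     FS_Hippocampus_asym     -8.766 1.000   0.000 1.000 RHS_vs_HC  lower_is_positive
 FS_Hippocampus_left_pct      0.190 0.800   0.033 0.894 LHS_vs_HC  lower_is_positive
     FS_Hippocampus_left   2909.670 0.857   0.180 0.886 LHS_vs_HC  lower_is_positive
     FS_Hippocampus_asym      8.686 0.971   0.033 0.980 LHS_vs_HC higher_is_positive
```

Each row is one discriminator against healthy controls for one patient
group: `ref_value` is the optimal cutoff in the discriminator's units
(%TIV, mm³, or asymmetry percent), with its sensitivity, 1−specificity and
AUC. On this cohort the asymmetry index separates right-HS patients from
controls perfectly (AUC 1.000 at a cutoff of −8.8%), while the right
hippocampus %TIV volume alone reaches AUC 0.898 — the asymmetry index is
the strongest discriminator, because each patient serves as their own
control.

The same model/results pattern applies to single discriminators and to the
classifier validation:

```python
res = h.ForestValidation.from_table(table, "HC_vs_HS", h.PFEConfig(seed=1)).fit()
print(res.summary())          # selected features, accuracy, confusion matrix
```

A command-line interface mirrors the library:
`hippodx simulate | ingest | derive | refvalues | roc-table | validate-rfc | run-all`.

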