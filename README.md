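# lesionwise

Lesion-wise evaluation of multi-lesion brain tumor segmentations.

Brain metastases are often numerous and small, and a model that segments one
large lesion perfectly while missing five tiny ones still gets an excellent
whole-image Dice score. Challenge organizers and clinical evaluators instead
score *per lesion*: ground truth and prediction are decomposed into lesion
units, each unit is scored individually, and missed or spurious lesions incur
fixed penalties, so detection of small metastases carries real weight. This
package implements that evaluation framework as a tested library and CLI for
people who run segmentation benchmarks, evaluate metastasis-segmentation
models, or need a reference implementation of the metrics: lesion matching,
penalized lesion-wise Dice and HD95, cohort analytics, challenge ranking with
permutation significance testing, the multi-rater fusion stage used when
building consensus ground truth, and a synthetic phantom generator so every
code path is testable without patient data.

## The metrics

Label maps follow the multi-class convention 1 = non-enhancing tumor core
(NETC), 2 = peritumoral FLAIR hyperintensity (SNFH), 3 = enhancing tumor (ET),
evaluated over three composite regions: ET = {3}, tumor core TC = {1, 3},
whole tumor WT = {1, 2, 3}.

For each region the ground truth is dilated by 1 voxel (26-neighborhood) and
decomposed into 26-connectivity connected components, so satellite lesions
adjacent to a primary lesion form one evaluation unit; scoring always uses
the *undilated* ground-truth voxels. Predicted components are matched to the
unit whose dilated support they overlap; unmatched predicted components are
false positives (FP), unmatched units are false negatives (FN). Units of ≤ 2
voxels (2 mm³ at 1 mm isotropic) are excluded as likely annotation noise.
Case-level scores for a region are

    lesion-wise Dice = ( Σ_i Dice_i ) / (TP + FN + FP)
    lesion-wise HD95 = ( Σ_i HD95_i ) / (TP + FN + FP)

where a true-positive unit contributes its Dice and its 95th-percentile
surface distance (pooled bidirectional, Euclidean in mm), each FN contributes
Dice 0 and a fixed HD95 penalty of **374 mm**, and each FP contributes 0 to
the Dice numerator and the same 374 mm penalty to the HD95 numerator.

Teams are ranked per subject, region, and metric (midranks for ties; Dice
descending, HD95 ascending); the mean of a team's six slot ranks in a subject
is its *cumulative rank*, and the mean of cumulative ranks over subjects is
the final ranking score (FRS, lower is better). Pairwise significance is a
paired sign-flip permutation test on per-subject cumulative ranks (100 000
permutations by default; exhaustive enumeration for ≤ 20 subjects).

For consensus ground-truth construction, SNFH rater masks are fused with
binary STAPLE (EM estimation of a consensus plus per-rater sensitivity and
specificity), ET masks with a minority-vote union (any single detection is
kept), and the NETC mask overlays both.

## Worked example

```python
from lesionwise import (PhantomConfig, PerturbationConfig, generate_phantom,
                        perturb_prediction, evaluate_case)

gt, manifest = generate_phantom(PhantomConfig(seed=42))
pred, expected = perturb_prediction(gt, manifest, PerturbationConfig(seed=7))
scores = evaluate_case(gt, pred, case_id="case042")
for region, rs in scores.regions.items():
    print(f"{region}: lesion-wise Dice {rs.lesionwise_dice:.3f}  "
          f"HD95 {rs.lesionwise_hd95:.1f} mm  "
          f"(TP={rs.tp} FN={rs.fn} FP={rs.fp})  legacy Dice {rs.legacy_dice:.3f}")
```

```
ET: lesion-wise Dice 0.750  HD95 93.5 mm  (TP=3 FN=1 FP=0)  legacy Dice 0.993
TC: lesion-wise Dice 0.750  HD95 93.5 mm  (TP=3 FN=1 FP=0)  legacy Dice 0.993
WT: lesion-wise Dice 0.750  HD95 93.5 mm  (TP=3 FN=1 FP=0)  legacy Dice 0.972
```

The phantom has four enhancing lesions (15, 91, 559 and 389 mm³); the
perturbation dropped the 15 mm³ one. Whole-region ("legacy") Dice barely
notices the miss (0.993), while lesion-wise Dice falls to 3/4 of the mean
matched-lesion Dice and the missed lesion's 374 mm penalty pushes the
lesion-wise HD95 to 93.5 mm — exactly the small-lesion sensitivity the
framework is designed to reward.

The same pipeline from the shell:

```bash
lesionwise simulate --out cohort/ --n-cases 20 --seed 1
lesionwise evaluate cohort/ cohort/ --out scores/
lesionwise rank scores.csv --out ranking/ --seed 1   # long-format team scores
lesionwise fuse --snfh r1.nii.gz --snfh r2.nii.gz --snfh r3.nii.gz \
                --et r1_et.nii.gz --out fused.nii.gz
```

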