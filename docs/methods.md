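# Methods

This note records the evaluation model implemented by `lesionwise`, the
conventions chosen where toolkits legitimately differ, and what the synthetic
phantoms do and do not establish about behavior on real data.

## Lesion matching

A region mask (ET, TC or WT) is decomposed into *evaluation units* by
dilating the ground truth and taking 26-connectivity connected components of
the dilated mask. Dilation uses the full 3×3×3 structuring element — the
neighborhood that defines 26-connectivity — for `dilation_voxels` iterations
(default 1). Component ids are assigned by first-voxel order in a C-order
scan, so the labeling is deterministic and reproducible across runs.

Two consequences of dilating before component analysis are intended: lesions
whose gap is small (Chebyshev distance ≤ 2·dilation + 1) merge into a single
unit, so a satellite nodule beside a primary lesion is not scored as a
separate miss; and a prediction that lands within one voxel of a lesion
surface still matches it. The dilated voxels exist only for unit formation
and matching — every score is computed on the undilated ground-truth voxels,
and a merged unit's volume is the sum of its members' undilated voxels.

Each predicted 26-connectivity component is matched to the unit whose
dilated support it overlaps. A component overlapping several units is
assigned entirely to the unit with the largest voxel overlap, ties breaking
toward the lower unit id; splitting one predicted component across units is
deliberately forbidden so that every component is attributed to exactly one
category (matched or FP), keeping the counts a partition. A component
overlapping no unit is an FP, unless its volume is at or below the exclusion
threshold.

The exclusion threshold (`min_lesion_voxels`, default 2 voxels = 2 mm³ at
1 mm isotropic) is applied symmetrically: ground-truth units at or below it
are excluded from all counts, and unmatched predicted components at or below
it are ignored rather than counted as FP. The threshold exists to absorb
stray-voxel annotation error, and stray voxels occur on both sides of a
comparison; penalizing a model for a 2-voxel speck while forgiving the same
speck in the reference would be inconsistent. Exclusion is evaluated after
unit formation, on the unit's undilated volume. Volumes are voxel count ×
voxel volume from the header spacing, so at 1 mm³ the voxel and mm³ numbers
coincide.

## Scores and penalties

Per region, the case-level scores divide a numerator summed over units and
FP components by `TP + FN + FP`:

* a TP unit contributes its Dice and HD95 between the unit's undilated
  ground-truth voxels and the union of its matched predicted components;
* an FN unit contributes Dice 0 and the fixed HD95 penalty (374 mm);
* an FP component contributes 0 to the Dice numerator and the full 374 mm to
  the HD95 numerator.

Charging FPs in the HD95 numerator (rather than summing only over
ground-truth lesions) is required for the stated penalty semantics to hold:
without it, a case whose prediction contains only spurious lesions would
have an empty sum and an undefined or vacuously perfect score, while the
framework's intent is that false positives are rigorously penalized. The
same denominator is used for Dice so both metrics move on the same scale of
evaluable units. With no evaluable units and no FPs (`TP+FN+FP = 0`, e.g. an
empty region with an empty prediction) the case scores Dice 1 and HD95 0 by
the vacuous-truth convention long used for empty-region cases in tumor
benchmarks.

**HD95 convention.** HD95 is the 95th percentile (linear interpolation) of
the *pooled bidirectional* multiset of surface distances: every boundary
voxel of A to its nearest boundary voxel of B, and vice versa. This is
stated explicitly because other toolkits take the maximum of two directed
95th percentiles, which differs. Boundary voxels are foreground voxels with
at least one background 6-neighbor, with the array border treated as
background; distances are Euclidean in mm using the header spacing. A
computed TP HD95 larger than the penalty is clipped to 374 mm so the penalty
is the metric's supremum and the all-miss case is the exact worst case.
HD95 of an empty mask is an error; callers substitute the penalty, never a
silent default.

Legacy whole-region Dice/HD95 are computed on the full region masks and
reported alongside for comparison only; an empty-vs-nonempty legacy pair
takes the penalty value, an empty-vs-empty pair is perfect.

## Cohort analytics

Three rates summarize detection over a cohort, per region. The *lesion
detection rate* is the micro-average ΣTP / Σ(TP+FN) pooled over all cases —
every lesion counts equally, so large multi-lesion cases dominate.
*Sensitivity* is the macro-average of per-case TP/(TP+FN), skipping cases
with no ground-truth lesions — every case counts equally. The two coincide
only when all cases carry the same lesion count, which is why both are
reported; the micro/macro reading of the two headline rates is this
package's inference, as the distinction is rarely spelled out. *PPV* is
pooled ΣTP / Σ(TP+FP); a cohort with no positive predictions reports PPV 1
with a warning (no claims were made, none were wrong), and a cohort with no
evaluable lesions at all is an error rather than a set of NaNs.

Size-stratified curves are running averages within an expanding volume
window: lesions sorted by ascending volume, point k the mean of the metric
(Dice, HD95, or detection flag, penalties substituted for misses) over the
k smallest, ties entering together. The curve starts at the smallest lesions
precisely because that is where segmentation models degrade.

## Ranking

Per (subject, region, metric) slot, teams are ranked with midranks for ties
(keeping each slot's rank sum at T(T+1)/2), Dice descending and HD95
ascending. Cumulative rank = mean of a team's slot ranks within a subject;
FRS = mean of cumulative ranks over subjects. The score grid must be
complete; missing cells are an error naming the gaps, because silently
dropping a subject would change every team's FRS.

The pairwise test permutes *within subjects*: each permutation independently
swaps (or not) the two teams' cumulative ranks for each subject, equivalent
to sign-flipping the paired differences. The statistic is the FRS
difference; the default is two-sided (|ΔFRS| exceedance), with a one-sided
flag. With n ≤ 20 subjects all 2ⁿ patterns are enumerated and the p-value is
exact; above that, Monte Carlo with `n_permutations` draws (default 100 000)
and add-one smoothing (count+1)/(N+1), which floors the p-value at 1/(N+1)
instead of reporting an impossible 0. Two seeds differ by at most
Monte-Carlo error ~3·√(p(1−p)/N).

## Fusion

Binary STAPLE treats each rater j as a noisy channel over a hidden true
mask, with sensitivity p_j and specificity q_j, voxels independent. The
E-step computes the voxel posterior of foreground from the current (p_j,
q_j) and a prior; the M-step re-estimates (p_j, q_j) from the posteriors;
the data log-likelihood is recorded each iteration and is non-decreasing (a
property test asserts this). Defaults: p_j = q_j = 0.99999 initialization
(the conventional near-perfect start), tolerance 1e-6 on the largest
parameter change, 100 iterations max, consensus threshold 0.5. The prior
defaults to the scalar mean foreground fraction across raters — a
data-driven choice, since no prior is prescribed for this pipeline;
voxel-wise spatial priors are out of scope. Degenerate raters (empty or
full masks) trigger a warning and parameter clamping into (ε, 1−ε) rather
than a crash, since EM otherwise hits log(0). A `per_component` flag runs
STAPLE independently per connected component of the union support, limiting
the background-dominance bias a global run suffers when foreground is a tiny
fraction of the volume; the default is the global, literal reading.

"Minority voting" for ET is the any-vote union: one rater suffices to keep a
voxel, because small metastases are the modal miss of automated raters and
the fusion stage feeds human refinement, where deleting a false detection is
cheaper than spotting a miss. A vote threshold k is exposed for sensitivity
analysis. Composition precedence is NETC (1) over ET (3) over SNFH (2):
the necrotic core is by definition surrounded by enhancing tumor, and only
one rater produces it, so it overlays both other labels.

## Phantoms

The generator emulates the *lesion statistics* of multi-institutional
metastasis cohorts, not their appearance: lesions are spheres with an
enhancing shell, an optional necrotic core (40 % of the radius, in 30 % of
lesions large enough to plausibly necrose, r ≥ 2.5 mm), and a 2 mm edema
halo. Per-case lesion count is 1 + Poisson(1.5) (median 2; reference cohorts
report per-case medians of 2–3 enhancing lesions), and the enhancing radius
is lognormal with median 2.8 mm and σ = 0.55, clipped to [1.5, 12] mm, which
puts the median discrete enhancing volume near 90 mm³ — inside the 65–141
mm³ range of cohort medians — while spanning sub-5 mm detections to
centimeter-scale lesions. Lesion surfaces (including halos) are kept ≥ 6 mm
apart; 6 mm exceeds 3√3 mm, the worst-case diagonal reach at which two masks
each dilated by one voxel could become 26-connected, so every phantom lesion
is guaranteed to be its own evaluation unit. Placement is rejection sampling
with bounded retries; an infeasible configuration raises a packing error
rather than looping.

The perturbation module plants known errors: whole-lesion dropout with
probability `dropout_max · 2^(−V/halflife)` (defaults 0.8 and 100 mm³ — a
60 mm³ lesion is missed ~53 % of the time, a 500 mm³ lesion ~2.5 %),
mimicking the small-lesion misses that dominate automated segmentation
error; spurious enhancing blobs placed ≥ 6 mm clear of every lesion so their
FP status is unambiguous under the matcher; and boundary jitter implemented
as re-rendering surviving lesions with a perturbed radius. With jitter off,
the prediction is re-rendered from the same geometry, so the planned
TP/FN/FP counts are exact and the end-to-end consistency test can assert
equality, not approximation.

What phantom-based tests establish: the matching, scoring, aggregation,
ranking and fusion machinery is correct against independent oracles and
generator-known truth. What they do not establish: behavior on real MRI
label maps with irregular lesion shapes, confluent edema shared between
lesions, annotation noise, or registration artifacts — phantom lesions are
well-separated spheres by construction, so real-data edge cases (two lesions
merging into one unit, predicted components straddling units) are covered by
targeted unit tests rather than by the generator.

## Problem sizes and numerical choices

Default grids are 64³ (phantoms) and 32³ (fixtures); the acceptance cohort
uses 50 phantom cases, and STAPLE recovery is checked on a 64³ truth with
five simulated raters — sizes at which every property of interest is already
exercised and the full suite runs in well under a minute of compute per
module. Exact permutation enumeration caps at 20 subjects (2²⁰ ≈ 10⁶
patterns vectorized). All randomness flows from explicit
`numpy.random.default_rng` seeds; phantom manifests are serialized as JSON
next to the volumes, and a fixed seed reproduces volumes bit for bit.

## Known limitations

* Binary STAPLE only; multi-class consensus is out of scope, matching the
  per-tissue fusion design.
* Predictions are binary label maps; probabilistic/soft segmentations must
  be thresholded upstream.
* No resampling: compared volumes must share shape and spacing, since
  registration to a common atlas is assumed done upstream.
* The matcher never splits one predicted component across ground-truth
  units; a single blob covering two distant lesions scores as one match
  plus one miss, which is the deterministic reading of
  component-to-component comparison.
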