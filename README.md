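# dotgrouping

Perceptual grouping of moving dots by colour or by common motion, as a
fully executable desk-scale pipeline: the random-dot stimulus generator, a
synthetic multi-subject BOLD simulator with known ground truth, and the
two-level GLM analysis — parametric number-of-groupings modulators, 120 s
discrete-cosine high-pass, summary-statistics random effects, sign-flip
cluster-extent inference and conjunction by masking — plus the behavioural
and eye-tracking summaries.

The package is for researchers who want every computational rule of this
class of experiment to be testable: each kinematic constant of the
stimulus is measurable on generated sequences, and the analysis stack is
validated by parameter recovery on simulated cohorts rather than by
inspection.

## The stimuli

A field of 680 dots (10 px diameter) starts on a 34 × 20 grid over a
1024 × 768 px area, jittered by ±10 px per axis. Between 0 and 3 circular
grouping regions (100 px diameter) are placed uniformly at random,
non-overlapping and fully inside the field. Per frame, each ungrouped dot
updates its heading θ by a uniform increment in [−0.2, 0.2] rad, a
rightward bias of 1.5 px/frame is added to its velocity, and the result is
renormalised so every dot moves exactly 1.7 px/frame, wrapping toroidally
at the edges. Grouping is either chromatic — dots inside the (static)
regions display one shared random colour and revert to their own colour on
leaving — or kinetic — dots initialised inside the regions share a single
unbiased random walk and reverse direction at screen edges. Kinetic
stimuli are settled by 100 non-displayed burn-in frames. Greyscale
palettes replace each random RGB colour by the grey level of its CIELAB
L\* lightness. Stimuli play for 5 s followed by a 3 s blank; static
variants are single frames drawn from zero-group sequences.

## The analysis

For voxel time series **y** and design matrix **X** (condition boxcars and
mean-centred grouping-count modulators convolved with a canonical
double-gamma HRF, temporal derivatives, unconvolved nuisance regressors,
per-session intercepts), the first level is OLS,

    b = (XᵀX)⁻¹Xᵀy,   t = cᵀb / √(σ̂² · cᵀ(XᵀX)⁻¹c),

after projecting a DCT basis of periods ≥ 120 s out of data and design.
Per-subject contrast images (sessions concatenated) go to a voxelwise
one-sample t-test (dof = n−1). Group maps are thresholded at p < 0.001
(one-sided), clustered by 18-connectivity, and each cluster's
familywise-corrected p is the permutation probability that the maximum
cluster size under random sign flips of the subject maps reaches its size.
Conjunctions keep the primary contrast's suprathreshold voxels that are
also suprathreshold in the masking contrast at uncorrected p < 0.05.

## Worked example

```python
import numpy as np
from dotgrouping import (
    SimConfig, generate_sequence, ScanProtocol, default_ground_truth,
    simulate_cohort, fit_subject, contrast_t, second_level,
)
from dotgrouping.inference import cluster_inference, conjunction_by_masking

seq = generate_sequence(SimConfig(condition="moving_colour", n_groups=3, seed=1))
print(f"{seq.n_frames} frames x {seq.n_dots} dots; "
      f"{len(seq.regions)} grouping regions")

truth = default_ground_truth()   # 20^3 volume, slope 0.5 per grouping
cohort = simulate_cohort(n_subjects=16, protocol=ScanProtocol(), truth=truth, seed=1)
colour_maps, motion_maps = [], []
for subj in cohort:
    res, cons = fit_subject(subj.sessions)
    colour_maps.append(contrast_t(res, cons["colour_slope"]).effect)
    motion_maps.append(contrast_t(res, cons["motion_slope"]).effect)
colour_maps, motion_maps = np.vstack(colour_maps), np.vstack(motion_maps)

for name in ("v4_like", "v5_like", "cerebellum_like"):
    mask = truth.region(name).mask(truth.shape).ravel()
    print(f"{name:16s} colour slope {colour_maps[:, mask].mean():+.3f}  "
          f"motion slope {motion_maps[:, mask].mean():+.3f}")

clusters = cluster_inference(colour_maps, truth.shape, n_perm=199, seed=1)
conj = conjunction_by_masking(second_level(colour_maps, shape=truth.shape),
                              second_level(motion_maps, shape=truth.shape))
```

Output:

```
250 frames x 680 dots; 3 grouping regions
v4_like          colour slope +0.468  motion slope +0.003
v5_like          colour slope +0.028  motion slope +0.516
cerebellum_like  colour slope +0.478  motion slope +0.479
```

The estimated response gain per additional grouping is ~0.5 (the
generating value) exactly where each slope was injected: the colour slope
in the V4-like region only, the motion slope in the V5-like region only,
and both in the shared cerebellum-like region. The cluster table marks the
three colour-slope regions significant (sizes 33, 19, 33; corrected
p = 0.005–0.01) while the scattered single-voxel clusters are not
(p ≈ 0.99), and the conjunction of the two slope maps returns 36 voxels
centred on the shared region.

Every stage is also exposed on the command line:

```sh
dotgrouping simulate-stimuli --condition moving_greyscale --groups 2 --seed 1 --out stim.tsv
dotgrouping simulate-bold --subjects 16 --seed 1 --out bold/
dotgrouping run-all --seed 42 --out run/
```

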