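# Methods

This note documents the models implemented in `dotgrouping`, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical and design choices made where more than one
reasonable implementation existed.

## Stimulus model

### Dot kinematics

Each stimulus is a field of `n_dots` (default 680) dots of
`dot_diameter_px` = 10 px on a `field_w_px × field_h_px` = 1024 × 768 px
area. Dots are initialised on a cell-centred regular grid and offset by
independent uniform draws in [−`jitter_px`, +`jitter_px`] (default 10 px)
per axis. The grid is 34 columns × 20 rows: 34·20 = 680 exactly, and the
column/row ratio approximates the field's 4:3 aspect. Offsets that carry a
dot over the field edge are wrapped immediately, consistent with the
running wrap rule (at the default geometry the first grid line sits
~15 px from the edge, so this never fires).

The per-frame update of an ungrouped dot is, in order:

1. heading jitter: θ′ = θ + U(−`dir_jitter_rad`, +`dir_jitter_rad`)
   (default ±0.2 rad), one draw per dot per frame;
2. raw velocity: **v** = s·(cos θ′, sin θ′) + (`x_bias_px_per_frame`, 0)
   with s = `speed_px_per_frame` = 1.7 and bias 1.5 px/frame;
3. renormalisation: displacement = s·**v**/‖**v**‖, so every dot moves
   exactly 1.7 px every frame; the stored heading becomes the direction of
   the realised displacement.

The pre-bias magnitude in step 2 is a free choice (only the ratio of bias
to heading-vector length matters after renormalisation); using the nominal
speed s makes that ratio (1.5/1.7) scale-free in the configuration. Since
bias < speed, ‖**v**‖ cannot vanish; a fallback to the jittered heading
guards non-default configurations where it could.

Ungrouped dots wrap toroidally, `x mod field_w`, `y mod field_h`. A float
subtlety: the modulo of a tiny negative coordinate can round up to the
field bound itself; such values are mapped to 0 to keep positions in the
half-open interval.

### Grouping regions

0–3 circular regions of `region_diameter_px` = 100 px are placed by
rejection sampling: centres uniform over the rectangle that keeps the
whole disc inside the field, a candidate rejected if its centre lies
within one diameter of an accepted centre. "Not coincident" is thus read
as *non-overlapping discs*; the weaker reading (only identical centres
forbidden) would allow visually merged regions, defeating the count task.
The sampler caps iterations (10,000) and raises on pathological
configurations; at the default geometry three regions are placed in a
handful of draws.

### Chromatic grouping (moving colour)

All dots follow the ungrouped kinematics. Regions are static. A dot whose
*centre* lies inside any region disc (boundary counts as inside; dot
radius ignored) displays the single per-stimulus group colour, drawn once
uniformly from the 8-bit RGB cube and shared by all regions; outside, it
displays its own base colour, so reversion on exit is exact by
construction.

### Kinetic grouping (moving greyscale)

Dots whose centres lie inside a region *at initialisation* are marked
grouped, permanently. All grouped dots — across all regions — share one
heading that random-walks with the same ±0.2 rad jitter (a single draw per
frame) but receives **no** rightward bias, and all receive the identical
displacement vector of length 1.7 px. If any grouped dot would leave the
field, the shared heading is reversed by 180° (the literal reading;
axis-wise reflection is the alternative) before the move. If the reversed
move would *also* exit — impossible at the default geometry, where groups
start well inside the field — the group holds position for one frame, so
containment is unconditional. Kinetic stimuli are settled by
`burn_in_frames` = 100 simulated, non-displayed frames before the
displayed frames are recorded; chromatic stimuli need no burn-in because
all dots share the same kinematics.

### Palettes, timing, static variants

Base colours are uniform over the full 8-bit RGB cube. Greyscale palettes
replace each colour by the 8-bit encoding of its CIELAB lightness,
`round(255·L*/100)`, using the sRGB transfer function with the D65 white
point (the conversion runs through `skimage.color.rgb2lab`); black maps
to 0 and white to 255, so the greyscale palette is the lightness
distribution of the colour palette. Stimuli display for
`stim_duration_s` = 5 s at `frame_rate_hz` (default 50 Hz — implied by a
dot of ~0.2° moving at 1.7°/s when 10 px ≈ 0.2°), followed by a 3 s
blank. Static variants are a single frame drawn uniformly from a
zero-group moving sequence of the matching palette; no burn-in is applied
to the source sequence, since burn-in exists only to heal the holes left
by grouped motion and zero-group sequences have none.

### Reproducibility

One root seed per sequence spawns independent named substreams
(positions, colours, regions, directions, group, static), so changing the
draw count of one component never perturbs the others. Identical
configuration + seed gives bitwise-identical sequences. Frame dumps are
tab-separated UTF-8 with the full configuration in the header and
shortest-round-trip float formatting, so export→import is lossless.

## Synthetic BOLD model

### Event design

Trials sit at a fixed 8 s pitch (5 s stimulus + 3 s blank) — no further
jitter is assumed. The category sequence follows a first-order Markov
chain over the six analysis categories (moving colour grouped/ungrouped,
moving greyscale grouped/ungrouped, static colour, static greyscale) with
self-transition probability `stay_probability` = 0.3 against 1/6 ≈ 0.17
under uniform sampling — "semi-random, favouring short runs". Grouped
categories draw 1–3 groupings uniformly; ungrouped and static trials have
zero. (The marginal grouping-count distribution within a moving trial
type is therefore ½, ⅙, ⅙, ⅙ for 0–3 — the grouped/ungrouped split is
carried by the chain states, mirroring the six condition regressors.)
Simulated keypresses use accuracy 80/89/85% for 1/2/3 groupings and mean
RTs of 2926/2923/2790 ms (SD 300 ms), the study-level behavioural
profile.

### Forward model

The default volume is a 20³ voxel toy (full-brain geometry adds nothing
to correctness and much to runtime) containing five spherical effect
regions: a colour-slope-only region ("V4-like"), a motion-slope-only
region ("V5-like"), two contiguous non-overlapping compartments
("IPS-like"), and one region carrying both slopes ("cerebellum-like").
Voxel signal is

    y = Σ_k a_k·(boxcar_k ⊛ h) + s_c·(m_c ⊛ h) + s_m·(m_m ⊛ h)
        + baseline + drift + AR(1) noise

with condition amplitudes a_k, colour/motion grouping slopes s_c, s_m,
mean-centred grouping-count modulators m, and the same double-gamma HRF h
the analysis uses — so the noiseless model is exactly identifiable and
the analysis recovers the generating amplitudes to machine precision.
Drift is a sum of sinusoids with periods ≥ 160 s (default 160 s and 320 s,
amplitude 2), deliberately beyond the 120 s high-pass cutoff so the
filter must remove it. Noise is AR(1) with coefficient 0.3 and marginal
SD 1.0 (innovation SD scaled by √(1−φ²)). Seven equilibration volumes are
simulated at the start of each session and dropped. Sessions (default 2
per subject) share the subject's effect draws but have independent event
orders and noise; subject effects are Normal around the group means with
`between_subject_sd` = 0.1.

Default effect sizes — condition amplitude 1.0 (0.5 static), slope 0.5
per grouping, noise SD 1.0 — were fixed by a design-stage power argument:
with 16 subjects × 2 sessions × 54 trials, the subject-level slope
standard error is ≈0.2 per voxel, ≈0.03 for a ~45-voxel region mean, so
second-level region t-values land in the 15–25 range. That is the
clear-effect regime the experiment reports, while single-voxel inference
remains non-trivial.

Nuisance series are 6 slow random-walk "motion parameters" plus a binary
keypress regressor (stick at the volume nearest each response). Synthetic
gaze logs scatter isotropically around fixation at 500 Hz with blink-like
~100 ms invalid runs; a dispersion gain during grouping epochs is
available but defaults to 1.0, the null relationship the experiment
observed.

### What the generator does *not* emulate

No MR physics (T1/T2\*, slice timing, susceptibility), no anatomy or MNI
geometry, no spatial correlation of the voxel noise, no motion-induced
signal coupling, no physiological noise spectra, no retinotopy. Passing
recovery tests therefore demonstrates the *statistical* correctness of
the pipeline under its own generative assumptions — unbiasedness,
calibration, dissociation logic — not robustness to the artefact
structure of real scanner data.

## GLM analysis

### Design matrices

Two variants mirror the experiment's two models. The six-condition
variant has one 5 s boxcar per analysis category; the four-condition
parametric variant has one boxcar per trial type plus, for the two moving
types, a linear modulator whose value is the trial's grouping count,
mean-centred across that condition's events *within each session* before
convolution (centring decorrelates modulator and condition regressor; the
condition column keeps the mean response, the modulator the per-grouping
increment). A modulated condition with no grouping variation in a session
contributes no modulator column (it would be identically zero).

Regressors are built on a microtime grid of TR/16, convolved with the
canonical double-gamma HRF (peak delay 6 s, undershoot delay 16 s, unit
dispersions, undershoot ratio 6, 32 s support, unit-sum normalisation),
and sampled at volume onsets. Each condition and modulator regressor gets
a temporal-derivative twin (convolution with the finite-difference
kernel); derivatives are treated as confounds, not contrasted. Nuisance
columns enter unconvolved; an intercept closes each session. Rank is
checked after assembly and collinear columns are named in the error.

### High-pass filter

Drift handling projects the residual-forming complement of an orthonormal
DCT basis — every cosine with period ≥ 120 s, highest order
⌊2·N·TR/120⌋ — out of both data and design. This is numerically identical
(to 1e−6 in t) to including the DCT set as confound columns, which the
test suite verifies; the equivalence requires counting the projected-out
dimensions against the residual degrees of freedom, which `fit_glm` does.
The filter is idempotent, and a scan shorter than the cutoff passes
through unchanged with a warning. Measured at the default session length
(140 volumes, TR 3.264 s): a 240 s sinusoid keeps <1% of its power, a
40 s sinusoid >99%.

### Estimation and inference

First-level estimation is OLS without prewhitening; with AR(1) noise OLS
remains unbiased, and random-effects inference at the second level is
valid because only one summary statistic per subject is carried up.
Sessions are concatenated with shared condition/modulator columns,
per-session nuisance and intercept columns, and per-session filtering.
Voxels with exactly zero residual (or between-subject) variance are
flagged undefined rather than silently zeroed or divided by.

Cluster-extent inference thresholds the group t-map at one-sided
p < 0.001 (the conventional figure threshold), labels clusters by
18-connectivity (6 and 26 are available), and computes each cluster's
familywise-corrected p as the add-one permutation probability that the
maximum cluster size under random sign flips of the subject maps reaches
the observed size, optionally Bonferroni-multiplied across a declared
contrast family. Sign-flipping is exact under symmetric errors. Fewer
than 100 permutations are refused as unstable. The permuted t-maps are
vectorised by noting that sign flips leave Σx² per voxel unchanged, so
only the means need a matrix product.

A caveat that matters for calibration: on *spatially independent* noise,
suprathreshold voxels are nearly all isolated, the max-cluster-size null
collapses onto {0, 1, 2}, and the corrected p-values become so granular
that the realised familywise error is far below nominal. Cluster-extent
inference presumes smooth maps. The null generator used for calibration
(`simulate_null_maps`) therefore smooths subject maps with a Gaussian of
FWHM 3 voxels (~9 mm at 3 mm voxels, the conventional smoothing range),
under which the measured familywise error over 500 null cohorts is 0.042
at nominal 0.05.

Conjunction by masking keeps voxels of the primary contrast at
p < `primary_p` (default 0.001) that also reach p < `mask_p` (default
0.05, uncorrected) in the masking contrast; it applies unchanged at
subject and group level.

## Behavioural and eye summaries

Accuracy is the fraction of reported counts equal to the true count per
grouping level 1–3; RT summaries use correct responses only; empty cells
are flagged missing, never zero. Across-subject paired two-sided t-tests
compare levels; an all-zero difference vector returns p = 1 by
convention. Eye-tracking sessions are kept only if *strictly* more than
80% of samples are valid — a session at exactly 80% is dropped. Gaze
dispersion per stimulus epoch is √((var_x + var_y)/2) over valid samples
(invalid samples are dropped, not interpolated); the temporal support of
the dispersion is the whole epoch by default, with a sliding-window
variant behind a flag since the original windowing is not determinable.
The grouping correlation is the Pearson coefficient between per-epoch
dispersion and the binary grouping indicator; fewer than 3 usable epochs
or a degenerate series (detected by range, not by floating-point standard
deviation) is flagged undefined.

## Pipeline

`run_pipeline` chains stimuli → synthetic BOLD → both GLM variants →
second level → cluster inference on the two slopes → conjunction →
behaviour/eye, each stage seeded by a hash of the root seed and stage
name, and writes a manifest of SHA-256 checksums; identical
configurations reproduce identical manifests (volumes are written as
uncompressed NIfTI-1 to keep bytes stable). Test and demonstration
problem sizes (10³–20³ volumes, 12–54 trials, 100–199 permutations,
50-cohort replications) are chosen so the full suite runs on a single CPU
in minutes while every statistical claim is still measurable.

## Known limitations

* OLS ignores serial correlation at the first level; subject-level t-maps
  are mildly miscalibrated (second-level inference is not).
* The permutation null requires symmetric second-level errors.
* The toy volume has no anatomy; cluster peak coordinates are voxel
  indices, not millimetres.
* The greyscale palette matches the colour palette in lightness
  distribution but not in luminance as displayed on any physical screen;
  no display calibration is modelled.
* The behavioural generator draws responses independently per trial; it
  does not model lapses, bias toward adjacent counts, or learning.
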