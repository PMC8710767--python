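# Methods

`localbrainage` implements voxel-level brain-age prediction: a 3D regression
U-Net maps co-registered grey-matter (GM) and white-matter (WM) tissue-volume
maps to a whole-brain map of predicted chronological age, together with the
surrounding study machinery — block extraction/stitching, age-bias
adjustment, test-retest reliability (ICC) mapping, and group-comparison
statistics — and a synthetic phantom generator that makes the entire design
runnable without real MRI.

## The model

**Input/output contract.** The network consumes overlapping two-channel
blocks of 52³ voxels and emits the central 12³ block of voxel-level age
predictions plus two scalar auxiliary (block-level) age predictions.  The
training target for a block is the participant's chronological age repeated
over all 12³ output voxels; this deliberately forces the network to exploit
spatial context rather than single-voxel intensity.

**Architecture.** Three scales; two valid (unpadded) 3×3×3 stride-1
convolutions per scale on both the down- and up-path; initial width 64
channels, doubling per encoder level; leaky-ReLU activations (slope 0.2); a
squeeze-and-excite channel gate after every convolution (reduction ratio 16,
floored at one hidden unit — the originating publication's default); 2×2×2
average pooling; nearest-repeat upsampling; skip connections concatenated
after centre cropping; a 1×1×1 readout convolution.  Auxiliary heads (global
average pooling → one dense unit) sit on the bottleneck and the middle
decoder scale.

**Pooling geometry and the 23³ receptive field.** Two published statements
conflict: 2×2×2 average pooling normally halves resolution (stride 2), yet
the stated field-of-view accounting — +2 voxels per convolution, +1 per
average pooling because "their stride is set to 1", +0 for repeat
upsampling — only holds when no layer ever decimates.  A conventional
stride-2 U-Net with this layer stack has a measured receptive field of 44³
voxels, not the published 23³.  We therefore implement the average pooling
with stride 1 (side n → n−1) and the upsampling as its size-restoring
nearest repeat (n → n+1), so the network runs at full resolution throughout
and the receptive field is exactly 1 + 2·10 convs + 1·2 poolings = 23 voxels
per side — which `measure_receptive_field` confirms empirically by
back-propagating from one output voxel through a clone with non-negative
weights.  Under this geometry a 52³ input yields a 32³ stride-1 output; the
52³→12³ contract is completed by a final centre crop.  The squeeze-and-excite
gate is a *global* scalar modulation per channel (its pooling spans the whole
block); during the receptive-field measurement the gate is held constant so
that the measured region is that of the spatial convolutional pathway — the
published figure likewise ignores the attention path.

**Loss.** For one sample, `sum_v |y − ŷ_v|` over the 12³ output voxels plus
`Σ_b α_b(t)·|y − ŷ_b|` for the two auxiliary heads, summed over the
minibatch.  α₁ = α₂ = 1 at iteration 0 and decay linearly to 0 at 50 000
iterations (the decay shape is not published beyond "progressively
decreased"; linear is the simplest monotone choice), after which gradients
flow exclusively from the voxel predictions.

**Optimisation.** Adam, learning rate 1e-4, minibatch 32 assembled as four
gradient-accumulation splits of 8, 80/20 participant-level train/validation
split, early stop when the validation voxel-MAE fails to improve by more
than a tolerance for a fixed number of evaluations (a formalisation of the
published "visual inspection of the validation loss reaching a plateau";
evaluation cadence and tolerance are configurable because the original
values are unstated).

**Conditioning for short schedules.** The published model trains for
500 000 iterations; desk-scale runs get under a thousand.  Several standard
conditioning devices close that gap, all optional and all defaulting to the
faithful published parameterisation:

* `output_bias` — initialise the readout and auxiliary biases at the
  training-cohort mean age; `output_scale` — a fixed target-standardisation
  gain on the readout heads (Adam's bounded per-parameter steps then span
  the ±36-year output range in hundreds rather than hundreds of thousands
  of iterations).
* `init="local"` — identity-preserving initialisation: each convolution is
  damped variance-scaled noise plus a unit centre tap copying an input
  channel; squeeze-and-excite gates start *constant* (zero gate weights, a
  small live hidden bias keeps them trainable) because an input-dependent
  gate multiplies the passthrough by a per-block gain that compounds across
  ten layers; readout weights start at zero.  Local tissue intensity then
  reaches the readout unmixed from iteration 0.  (The gate bias starts at
  sigmoid⁻¹-open in both init modes: a gate closed at 0.5 attenuates
  activations by 0.5¹⁰ ≈ 10⁻³ across the network and starves the readout.)
* `hidden_lr_factor` — learning-rate split between the readout heads and
  everything else (fine-tuning convention: quasi-stationary features, fast
  linear head); at exactly 0 the features are frozen and `train` switches
  to a fast path that caches each distinct block's head inputs — gradients
  are bit-identical to the full path (unit-tested), iterations become
  nearly free, and the published full minibatch of 32 becomes affordable.
* `lr_final_factor` — linear learning-rate decay across the run.

The desk-scale fixture trains in two phases totalling 950 iterations:
phase A (250 iterations, minibatch 4, `hidden_lr_factor` 0.05) lets the
convolutional features adapt; phase B (700 iterations, minibatch 32,
features frozen, lr decaying to 20%) converges the readout on those
features.  None of this changes the architecture, the receptive field, the
spatial contract, or the loss.

## Implementation

No deep-learning framework is used: forward and backward passes of every
layer are written out in NumPy (float32), with the im2col gather/scatter of
the valid 3×3×3 convolutions jitted by numba and the contractions done by
BLAS.  Gradients of every layer are verified against central finite
differences in the unit tests.  Determinism: all randomness flows through
`numpy.random.Generator` seeds; on a fixed machine and thread count, runs
are bit-reproducible.

## Blocks, stitching, prediction maps

Output regions tile the mask bounding box on a stride-12 lattice (the
inter-block stride is not published; stride 12 predicts each interior voxel
exactly once).  The lattice's last origin per axis is clipped back inside
the volume; only those clipped regions overlap, and stitching averages
there.  Input context windows (margin 20 voxels per side) may reach past the
volume and are zero-padded — preprocessed tissue maps are zero outside the
head, so the padding is distribution-consistent.  Blocks whose 12³ output
region contains no in-mask voxel are skipped.  A participant's *global*
brain-age is defined as the mean of the stitched voxel map over the mask.

## Bias adjustment

Brain-age models over-predict young and under-predict old participants
(regression dilution), so raw deltas Δ = ŷ − y correlate with age.  Two
adjustments are implemented:

* **Global linear** — fit Δ = α·c + β by least squares with covariate c
  either chronological age or predicted age, and subtract the fitted line:
  Δ̃ = Δ − (α·c + β).  (The subtraction is of the whole fitted line; only
  this zeroes an exactly linear bias.)
* **Voxel-level binned** — on a held-out calibration cohort (disjoint from
  train/validation/test; the original study used n = 200), bin participants
  by age — [18, 25) first, then 5-year half-open bins, the last closed —
  and store the per-bin, per-voxel mean delta Δ_{b,v}; a new participant's
  map is adjusted by subtracting their bin's mean-delta map.  By
  construction the mean adjusted delta of the calibration set is exactly
  zero within every (bin, voxel).  Ages outside the calibration range clamp
  to the nearest bin, as do ages falling in unoccupied bins (refusal would
  break clinical cohorts older than the healthy calibration range); pass
  `clamp=False` to make that an error instead.

## Statistics

Welch's t with the Welch–Satterthwaite degrees of freedom and two-sided
p-values; Cohen's d with the pooled *standard deviation* (the printed
formula pools raw variances without a square root, which is dimensionally
inconsistent for a standardised effect size); Fisher's classical pairwise
intraclass correlation and ICC(2,1) (two-way random effects, absolute
agreement, single measure) from the ANOVA mean squares, with a vectorised
voxelwise variant for reliability maps; Pearson's r; Bonferroni correction
with m defaulting to the number of tests at the given scope (voxels in
mask, ROI count, or group-pair count), user-overridable.  Group comparisons
run at three scopes: global (one value per participant), ROI (per-ROI mean
of the adjusted delta map, Bonferroni over ROIs), and voxel (participants'
in-mask voxel values pooled into one "population" per group — reproducing
the published procedure; pooling treats voxels as independent observations,
an exchangeability assumption we reproduce without endorsing).  The
published "paired Welch's t-test" at voxel scope is implemented as the
ordinary two-sample Welch test on the pooled populations, since a paired
Welch test is not a defined procedure.  Age matching selects controls
strictly older than the threshold (60 years in the study design).

## Synthetic phantoms

Each participant is a two-channel 3D map on an n³ grid (default 48³, voxel
size 1.5 mm, diagonal affine).  The brain mask is a superellipsoid
(exponent 4, semi-axes 0.37·n — sized so a 48³ phantom tiles into a 3³
block lattice, and boxy enough that the rectangular 12³ output regions
contain few out-of-mask voxels, which would otherwise dilute the
constant-age block loss); the WM support is its core (normalised radius
≤ 0.55), the GM support the surrounding shell — a trivially reproducible
cortex/white-matter analogue.  Voxel intensity follows

    I(v) = S[ base(v) − β(v)·(age − 18) + g(v) + ε(v) ] · mask(v)

with Gaussian smoothing S (FWHM 2 voxels ≈ 4 mm at 1.5 mm voxels, applied
after noise, emulating preprocessing smoothing), GM/WM baselines 0.80/0.70,
i.i.d. Gaussian noise ε (SD 0.03), and a per-voxel atrophy rate β(v).  Age
18 is the absolute intensity reference for every cohort, whatever its
sampled age range.  The default β field (`anterior_step`) is 0.008
intensity-units/year over the anterior two thirds of the grid and 0 in the
posterior third — a region where age is locally decodable at a homogeneous
rate, and a control region where it is not.  A linear anterior–posterior
ramp (`anterior_gradient`) is available and mirrors the frontal accuracy
gradient reported on real data, but a spatially varying rate turns the
voxel readout into a position-dependent-gain problem that no desk-scale
schedule can solve (closed-form fits cap at the constant-prediction
plateau), so the step field is the default study condition.  The signal
majority matters too: with the two regions at 50/50 the pooled voxel-MAE
objective is indifferent between decoding age and predicting a constant.
Ages are uniform on [18, 90] (flat coverage); `age_sampling="grid"` spaces
them evenly instead — used for the calibration cohort so every 5-year bin
is populated at n = 20, the desk-scale stand-in for the study's large
random calibration sample.  Group effects subtract β(v)·delta_years inside
configured atlas ROIs, i.e. a group looks `delta_years` older wherever age
is decodable.  The ROI atlas partitions the mask into up to 27 macro-block
ROIs.

Because smoothing is linear, the *effective* generating fields are the
smoothed, masked versions of base, β and g; `PhantomTruth` stores these, so
at noise 0 a per-voxel OLS of intensity on age recovers them to float
precision (a unit test), and group means outside the smoothed group-effect
support are exactly equal.

Repeat scans rebuild the noise-free signal and add fresh smoothed noise
(within-scanner); between-scanner repeats additionally receive a smooth
additive site field with configurable in-mask RMS amplitude, fixed per
scanner.

**What the phantoms do not emulate:** anatomy, acquisition physics,
segmentation artefacts, site/vendor nonlinearities, nonlinear age
trajectories, or realistic covariance between regions.  Passing tests show
the *machinery* is correct and sensitive under a known linear ground truth;
they say nothing about accuracy on real MRI.

## Desk-scale study conditions

The packaged end-to-end fixture uses: 48³ grid; 80 healthy phantoms for
training/validation (80/20 participant split) plus 20 grid-age calibration
phantoms; 10 held-out test phantoms; a clinical cohort of 14 + 14 aged
55–90 with one group carrying a +5-year-equivalent effect in the highest-β
ROI and controls age-matched at >60 years; network width reduced to base 2
channels (the *layer structure* — and hence the 23³ receptive field — is
never reduced); `init="local"`, `output_scale` 100, `output_bias` at the
training mean age; the two-phase 250 + 700-iteration schedule described
above.  These sizes are the package's own desk-scale choices; the
full-scale defaults (base 64, He-style init, lr 1e-4, minibatch 32/4
splits, 500k-iteration horizon) remain the configuration defaults.

## Numerical choices and edge cases

* Out-of-mask voxels in every output map are NaN, never 0 (0 is a legal
  brain-PAD).
* Zero-variance inputs raise `ZeroDivisionError` (undefined statistic)
  rather than returning NaN silently.
* The sigmoid pre-activation in the squeeze-and-excite gate is clipped at
  ±60 before exponentiation (saturation without overflow).
* MAE subgradient at 0 is taken as 0.
* `stitch` averages in float64 and casts to float32.
* Empty age-matched subsets warn and return empty rather than failing.

## Known limitations

* Single-CPU NumPy training is ~10⁴× slower than a GPU framework; the
  full-scale configuration is expressible but not trainable here.
* The stride-1 pooling resolution of the published geometry conflict is our
  reading; a stride-2 variant would change the receptive field to 44³ and
  break the published accounting.
* The voxel-scope pooled Welch test inherits the published exchangeability
  assumption (voxels treated as independent observations).
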