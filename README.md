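# localbrainage

Voxel-level ("local") brain-age prediction from structural MRI tissue maps.

Conventional brain-age models output a single predicted age per scan, so an
older-appearing brain cannot be localised.  This package implements a
framework that predicts chronological age at (near-)voxel resolution: a 3D
regression U-Net consumes co-registered grey-matter (GM) and white-matter
(WM) volume maps (NIfTI, MNI-space, e.g. SPM12/DARTEL output) in
overlapping 52³ blocks and emits 12³ blocks of voxelwise brain-age, which
are stitched into a whole-brain map.  Downstream, the package provides the
full study machinery: per-voxel age-bias ("regression dilution")
adjustment, test-retest reliability maps (ICC[2,1]), and group comparisons
(Welch's t, Cohen's d, Bonferroni) at voxel, ROI and global scope.  A
synthetic-phantom generator with a known, spatially varying atrophy rate
makes the entire design runnable and testable end to end without real MRI.

It is intended for methods researchers working on brain-age and voxelwise
normative modelling who want a transparent, fully inspectable reference
implementation — every layer's forward and backward pass is plain
NumPy/numba, with no deep-learning framework behind it.

## The model in brief

For participant *i* with chronological age *y_i*, each 52³ input block is
trained against a constant target block filled with *y_i*; the loss is

    L = Σ_i Σ_{v ∈ 12³} |y_i − ŷ_{i,v}|  +  Σ_{b=1,2} α_b(t) · Σ_i |y_i − ŷ_{i,b}|

where ŷ_{i,b} are two auxiliary block-level age readouts whose weights
α_b decay linearly to zero at 50 000 iterations.  The network uses valid
3×3×3 stride-1 convolutions (two per scale, three scales, 64 base channels
doubling per level), leaky-ReLU (0.2), squeeze-and-excite channel gates,
2×2×2 average pooling and nearest-repeat upsampling; the effective
receptive field of one output voxel is exactly 23³ voxels (measured
empirically by `measure_receptive_field`), so "voxel-level" predictions
have ~23³ true resolution.  The voxelwise brain-age delta
Δ_{j,v} = ŷ_{j,v} − y_j is de-biased by subtracting the per-voxel mean
delta Δ_{b,v} of the participant's chronological-age bin, estimated on a
held-out calibration cohort (Δ̃_{j,v} = Δ_{j,v} − Δ_{b,v}).

## Worked example

Train on a synthetic cohort and inspect one participant's local brain-age:

```python
import numpy as np
import localbrainage as lba
from localbrainage import phantom, training

# 1. a cohort of 40 two-channel phantoms, ages uniform on [18, 90], with a
#    known anterior atrophy-rate field and a posterior control region
cfg = phantom.PhantomConfig(grid_side=48, n_participants=40, seed=0)
volumes, records, truth = phantom.generate_cohort(cfg)

# 2. 80/20 split, desk-scale network (thin channels, full layer structure)
train_ids, val_ids = training.split_cohort(records, 0.8, seed=0)
idx = {r.id: i for i, r in enumerate(records)}
sampler = training.CohortBlockSampler(
    [volumes[idx[i]] for i in train_ids],
    [records[idx[i]] for i in train_ids], truth.mask)
ages_tr = [records[idx[i]].age_years for i in train_ids]
net = lba.build_network(lba.ArchitectureSpec(base_channels=2), seed=0,
                        output_bias=float(np.mean(ages_tr)),
                        output_scale=100.0, init="local")
# two-phase desk-scale schedule: brief feature adaptation, then a long,
# cheap readout polish on frozen features
feature_phase = training.TrainConfig(learning_rate=0.01, hidden_lr_factor=0.05,
                                     max_iterations=100, minibatch=4,
                                     grad_splits=4, seed=0)
net, _ = training.train(net, sampler, feature_phase)
readout_phase = training.TrainConfig(learning_rate=0.01, hidden_lr_factor=0.0,
                                     lr_final_factor=0.2, max_iterations=700,
                                     minibatch=32, grad_splits=4, seed=1)
net, history = training.train(net, sampler, readout_phase)

# 3. a whole-brain prediction map for one held-out phantom
test_cfg = phantom.PhantomConfig(grid_side=48, n_participants=1, seed=99)
(test_vol,), (test_rec,), _ = phantom.generate_cohort(test_cfg)
pred = training.predict_map(net, test_vol, truth.mask)
print(f"chronological age {test_rec.age_years:.1f}")
print(f"global brain-age  {np.nanmean(pred):.1f}")
```

which prints (seeds fixed):

```
chronological age 54.4
global brain-age  49.1
```

The map `pred` holds one predicted age per in-mask voxel (NaN outside the
mask); `np.nanmean(pred)` is the participant's global brain-age, and
`np.nanmean(pred) - test_rec.age_years` their global brain-PAD — here the
phantom appears about five years younger than it is, the under-prediction
of a desk-scale model whose age-bias the binned calibration of
`localbrainage.bias` is designed to remove.
`localbrainage.stats.roi_aggregate` turns the same map into per-ROI
brain-PAD values.

The four-stage study pipeline (train → held-out accuracy → reliability →
de-biased group comparison) runs from one config:

```bash
localbrainage run --config study.yaml --out results/
```

writing maps, CSV comparison tables, checkpoints, a JSON manifest and
JSON-lines logs under `results/`.

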