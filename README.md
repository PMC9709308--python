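# binloc — binaural sound source localization via contrastive embeddings

`binloc` estimates the direction (azimuth and elevation) of a single sound
source from two-channel "ear" signals, the way computational auditory
models and hearing-aid / robot-audition front-ends do.  Instead of mapping
binaural cues straight to angles, it learns a low-dimensional **embedding**
of the cues in which Euclidean distance reflects how close two source
directions are; localization then reduces to nearest-neighbor regression in
that space.  This makes the system robust to reverberation and to small
training sets, and the 3-D embeddings are directly visualisable as a
manifold of source directions.

## The model

**Features.**  From the STFT coefficients S1(t, k), S2(t, k) of the
left/right channels, per-bin interaural level and phase differences

    alpha_tk = 20 log10 |S1(t,k)| / |S2(t,k)|           [dB]
    phi_tk   = angle( S1(t,k) conj(S2(t,k)) )           [rad]

are averaged over frames (a_k = mean_t alpha_tk, p_k = mean_t e^{j phi_tk})
and concatenated over analysis bands into a measurement vector
x in R^D.  At 16 kHz with a 1024-point DFT and bands 200–7000 Hz (ILD) /
200–2500 Hz (IPD), D = 729.

**Embedding.**  A siamese network f_W : R^D -> R^3 (two sigmoid hidden
layers of width D with batch-norm and dropout, linear 3-unit output) is
trained on all C(n,2) pairs of every mini-batch with the adaptive-margin
contrastive loss

    L = sum_{i<j} [ y_ij ||z_i - z_j||^2
                  + (1 - y_ij) max(0, mu_ij - ||z_i - z_j||)^2 ],

where z = f_W(x), the indicator y_ij marks pairs whose sources are within a
threshold (angle eps_u in the supervised variant SCE, physical distance
eps_s ≈ eps_u · Phi · pi/180 on a radius-Phi sphere in the weakly
supervised variant WSCE), and the pair-specific margin
mu_ij = e^{d_ij} / (e^{d_ij} + 1) grows with latent distance.

**Localization.**  A query embedding z is regressed against its K = 5
nearest training embeddings with exponential weights
w_i ∝ exp(-||z - z_i||^2 / eps), eps the median squared neighbor distance;
the estimate is the weighted mean of the neighbors' labels.

**Baselines.**  Laplacian eigenmaps (spectral embedding of the
M-nearest-neighbor affinity graph via the top non-trivial eigenvectors of
P = D^-1 K, with a kernel-barycentre out-of-sample extension) and a
feed-forward regressor (same trunk, tanh output scaled by 180°, MSE loss).

**Synthetic scenes.**  A built-in cue-domain simulator generates labeled
measurement vectors on an azimuth × elevation grid from a spherical-head
model (Woodworth interaural delay, frequency-dependent level differences,
an elevation-dependent spectral notch standing in for pinna filtering),
with seeded additive noise and frame-correlated reverberant perturbation —
so every component is testable without external recordings.

## Worked example

Train a supervised contrastive embedding (eps_u = 5°) on a reverberant
synthetic grid (37 azimuths × 19 elevations, 15 dB SNR, reverberation
strength 0.5) and localize a freshly drawn test condition:

```python
import numpy as np
from binloc import (ContrastiveEmbedding, NetworkSpec, TrainConfig,
                    ThresholdConfig, SceneConfig, generate_dataset, evaluate)

scene = SceneConfig(snr_db=15.0, reverb_strength=0.5)
ds = generate_dataset(scene)

model = ContrastiveEmbedding(
    ds.train_features, ds.train_labels["azimuth_deg"].to_numpy(),
    network=NetworkSpec(input_dim=ds.train_features.shape[1]),
    thresholds=ThresholdConfig(angle_threshold_deg=5.0),
    val_features=ds.val_features,
    val_labels=ds.val_labels["azimuth_deg"].to_numpy())
res = model.fit(TrainConfig(max_epochs=100, seed=1))
print(res.summary())

report = evaluate(res.localize(ds.test_features).ravel(),
                  ds.test_labels["azimuth_deg"].to_numpy())
print("test-set azimuth error:", report.to_dict())
```

Output:

```
Contrastive Embedding Results
==================================
mode:              supervised
n train / val:     492 / 211
architecture:      90 -> 90 -> 90 -> 3
dropout / bnorm:   0.2 / True
parameters:        17013
epochs run:        100
final train loss:  2149.24
best val error:    2.565 deg
eps_u (deg):       5.0
seed:              1

test-set azimuth error: {'median': 2.799, 'q1': 1.328, 'q3': 5.000,
                         'max': 19.052, 'n': 703}
```

The median test error of ~2.8° under unseen reverberation — against a
5°-spaced training grid — is the headline behavior: embedding-space
neighbors share source directions even when raw-cue neighbors no longer
do.  On clean data the same pipeline reaches essentially zero median error.

The same `ds` also drives the baselines (`LaplacianEigenmaps`,
`FeedForwardLocalizer`) and the study recipes in `binloc.workbench`
(`dropout_sweep`, `method_comparison`, `reduced_training`, `wsce_sweep`).
A `binloc` command-line tool exposes feature extraction, simulation,
training, localization and the experiment recipes (`binloc --help`).

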