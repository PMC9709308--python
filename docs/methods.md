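# Methods

This note documents the models, the synthetic data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Binaural features

A stereo recording is framed without padding (frame count
T = 1 + floor((N − K)/hop), hop = K·(1 − overlap)) and windowed with a sine
("cosine") window w[n] = sin(pi (n + 0.5)/N); Hann and rectangular windows
are available.  Per-bin cues are the level ratio in dB and the phase
*difference* angle(S1 · conj(S2)) — an interaural phase difference must be
a difference of the two channels' phases, so the product-without-conjugate
reading of the defining expression is treated as a typo.  A magnitude floor
of 1e-12 inside the ILD logarithm keeps silent bins finite; all frames are
averaged with no voice-activity gating.

Band edges map to DFT bins by k_i = round(f_i · K / f_s) (ties away from
zero; the operative values are far from ties).  The ILD block covers bins
[k1, k2) and the IPD block [k3, k4), interleaving the real and imaginary
parts of the mean unit phasor, giving D = (k2 − k1) + 2(k4 − k3).  The
half-open convention is forced by the dimension formula itself: at 16 kHz,
K = 1024, bands 200–7000 / 200–2500 Hz, the bins are (13, 448, 13, 160) and
D = 435 + 294 = 729, which an inclusive reading cannot reproduce.  Bin
indices are 0-based everywhere.

## Pair labels and margins

Supervised similarity compares one angle (azimuth or elevation) per task
with the wrap-aware distance d_u = min(|Δ|, 360 − |Δ|) and threshold eps_u
(boundary inclusive).  Weak similarity compares Cartesian source positions
on a radius-Phi sphere with threshold eps_s ≈ eps_u · Phi · pi/180 (arc
length of eps_u); a grouping-key fallback marks same-key recordings similar
with the constant margin when no positions are available.  The adaptive
margin mu = 1/(1 + e^{−d}) is evaluated in the numerically stable logistic
form and uses the raw latent units (degrees or meters) — no rescaling is
applied, matching the defining formula; with degree inputs the margin
saturates near 1 beyond a few degrees, which we document rather than
renormalize.  An optional `margin_scale` factor is exposed for users who
want a softer profile.  Pairs are the C(n,2) unordered distinct pairs of a
mini-batch (8,128 for the default batch of 128).

## Embedding network and training

One siamese branch is linear → batch-norm → sigmoid → dropout (twice, width
D) followed by a linear 3-unit output; the pairwise loss is evaluated on a
single forward pass of the batch, so weight sharing between "branches" is
structural.  Initialisation is fan-balanced uniform; one seeded generator
drives initialisation, epoch shuffling and dropout masks, making training
bit-reproducible.  Optimisation is Adam at 1e-3 with the learning rate
halved after 20 epochs without validation improvement; training stops after
3 consecutive halvings without improvement or at `max_epochs` (default 500;
the desk-scale experiments use 100–200, which the loss curves show is past
convergence at these problem sizes).  The "validation performance" driving
both scheduling and best-checkpoint selection is the median validation
localization error in degrees, obtained by embedding train and validation
sets and running the kernel kNN regressor — the quantity the studies
actually report.  A run in which no mini-batch ever contained a similar
pair is flagged as degenerate in the results.

Loss reduction is a sum over pairs by default (mean available for
learning-rate comparability).  Gradients, including the batch-norm
through-statistics terms, are analytic and tested against central finite
differences; parameters whose true gradient is exactly zero (hidden biases
under batch-norm, the output bias, which cancels in pairwise differences)
are covered by an absolute floor in the check.

## Baselines

*Laplacian eigenmaps*: affinity by the symmetric OR-rule M-NN graph
(M = 10 default, zero diagonal, ties broken by lowest index after sorting
by distance then index) or a Gaussian kernel.  The embedding solves the
symmetric eigenproblem of D^{−1/2} K D^{−1/2} and maps eigenvectors back by
D^{−1/2} — numerically stabler than, and spectrally identical to,
P = D^{−1} K.  Coordinates are eigenvectors 2..d+1 by descending
eigenvalue; the constant top eigenvector is excluded, and a disconnected
graph raises an error naming the component count.  Out-of-sample points are
extended by a kernel-weighted barycentre of training coordinates (weights
renormalised to sum to one); the spectral literature's 1/lambda correction
is available behind a flag but off by default, keeping the simplest
defensible reading of "linear combination of the training points".
Test points are never folded back into the training graph by default.

*Feed-forward*: the full branch (including the 3-unit linear layer) plus a
tanh head per task, trained with MSE on labels normalised by 180°;
predictions are scaled back to degrees.  One scalar head per task mirrors
the unidimensional treatment of the supervised embedding.

## Localizer

K = 5 neighbors, exponential weights with the bandwidth set to the median
squared neighbor distance (even K uses the mean-of-middle-two median).  If
all K neighbors coincide with the query the weights fall back to uniform.
Inverse-square and uniform weightings are implemented but non-default —
inverse-square weights are known to localise less accurately.  Angles are
averaged arithmetically: with frontal sources (|azimuth| ≤ 90°) wrap-around
cannot occur among true neighbors; a circular-mean option exists for
full-range labels.  Errors are reported wrap-aware (median, quartiles,
maximum).

## Synthetic generator (version `binloc-synth-1`)

The generator is a *cue-domain* simulator, not a room-acoustics engine:
it emulates the statistical structure real binaural datasets give the
learning problem (a direction grid, several noisy/reverberant draws per
direction, distinct train and test conditions) at a cost of seconds.

Clean templates: interaural delay from the spherical-head (Woodworth) form
ITD = (r/c)(sin θ + θ) with r = 8.75 cm, c = 343 m/s; per-bin IPD =
2π f ITD wrapped to (−π, π]; ILD = sin(azimuth) · g · f[kHz] with
g = 3 dB/kHz (≈ ±21 dB at 7 kHz, the magnitude real heads reach), minus an
elevation cue: a Gaussian spectral notch (depth 12 dB, width 300 Hz) whose
center moves affinely with elevation (5200 + 22·elevation Hz, spanning
≈ 4.2–6.8 kHz).  The notch stands in for the pinna filtering that makes
elevation identifiable in real head-related transfer functions; its range
keeps the center ≥ 2 sigma inside the 7 kHz ILD band edge at every
elevation so the in-band notch energy — and hence the template geometry —
does not degenerate at extreme elevations.  Because the notch is additive
and even in azimuth, exact ILD negation under azimuth mirroring holds for
the azimuth-dependent component; the property tests assert exactly that
(and full IPD negation).

Corruption: each channel's clean complex gain g is perturbed per frame and
bin as g(1 + r·h_t) + σ n_t, where h is a unit-variance complex AR(1)
process over frames (correlation 0.9) emulating reverberant channel
fluctuation with strength r ∈ [0, 1], and n is white complex sensor noise
with σ set by the SNR in dB.  Cues are then extracted and averaged through
the same code path as real recordings.  r = 0 with infinite SNR reproduces
the template exactly.  Default scene conditions are 15 dB SNR, r = 0.3, 20
frames — a lightly reverberant room; the study recipes set r per
experiment (0 for the clean recovery study, 0.5 for the robustness study).

Splits: train/validation are a 70/30 random partition of one condition
draw; the test set is the full grid redrawn under `condition_seed + 1` —
new noise and reverberation realisations, emulating evaluation in unseen
rooms.  All draws are bit-reproducible functions of the scene config.

Desk scale: the default analysis for synthetic work uses K = 128 (D = 90,
hidden width 90), the full 37 × 19 5°-grid (703 directions), and 100–200
epochs, chosen so every recipe runs in seconds-to-minutes on one CPU while
preserving the qualitative contrasts of interest.  A waveform renderer
(`render_waveform`) produces stereo WAV files consistent with the
templates for exercising the external-audio pipeline, and externally
rendered BRIR-convolved WAVs can be fed through the same `extract` path.

What the generator does *not* model: measured HRTFs and their
individuality, true room impulse responses (early reflections, coloration),
source spectra other than broadband noise, multiple or moving sources.
Passing tests therefore demonstrate the correctness and the *relative*
behavior of the methods under controlled distortion — not absolute error
levels on real recordings.

## Experiment recipes and dropout at desk scale

The workbench recipes mirror the study designs: a dropout sweep
{0.0, 0.2, 0.5, 0.8}, a three-method comparison, a reduced-training sweep
{10, 25, 50, 70}%, and a weak-supervision threshold sweep
eps_u ∈ {5°, 15°, 30°} (eps_s ∈ {0.09, 0.26, 0.52} m on the unit sphere).
Each cell derives its own seed from the experiment seed and cell label, so
reports are pure functions of (config, seed) and serialise to JSON/TSV.

Dropout interacts with width: 0.2 is the right regularisation for the
contrastive embedding at any width we tested, but the direct feed-forward
regressor at the desk-scale width of 90 units is over-regularised by it
(it stalls at ~8–10° median) while converging cleanly without dropout.
The robustness experiments therefore run the embedding at dropout 0.2 and
the feed-forward baseline at its validation-optimal 0.0 — the same
tune-on-validation-then-compare protocol the dropout sweep implements —
so the comparison reflects each method at its best, not an artifact of a
fixed regulariser.

## Known limitations

- The margin saturates near 1 for latent distances beyond a few degrees,
  so for supervised training with degree labels the adaptive margin mostly
  differs from a constant margin near the similarity threshold.
- The Nyström-style extension for Laplacian eigenmaps is a first-order
  approximation; its error grows for queries far from the training
  manifold (this is the known weakness of spectral embeddings that the
  parametric embedding addresses).
- Arithmetic angle averaging in the localizer assumes frontal sources;
  enable the circular mean for full-circle azimuth labels.
- Batch statistics make the training loss depend on batch composition;
  inference always uses running statistics and is deterministic.
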