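# Methods

This note documents the models, numerical choices and study conditions
implemented in `tomoshot`: a one-shot Siamese 3D network that simultaneously
matches a target cryo-ET subtomogram against a support set of single-example
classes and produces a voxel-level segmentation, refined by a fully connected
3D CRF; plus the tilt-series simulator used to generate labeled data.

## The one-shot matching and segmentation model

Two weight-shared streams process the support subtomograms X_S and the
target X_T. A shared **volume encoder** P_VE (three levels of two 3x3x3
convolutions + ReLU, each level followed by a dual squeeze-and-excitation
block and, at the first two levels, 2x max-pooling) maps a 32^3 cube to a
latent representation F_1. From F_1:

* the **volume decoder** P_VD (mirrored levels with trilinear upsampling and
  a final 1x1x1 convolution + sigmoid) emits a per-voxel foreground
  probability map M in [0,1]^{32^3}; optionally each decoder level
  concatenates the encoder's pre-pooling feature map at the matching
  resolution (`decoder_skips`), letting the decoder act as a learned
  full-resolution filter of the input rather than a pure generator from the
  latent code;
* the **feature encoder** P_FE flattens the latent, projects it to 512
  dimensions (adapter), applies ReLU and a 512x512 fully connected layer,
  giving the embedding F_2 in R^512.

Matching scores the elementwise L1 distance F_dis = |F_S2 - F_T2| through a
single 512-to-1 fully connected head P_final. During training the head's
sigmoid output is a per-pair match probability trained with binary
cross-entropy against the n^2 pairwise class-match labels; at inference the
n per-class logits are passed through a softmax and the predicted class is
the argmax (ties broken toward the lowest class index). Both modes share
P_final's weights, which reconciles the pairwise binary labels used by the
loss with the softmax-over-support readout used by the n-way protocol.

**DuSE block.** The channel branch squeezes each channel to its spatial mean
v_z, gates channels with sigmoid(w2 relu(w1 v)) (bottleneck C -> C/2 -> C,
bias-free); the spatial branch squeezes channels with a 1x1x1 convolution to
one map m and gates voxels with sigmoid(m). The two recalibrated maps are
summed elementwise. Both branches are verified against scalar triple-loop
oracles in the test suite.

**Losses.** L_tot = L_dsc + L_bce with unit weights. L_bce is averaged over
the n^2 pairs of an episode so the 1:1 balance is independent of n. L_dsc is
the two-support-set soft Dice loss 2 - DSC(M_S1, M_gt1) - DSC(M_S2, M_gt2)
with product intersection, sum cardinality and epsilon = 1e-6 smoothing
(set notation in the objective is made differentiable this way; an empty
ground truth with an empty prediction counts as perfect). Internally the BCE
is evaluated in logit space (log-sigmoid), which is algebraically identical
to clipping at probabilities but keeps gradients alive when the head
saturates; the probability-space form with clipping at 1e-7 is exposed as
`bce_loss` and used for closed-form checks.

**Training strategy.** Episodes mirror inference: two support sets over the
same randomly drawn n classes, one record per class (distinct records when a
class has at least two), binary labels by class match. At test time one
support set is replaced by the target; test classes are never seen in
training, so segmentation of unseen classes never uses their labels.

**Numerical stabilization.** Several choices matter on small runs and are
on by default: (a) group normalization after every convolution — batch-size
independent, so training and inference behave identically on batches of a
handful of volumes; (b) the decoder's output bias starts at -2.0, i.e. a
foreground prior of ~12%, which prevents the class-imbalanced Dice gradient
from saturating the sigmoid output early; (c) a global gradient-norm
ceiling of 5.0 per update; (d) Adam (lr 1e-3), with an optional separate
learning-rate scale for the decoder (`decoder_lr_scale`) — the segmentation
head converges more slowly than the matching head at small episode budgets,
and scaling its rate balances the two without touching the 1:1 loss
weights. The optimizer and rates are free parameters of the method and
fully configurable.

**Augmentation and rotation averaging.** Subtomogram classes appear in
uniformly random orientations and the method performs no alignment, so
rotation robustness must come from the data. Training applies a random cube
symmetry (one of the 24 proper 90-degree rotations) to each record per
episode. Evaluation averages each record's embedding over all 24 cube
rotations before computing distances; this is a deterministic, label-free
test-time choice that reduces the orientation variance of the embedding.

## Architecture defaults and their rationale

| Parameter | Default | Why |
| --- | --- | --- |
| channels | 32/64/128 (full scale) | smallest standard three-level design |
| duse_reduction | 2 | the bottleneck shapes C/2 x C and C x C/2 |
| embedding_dim | 512 | the 512x512 feature-encoder layer |
| n_pools | 3 (full scale) | 32^3 -> 4^3 latent |
| pre_embedding | flatten | preserves spatial structure for transfer |
| head | 512 -> 1 linear | pairwise sigmoid / softmax-over-support |

The desk-scale benchmark (below) uses channels 4/8/32, n_pools = 2 (latent
8^3 x 32) and decoder skips: at small training budgets the 4^3 latent with
global average pooling discards too much spatial structure for the decoder
to reconstruct masks and for embeddings to transfer to unseen classes;
shallower pooling, a wide deepest level (whose convolutions run at 8^3 and
cost almost nothing) and skip connections raise both. The
global-average-pool pre-embedding and the skip-free decoder remain
available (`pre_embedding="gap"`, `decoder_skips=False`).

## The simulator

The pipeline mimics tomographic acquisition: pack randomly posed structures
into an empty volume (bounding-sphere rejection sampling, balanced classes,
at most 1000 retries per particle), project a single-axis tilt series,
convolve with the optical transfer function, add Gaussian noise to a target
SNR, reconstruct by weighted back-projection, and crop subtomograms with
identically posed ground-truth masks.

* **Projection operator.** Each voxel is splatted onto the detector with
  linear weights (the detector coordinate is the rotated in-plane
  coordinate), implemented as an explicit sparse matrix per angle.
  Unfiltered back-projection is the exact matrix transpose, so the
  projector/backprojector pair satisfies the adjoint identity to machine
  precision — useful both for testing and for any iterative extension.
* **WBP.** Ram-Lak (|f|) filtering along the detector axis with 2x
  zero-padding, then transpose back-projection scaled by pi/(2 N_angles).
* **CTF/MTF.** CTF(f) = -(sqrt(1-A^2) sin(gamma) + A cos(gamma)) with
  gamma(f) = pi lambda Dz f^2 - (pi/2) Cs lambda^3 f^4 and the relativistic
  electron wavelength; the MTF is a Gaussian envelope exp(-f^2/(2 f_c^2))
  with f_c a fraction of Nyquist. Defaults: 300 kV, defocus -5 um, Cs
  2.0 mm, amplitude contrast 0.07, MTF cutoff 0.4 Nyquist — all
  configurable; they are canonical cryo-ET values, since the acquisition
  parameters of any given study vary.
* **SNR.** Defined as var(signal)/var(noise) on the projection stack; noise
  is added in projection space, before reconstruction. SNR = infinity means
  no noise. The standard study conditions use SNR in {inf, 1000, 0.5}.
* **Tilt scheme.** Default +/-60 degrees in 2-degree steps — the canonical
  missing-wedge condition; range and step are configuration parameters.
* **Ground-truth masks.** Full-scale simulated datasets derive ground truth
  from the known source structures, but there is no canonical recipe for
  turning a known structure into a voxel mask; the package thresholds the
  noiseless posed source density at a configurable fraction of its maximum
  (default 0: the support).

**What the simulator does not model:** dose-dependent or detector-physics
noise, tilt-series misalignment, stage drift, iterative reconstruction
(SIRT/ART), or macromolecular crowding beyond non-overlap of bounding
spheres. Passing tests on these synthetic volumes therefore demonstrates
correctness of the pipeline and learnability under idealized conditions,
not performance on experimental tomograms.

## CRF refinement

The decoder's probability map defines unary potentials -log P(x_i) (clipped
at 1e-8). The pairwise Potts term couples every ordered voxel pair with an
appearance kernel exp(-|p_i-p_j|^2/(2 sigma_alpha^2) - (I_i-I_j)^2 /
(2 sigma_beta^2)) weighted w1 and a smoothness kernel
exp(-|p_i-p_j|^2/(2 sigma_gamma^2)) weighted w2; intensities are the
reconstructed subtomogram normalized to zero mean and unit variance.
Mean-field inference runs 5 iterations by default; messages are computed
over truncated neighborhoods (2.5 sigma; the smoothness kernel via a
separable Gaussian filter rescaled to the unnormalized kernel, the
appearance kernel via explicit offset sums), and a dense all-pairs path is
retained for small volumes and serves as the test oracle. The final mask is
the argmax of the converged marginals.

The five kernel parameters are described as learnable in the objective but
no training procedure for them is specified; the package treats them as
hyperparameters (defaults w1 = w2 = 1, sigma_alpha = sigma_gamma = 1.5
voxels, sigma_beta = 0.5 normalized intensity units) and provides a small
validation-split grid search (`select_crf_params`).

## The desk-scale benchmark

`tomoshot.benchmark` pins the problem sizes used by the package's own
regression checks and by `scripts/acceptance.py`: a 150x150x100 tomogram
with 150 requested particles over 6 geometric phantom classes (sphere,
shell, dumbbell, torus, L-shape, plate), SNR infinity, a fixed
class-disjoint split (torus and L-shape are always the held-out classes,
as in a fixed full-scale train/test split — the seed drives poses, packing
and training randomness, not which classes are unseen), 2-way-1-shot
training for 24 epochs of 8 episodes,
and evaluation over several hundred episodes with rotation-averaged
embeddings. These sizes are the package's chosen reference conditions for a
single-CPU run; the full-scale conditions (600x600x300, 10,000 particles,
22 PDB-derived classes, thousands of episodes) remain expressible through
the same configuration objects.

Desk-scale results are *not* expected to reproduce full-scale accuracy
tables: with only four training classes the learned metric generalizes to
unseen classes far less reliably than with fourteen, and run-to-run
variance is large. The benchmark asserts the qualitative properties —
learning occurs, segmentation transfers, the decoder does not hurt
matching — and reports the measured numbers as-is.

## Known limitations

* No subtomogram alignment; orientation robustness comes only from
  augmentation and rotation-averaged embeddings.
* K = 1 only; no few-shot (K > 1) extension.
* Binary foreground/background segmentation only.
* The dense-CRF message passing is truncated-neighborhood, not
  permutohedral-lattice; very large sigma values are correspondingly
  expensive.
* Geometric phantoms, not rasterized PDB structures, are the default test
  fixture; `rasterize_structure` accepts real atomic models via gemmi when
  coordinate files are supplied by the user.
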