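# Methods

## Problem setting

Percent global glomerulosclerosis — the fraction of glomeruli that are
fully scarred — is a key criterion when pathologists evaluate donor
kidneys. Training a segmentation network to find and classify glomeruli on
whole-slide images (WSIs) is hampered by class imbalance: public kidney
WSIs contain far fewer sclerosed than normal glomeruli. `glomopaint`
addresses the imbalance with inpainting-based augmentation: new sclerosed
glomeruli are synthesised *into real tissue* so that the surrounding
context stays genuine, and only the glomerulus itself is generated.

The pipeline has five stages:

1. **Slide preparation** — slides are downsampled 2x, outlines are burned
   into per-class binary masks, tiles of 1024x1024 are cut with stride 512
   (the final window of each row/column is shifted flush to the image edge
   rather than padded, so duplicated coverage is preferred over synthetic
   borders), and every sclerosed glomerulus is exported as a 256x256 crop
   centred on the minimum enclosing circle of its outline.
2. **Inpainting network** — a mask-conditioned GAN fills mask-shaped holes.
3. **Mask synthesis** — a DCGAN proposes novel glomerulus-shaped masks.
4. **ROI synthesis** — masks and the trained inpainter paint new sclerosed
   glomeruli at tissue positions of a region of interest, and the
   annotations are updated with traced outlines.
5. **Segmentation** — an encoder–decoder network is trained on the mix of
   real and synthetic tiles.

## Inpainting model

The generator input is the 4-channel stack of the gap image
`X_gap = X_ori ⊙ (1 − X_mask)` (RGB, scaled to [−1, 1]) and the binary
mask. The encoder is a 7x7 convolution followed by two 4x4 stride-2
convolutions (batch norm + LeakyReLU 0.2 throughout); eight AOT blocks mix
context at dilation rates {1, 2, 4, 8}; a self-attention block sits where a
256x256 input has 64x64 features; the decoder mirrors the encoder with two
transposed convolutions, concatenative skip connections from the two
matching encoder stages, and a tanh output.

An AOT block splits its channels into four groups, transforms each with a
dilated 3x3 convolution, merges by concatenation plus a 3x3 fusion
convolution (the residual feature `x2`), and gates against the input `x1`
with a spatially varying `β = sigmoid(conv(x1))`:
`out = β⊙x1 + (1−β)⊙x2`. Which of `x1`/`x2` receives `β` is an open
choice; the orientation above is the default and a `gate_flip` flag
provides the ablation.

Self-attention follows the zero-init residual-gain convention: query/key/
value are 1x1 convolutions, attention rows are softmax-normalised, and the
output is `x + γ·attended` with `γ` initialised to 0, so the block is an
exact identity at initialisation.

Two PatchGAN discriminators share one architecture: six 4x4 stride-2
convolutions (channels 64, 128, 256, 512, 512, 1) map a 256x256 image to a
4x4 grid of patch scores. The printed channel list (64…512, 1) names five
widths for six layers; the fifth layer repeats 512. Batch norm is omitted
on the first and last layers (standard PatchGAN practice); a
`batchnorm_first_last` switch restores the literal conv+LReLU+BN ordering
everywhere. The *global* discriminator sees whole images; the *local* one
sees the glomerulus on a white canvas, `R = X ⊙ X_mask + (1 − X_mask)`.

## Losses

The generator objective is

```
L_total = λ_adv (L_advg + L_advl) + λ_1g L_1g + λ_1l L_1l
          + λ_per L_per + λ_sty L_sty
```

with weights λ_adv = 0.02, λ_1g = λ_1l = 1, λ_per = 0.1, λ_sty = 150. The
adversarial terms follow the least-squares GAN convention: each
discriminator minimises `E[D(fake)²] + E[(1 − D(real))²]` (expectation over
patches and batch) and the generator minimises `E[(1 − D(fake))²]` for
each of the two discriminators. L_1g/L_1l are mean absolute errors on the
full image and on the white-canvas local regions. Perceptual and style
distances use a frozen feature extractor φ: L_per sums
`‖φ_i(a) − φ_i(b)‖₁ / N_i` over layers (N_i = activation element count);
L_sty averages the L1 distance of raw Gram matrices `φᵀφ`, normalised by
N_i. φ is injected: the package ships an identity test double and a frozen
random-weight convolutional stack (`RandomConvFeatures`); random conv
features preserve enough perceptual structure for desk-scale work, and any
stronger pretrained extractor can be plugged in unchanged.

The segmentation objective is `L_seg = λ·BCE + Dice-loss` with λ = 0.5 and
soft Dice `1 − (2Σpt + ε)/(Σp + Σt + ε)`, ε = 1e−6.

## Training conditions

Inpainter: Adam, lr 1e−4, betas (0.5, 0.999), batch 16, 100 epochs,
train/test split 8:2, one discriminator step per generator step, both
discriminators on one optimiser. With λ_adv = 0 the loop is fully
deterministic under seed. The generator output is used raw (uncomposited)
in all losses; compositing happens only at synthesis time.

Segmenter: Adam with cosine-annealed learning rate (minimum 1e−5), batch
8, 200 epochs, split 8:2, online flip/rot90 augmentation with probability
0.5 each. Inputs are normalised by the per-channel mean/std of the
training manifest. The checkpoint with the highest validation mean Dice is
selected (selecting the *lowest* validation Dice would contradict the
selection's purpose, so highest is used) along with the last checkpoint.

## Mask synthesis and balancing

The DCGAN operates at 64x64 (4-layer transposed-conv generator from a
64-d latent, 4-layer strided-conv discriminator, non-saturating BCE
objectives, Adam lr 2e−4); samples are bilinearly upsampled to 256x256.
The generator ends in a sigmoid because masks live in [0, 1].
Post-processing converts to luma if needed, binarises at 0.5, and removes
8-connected components below 200 px (at 256x256). Components are rescaled
about their own centroids with nearest-neighbour sampling; size balancing
moves surplus masks into deficit area-bins with factor
`sqrt(target_area/area)`, targets drawn uniformly inside the bin.

## ROI synthesis

Candidate positions must have mean HSV saturation above 0.15 inside the
256x256 crop (tissue, not glass), must not intersect existing glomerulus
outlines, and must not overlap each other; masks are assigned to positions
by seeded permutation. Composites use hard mask edges — no boundary
feathering — and pixels outside every mask are bitwise identical to the
input. Each pasted mask contributes one traced outline
(largest connected component, marching-squares boundary, subsampled to
≤64 vertices) as a new sclerosed annotation. Synthetic tiles supplement —
never replace — their source tiles when training sets are mixed.

## Numerical engine

All trainable models run on `glomopaint.nd`, a compact reverse-mode
autodiff engine over numpy arrays. Convolutions loop over kernel offsets
with strided slices and `einsum` contractions; transposed convolutions use
the exact adjoint placement, verified by an inner-product identity and
finite differences. Batch norm uses full batch-statistics Jacobians in
training mode and running statistics in eval mode. Checkpoints are
self-describing npz archives with a JSON config entry. Default dtype is
float32; gradient-check tests switch to float64.

## Synthetic fixtures

`glomopaint.fixtures` generates PAS-like tiles: a saturated-pink textured
background (so the tissue heuristic recognises it), a white glass margin,
"normal" glomeruli as ellipses with a high-variance dotted dark-purple
interior, and "sclerosed" glomeruli as ellipses with a smooth dark
homogeneous fill. The two classes are separable by interior variance by
construction, which is what lets a tiny segmenter overfit them — passing
smoke tests therefore demonstrates that the training machinery optimises
its objective, not that the models reach publication-grade quality on real
stains. The fixtures deliberately omit: realistic stain variation,
tubular/interstitial structure, annotation noise, and scanner artefacts.

## Desk-scale problem sizes

The test suite and the acceptance script train at reduced sizes chosen as
the package's own smoke-scale conditions: the inpainter runs at 64x64 with
base width 8 for 200 non-adversarial steps on 8 fixture crops; the
segmenter uses the `tiny` backbone preset (widths 8/16/32) on four 128x128
tiles for 200 epochs; the mask DCGAN runs 200 steps at 64x64 with base
width 8. The smoke runs use Adam betas (0.9, 0.9): with only 200 steps,
the slow second-moment decay of the production betas (x, 0.999) never
finishes adapting, whereas 0.9 reaches a well-scaled step size within a
few dozen iterations. Full-scale defaults (256x256, width 64, 100 epochs, batch 16)
remain the configured production values.

## Known limitations

* No pretrained perceptual backbone is bundled; random-feature φ is a
  weaker perceptual prior than a pretrained one.
* The numpy engine is single-threaded per op and unsuitable for
  publication-scale training; it exists to make the full method exact,
  testable and dependency-light.
* Pyramidal slide formats are out of scope; inputs are pre-exported
  rasters.
* Whether published image-quality figures refer to masked-region or
  full-image measurements is ambiguous; both are reported.
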