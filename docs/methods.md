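# Methods

## Problem and model

In CBCT-guided online adaptive radiotherapy (ART), each treatment fraction
brings a new image of the patient on the couch, and targets plus
organs-at-risk must be re-contoured within minutes.  Conventional
auto-segmentation looks only at the current image (or the current image
plus the planning contours) and therefore repeats the same mistakes at
every fraction.  `progseg` implements a *progressive* segmenter: a 3D
U-Net whose skip connections pass through convolutional LSTM cells, so the
network carries a per-patient memory `(h, c)` at every resolution level
across the fractions of one treatment course.

Per fraction `t` the model receives a 3-channel volume:

1. the previous fraction's image (the planning CT before fraction 1),
   rigidly aligned to the current image;
2. the previous fraction's approved contours, encoded into a single
   channel as a label map (structure `k` of `K` maps to intensity `k/K`);
3. the current fraction's image.

The encoder produces one feature map per level (base width 32, doubling
per level over 5 levels by default; two `conv3^3 -> instance norm -> ReLU`
layers per level, 2x max pooling between levels).  Each level's feature
map is the input `x(t)` to that level's convolutional LSTM cell

    i = sigma(Wxi*x + Whi*h + bi)        f = sigma(Wxf*x + Whf*h + bf)
    o = sigma(Wxo*x + Who*h + bo)        g = tanh(Wxg*x + Whg*h + bg)
    c = f . c_prev + i . g               h = o . tanh(c)

with 3^3 resolution-preserving convolutions and no peephole connections.
The decoder consumes the cell states `c(t)` through the skip connections
(the bottom level feeds the decoder trunk) and mirrors the encoder with
transposed-convolution upsampling; a 1^3 convolution plus per-structure
sigmoid yields multi-label probabilities, binarized at 0.5 for metrics.
Memory is all-zero before a patient's first fraction and is cleared again
when the course ends, so patients are fully isolated.

Two memory-free baselines share the same trunk: `unet_prior` (same
3-channel input, plain skip connections) and `unet_ds` (current image
only).  The no-learning baseline `contour_prior` simply resamples the
previous fraction's contours through the rigid transform.

### Design choices worth flagging

- **`c(t)` feeds the decoder, not `h(t)`.**  This is implemented literally
  (a `skip_source` switch selects `h` for study).  It has a real
  consequence: under per-fraction truncated backpropagation the output
  gate's parameters receive *no* gradient, because `h(t)` only matters to
  the loss via the next fraction's gates.  With through-time
  backpropagation enabled (`detach_memory=False`, one optimizer step per
  patient) every gate of every cell receives gradient once the course is
  at least three fractions long; the test suite verifies both facts.
- **Truncated backpropagation is the default** (memory detached between
  fractions, one RMSProp step per fraction), matching sequential
  per-fraction training with batch size 1.
- **Instance normalization** is used because batch statistics are
  meaningless at batch size 1.
- **Teacher forcing**: during training and in the default "revised"
  evaluation mode the prior-contour channel holds the ground-truth
  contours of the previous fraction, mirroring a clinic where each past
  fraction's contours were clinician-approved.  "auto" mode feeds back
  the model's own predictions; "dir" mode uses deformably-registered
  contours on the current grid, with the current image in both image
  channels so image and contours stay consistent.
- **Forget-gate bias initialized to 1** so fresh cells retain early-course
  information; all other biases start at 0.
- **Multi-label sigmoid rather than softmax**, because targets (e.g. a
  nodal GTV) can abut organs-at-risk and the loss is per-mask.

## Training recipe

Composite loss `0.5*BCE + 0.5*softDice` (Dice smoothing eps `1e-6`,
probabilities clamped to `[1e-7, 1-1e-7]` inside the BCE); RMSProp
(`alpha=0.99`, `eps=1e-8`); initial learning rate `1e-5` with a
reduce-on-plateau schedule (factor 0.1, patience 3, monitoring validation
loss) floored at `1e-8`; 40 pre-training epochs on simulated courses
followed by 30 fine-tuning epochs continuing from the last pre-trained
checkpoint (learning rate and schedule restarted, a flagged choice);
patient order reshuffled every epoch from the run seed; memory cleared
before and after every patient.  Optional global-norm gradient clipping
(`grad_clip_norm`) is available and off by default.

The plateau patience/factor and the choice of validation loss as the
monitored quantity are not pinned by the recipe's description and are
package defaults; both are configurable.

## Synthetic data

No clinical data ships with the package; every test input is generated.

**Phantoms.**  `make_phantom` places `n` non-overlapping axis-aligned
ellipsoids ("organs") with at least a 2-voxel gap in a darker background
(intensity 0.15), emitting already-normalized intensities in [0, 1].  All
organs draw their intensities from one narrow soft-tissue band
([0.55, 0.80]) with distinct values whose per-patient ordering is random:
intensity *localizes* organs against the background but does not reliably
*identify* which structure a blob is — as with soft-tissue OARs on CBCT —
which is precisely the information the prior contours carry.  Gaussian
image noise (sd 0.02 by default) is added and clipped to [0, 1].

**Fraction simulation.**  A smooth random displacement field (per-component
Gaussian-smoothed white noise, rescaled so the maximum displacement norm
equals the requested amplitude) is scaled by `s in {-1, -0.5, 0, 0.5, 1}`
and applied to the base image (trilinear) and contours
(nearest-neighbour), yielding five fractions of gradually changing
anatomy per patient.  Negation is literal vector negation, not true
field inversion; the discrepancy is accepted as part of the method.  The
`s=0` fraction reproduces the base exactly and is kept in training.
Displacements are stored in voxel units; warping is backward (pull) with
edge clamping.

What the phantoms do *not* emulate: CT physics (noise texture, artifacts,
beam hardening), realistic head-and-neck anatomy and topology change,
inter-observer contour variability, and CBCT->sCT synthesis.  Passing
phantom studies therefore demonstrates that the architecture, memory
mechanism, training loop and evaluation chain work as specified — not
clinical-grade accuracy.

## Reference studies (scripts/acceptance.py, tests)

Problem sizes are chosen so each study runs in minutes on one CPU.

- **Overfit recovery**: one phantom patient, three fractions (scales
  -1, 0, 1), 32^3 voxels; LSTM-UNet with base width 8 and 3 levels trained
  for 150 fraction-steps.  Success is a teacher-forced course DSC >= 0.90,
  demonstrating the full loop end to end.  The learning rate for these
  demonstration studies is 5e-3: RMSProp's normalized updates let a small
  model converge within a few hundred steps, where the full-scale recipe's
  1e-5 presumes tens of thousands.
- **Cohort comparison**: 6 training / 2 held-out phantom patients, 24^3
  voxels, 3 structures, displacement amplitude 5 voxels (smoothness 3);
  `unet_ds` and `lstm_unet` (width 8, 3 levels) trained for 40 epochs
  under an identical protocol, then scored on the held-out courses
  together with `contour_prior`.  The expected qualitative result is the
  directional ordering `unet_ds < contour_prior <= lstm_unet`: direct
  segmentation cannot tell the structures apart, while the
  memory-equipped prior-guided model must at least match the raw prior it
  is given.  A paired t-test on the concatenated per-structure DSC atoms
  accompanies the means.  Because grids are constructed aligned, rigid
  registration is skipped (`register=False`) inside these studies.

  With only six training patients the upper leg of the ordering is a
  *stochastic* property: whether the trained network generalizes past the
  raw contour prior on two particular held-out patients varies with the
  run seed (the lower leg, `unet_ds < contour_prior`, is robust).  The
  test suite therefore checks the ordering at a fixed seed, while
  `scripts/acceptance.py` reports whatever its given seed produces.

## Numerical and degenerate-input conventions

- Dice of two empty masks is 1.0 (absence agreeing with absence); exactly
  one empty mask scores 0.  Hausdorff distances are undefined for empty
  masks and raise.
- Surface distances use boundary voxels (face-connected erosion residue),
  in mm via the voxel spacing; HD95 is the 95th percentile of the pooled
  directed nearest-boundary distances.
- The paired t-test follows the pooled "concatenated structures" design;
  this pools non-independent observations and is offered alongside
  per-structure testing (`summarize` keeps the atoms recomputable).
  Zero-variance differences raise rather than returning NaN.
- Rigid registration (SimpleITK Euler3D, mean squares, multi-resolution)
  short-circuits to identity for bit-identical inputs; solutions rotating
  more than 0.2 rad are treated as failures and fall back to identity
  with a `converged=False` flag.
- Max-pool gradient is shared equally among tied maxima; instance-norm
  epsilon is 1e-5; all computation is float64, which makes fixed-seed
  runs bit-reproducible on one CPU.

## Known limitations

- Deformable image registration itself is out of scope; "dir" mode
  consumes externally produced contours, and at phantom scale the
  simulator's known field acts as a DIR oracle of controllable accuracy.
- The phantom studies use small volumes and cohorts; absolute DSC values
  are not comparable to clinical-scale results, only the directional
  relationships between models are meaningful.
- The single-channel label-map encoding of all structures is a literal
  reading of the 3-channel input description; abutting structures with
  adjacent label values could in principle be confounded by interpolation
  of the prior channel (masks are nearest-neighbour resampled to avoid
  this).
- Under the default truncated backpropagation the output gates stay at
  initialization (see above); enable `detach_memory=False` to train them.
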