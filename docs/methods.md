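# Methods

## Problem and model

Glaucoma screening from a color fundus photograph rests on a handful of
closely related measurements: the outline of the optic disc (OD), the
outline of the optic cup (OC) inside it, the vertical cup-to-disc ratio
vCDR = OC_height / OD_height that quantifies "cupping", the position of
the fovea, and the binary diagnosis itself.  `fundusmtl` trains one
shared network for all four tasks and couples it with a second, purely
geometric classifier on the vCDR.

The backbone is a U-Net whose encoder is the 13-convolution VGG-16
feature stack: five blocks of 3x3 convolutions with ReLU, 2x2 max-pools
after the first four blocks, no batch normalization, bottleneck at 1/16
resolution with 512 channels.  The decoder has four stages; each doubles
the resolution with parameter-free bilinear interpolation, concatenates
the matching encoder block's pre-pool features (512/256/128/64
channels), and applies one 3x3 convolution + ReLU with output widths
192, 96, 64, 32.  Heads:

* OD and OC: 1x1 convolution + sigmoid on the final decoder features;
* fovea: 1x1 convolution with identity activation, trained to regress a
  Gaussian saliency map and read out via center of mass;
* glaucoma: global average pooling of the bottleneck, dense 512->256 +
  ReLU, dense 256->1 + sigmoid.

This pinned layout has exactly 17,169,188 trainable parameters
(14,714,688 of them the canonical VGG-16 convolution stack).  The four
single-task variants - the same backbone carrying only one head each -
total 65,958,884 parameters, 3.84x the shared model.  The decoder
widths and the 256-unit classifier hidden layer are fixed precisely so
that these totals hold; counting follows k^2*c_in*c_out + c_out per
convolution and n_in*n_out + n_out per dense layer.

All weights start from Kaiming-uniform draws with ReLU gain
(U(+-sqrt(6/fan_in))) and zero biases; an ImageNet- or fundus-pretrained
encoder can be loaded from a named-array container instead.

The network, its backward passes and both optimizers are implemented
directly on numpy: convolutions are evaluated as one large GEMM per
layer over an im2col patch matrix, and every layer's analytic gradient
is verified against finite differences in the test-suite.  This keeps
the package importable anywhere scientific Python runs, at the cost of
training speed - which is why the shipped experiments run at 64-px
resolution (see "Problem sizes" below).

## Losses

* OD/OC maps: binary cross-entropy averaged over pixels.
* Fovea: the target is an isotropic Gaussian bump (equal variances,
  zero covariance) centered on the annotated coordinate and
  peak-normalized to 1; the loss is the SUM of absolute deviations over
  pixels, because the target values are continuous rather than binary.
  The sum (not mean) convention follows the loss as defined; relative
  task scales are not re-balanced because the per-task uniform weights
  c^(k) = 1 are kept and, under per-task Adam, each task's update
  magnitude is normalized per coordinate anyway.
* Glaucoma: focal loss -(1 - p_t)^gamma log(p_t) with gamma = 2,
  down-weighting confident decisions so the ~10% positive class is not
  drowned out.  The focal loss is implemented with the standard
  negative sign so that it is non-negative and decreasing in
  confidence.
* All logarithms clamp probabilities to [1e-7, 1 - 1e-7].

Saliency spread: the default is sigma = 8 px at 512-px input, scaled
linearly with resolution (1 px at 64).  The desk-scale experiments pass
sigma = 5 px explicitly at their 64-px working resolution, for two
reasons.  A 1-px bump covers less than 0.1% of the image and provides
nearly no gradient signal to a randomly initialized network.  More
importantly, the fovea coordinate is read out as the center of mass of
the raw predicted map (deliberately without cleaning), so any residual
positive ripple over the background competes with the peak; a wider
bump carries proportionally more mass (~2 pi sigma^2) and keeps the
center of mass anchored even when small residuals remain.  Five pixels
at this resolution is about a quarter of a disc diameter - roughly the
extent of the foveal avascular zone - and costs nothing in extraction
accuracy, which is exact for any symmetric bump away from borders.

## Training rules

With task losses L^(k), shared weights w, learning rate eta and one
mini-batch xi_t per iteration, three update rules are provided:

1. aggregated ("vanilla"): one step on sum_k c^(k) L^(k), a single
   shared optimizer;
2. alternating: N sequential plain gradient-descent sub-steps, task k
   differentiating at the weights left by task k-1;
3. independent optimizers (MTL-IO): the alternating rule, but task k's
   gradient passes through its OWN moving-average transform (Adam with
   betas (0.9, 0.999), eps 1e-8 by default).  Each task's first/second
   moments and step counter see only that task's gradients, so no
   momentum direction ever leaks between tasks.  With plain SGD as the
   per-task transform the rule is bitwise identical to (2); with one
   active task all three rules reduce bitwise to single-task training.

Design choices where the design was genuinely open: the task order is
fixed to (od, oc, fovea, glaucoma) for reproducibility rather than
shuffled; the same mini-batch is shared by all sub-steps of an
iteration; the glaucoma sub-step updates only the dense branch under
multi-task training (the segmentation and fovea tasks train the shared
body; this also makes the classifier a cheap sub-step), while the
glaucoma-only single-task model lets the gradient flow into the
encoder, since nothing else would train it.  A non-finite loss aborts
training immediately rather than skipping batches.

The vCDR logistic classifier sigmoid(a * vCDR + b) is fitted after the
epochs finish, on the training set's own post-processed predictions, by
Newton iterations on the log-likelihood with an L2 penalty
(lambda = 1e-3) on the slope only.  The unpenalized intercept keeps the
fit equivariant under shifts of the vCDR axis (symmetric data crosses
probability 0.5 exactly at its midpoint); the slope penalty guarantees
a finite optimum when the classes are separable.

## Post-processing and metrics

Maps are thresholded at 0.5 (the sigmoid midpoint) and reduced to their
largest 8-connected component before any measurement; the fovea map is
deliberately NOT post-processed, because pruning could shift its center
of mass.  vCDR heights are occupied-row spans (max - min + 1).  The
glaucoma score is the average of the dense head's probability and the
vCDR classifier's probability, thresholded at 0.5 with ties called
positive (screening favors sensitivity).  Metrics: Dice overlap (both
masks empty counts as agreement), Euclidean fovea error in pixels (an
optional scale factor converts units), and ROC AUC computed as the
Mann-Whitney pair statistic with ties at 1/2 - identical, as the tests
verify, to the trapezoidal area under the constructed ROC curve.

Degenerate cases: an empty predicted disc leaves the vCDR undefined;
such images fall back to the dense head's probability alone and are
flagged in the per-image records instead of aborting the report.

## Synthetic data

The generator emulates the statistical structure the pipeline relies
on: a bright elliptical OD containing a brighter concentric OC, the
vertical extents realizing a known vCDR; a darker fovea spot at a
recorded coordinate 2-3 OD diameters to the side (clamped so the whole
geometry stays inside the frame at small image sizes); a smooth reddish
background texture; pixelwise Gaussian noise (sd 0.05).  The label is
1 exactly when the recorded vCDR exceeds 0.6, with an optional flip
probability, and the positive class is held at 10% prevalence - the
class imbalance the focal loss targets - by drawing exactly
round(0.1 n) positive vCDRs above the threshold (stratified sampling
rather than rejection, so generation time is bounded).

Rasterization is exact by construction: pixel centers are tested
against the ellipse inequality, ellipse centers sit on integer pixels
and vertical semi-axes are half-integers, so a semi-axis m + 0.5 spans
exactly 2m + 1 rows.  The recorded vCDR is the realized row-span ratio
(2m+1)/(2M+1) closest to the drawn value (nudged at most one row to
stay on the drawn label's side of the threshold), which the mask-based
vCDR computation recovers exactly; `verify_ground_truth` audits this,
cup-inside-disc containment, and that the recorded fovea coordinate
sits on the local intensity minimum.

What the generator does NOT emulate: vessel trees, illumination
artifacts, camera color profiles, annotation noise, or any correlation
between image quality and disease.  Passing the desk-scale recovery
test therefore shows that the architecture, losses, optimizer scheme
and post-processing interlock correctly end to end - not that the
trained weights transfer to real fundus photographs.

## Problem sizes, staged training, numerical choices

The shipped training experiments run at 64-px resolution with batch
size 8 on 64 synthetic training images, evaluating on 100 held-out
images; these sizes keep the full suite tractable on a single CPU
core.  Training uses a staged schedule of three MTL-IO phases over the
same data (20 epochs at learning rate 3e-3 with per-task Adam betas
(0.9, 0.99), then 4 at 1e-3 and 2 at 2e-4 with default betas; per-task
optimizer state restarts at each stage, which the bias correction
absorbs).  The staging reflects how Adam behaves at aggressive rates:
per-coordinate updates have near-constant magnitude ~eta, which forms
features quickly but leaves every output oscillating with amplitude
proportional to eta; the low-rate stages let that jitter decay so that
thresholded masks sharpen and the fovea map's background residual
stops polluting the center of mass.  The second-moment constant 0.99
(instead of the 0.999 default) shortens Adam's memory so the per-task
optimizers adapt within the short first stage; the default is kept at
the conventional (0.9, 0.999) for long training runs.

One caution from developing this schedule: at rates near or above
5e-3 this 13-layer, batch-norm-free network trains chaotically - small
changes (a different loss-target width, even a different rounding of
the same arithmetic) can flip a run between convergence and collapse
of a task.  The shipped stage rates were chosen on the stable side of
that boundary.  Forward passes are float32; losses and metrics
accumulate in float64.  Gradient checks in the tests run the whole
network in float64, where every layer's analytic backward matches
central differences to ~1e-6 relative error.

## Known limitations

* No GPU or SIMD-specialized kernels: training wall-time is dominated
  by im2col copies and single-threaded GEMMs, so REFUGE-scale training
  (hundreds of 512-px images, dozens of epochs) is out of reach of this
  implementation; the package targets method study and desk-scale
  validation, with real-data training left to a GPU port of the same
  update rules.
* Within the few hundred optimizer steps the desk-scale budget affords,
  the high-contrast disc segments reliably, but the subtler cup
  boundary and the fovea saliency map may remain under-converged, and
  which of them matures in a given run is sensitive to the training
  trajectory (see the chaos caution above).  Fully stable convergence
  of all four tasks needs substantially longer low-rate training than
  the shipped experiments run.
* The vCDR classifier is fitted on training-set predictions; with very
  small or single-class training sets it is skipped and the ensemble
  degrades to the dense head alone.
* The alternating rules make training time scale linearly with the
  number of tasks per iteration.
* Mask decoding assumes the tri-level gray convention; datasets with
  per-structure binary masks need a trivial re-encoding pass first.
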