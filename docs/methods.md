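# Methods

## Model

The network is a minimal visual hierarchy: an image layer (`h = 0`) and two
hierarchies of sigmoid units above it (`h = 1, 2`; 64 + 64 units at full
scale).  At every time step each hierarchy updates from the *previous* state
through three pathways,

```
X[h, t] = sigma( W_td[h]  X[h+1, t-1]      (top-down; absent at the top)
               + W_rec[h] X[h,   t-1]      (recurrent)
               + W_bu[h]  X[h-1, t-1]      (bottom-up)
               + b[h] )
```

with `sigma` the logistic function, so responses live in (0, 1).  The image
layer is clamped to the presented stimulus; the top-down inference into it,
`sigma(W_td[0] X[1, t-1] + b[0])`, is kept as a separate *reconstruction*
channel.  The 64x96 image is divided into four overlapping corner-anchored
38x58 patches; each patch feeds its own disjoint group of 16 lower-hierarchy
units through a structurally sparse matrix whose zero pattern is enforced at
initialisation and after every update.  Everything else is dense.

Time is processed in windows of 5 steps with a fixed image; across windows
the responses carry over (the final state of one window seeds the next), and
the state's image slot likewise carries the previous window's image into the
first bottom-up step — fresh states start at the sigmoid midpoint 0.5 with an
empty (zero) image slot.  Five steps is the shortest window in which image
information can ascend the two hierarchies, return, and still leave one step
of "future" response to compare against.

## Objective

Learning minimises `L = L_temporal + lambda * L_spatial` by gradient descent.

**Temporal term.**  For every anchor step `t` whose two- and three-step
compositions both fit in the window (`t = 2..4` for a 5-step window),
the squared component-wise difference between the state after `t` steps and
the state after `t + 1` steps is summed over units, batch and anchors.  At
the image layer the deeper composition is *defined* as the presented image,
so the term compares the reconstruction with the true image: reconstruction
error is built into temporal smoothing.  The reduction over components is a
plain sum by default (`temporal_reduction="sum"`); a per-hierarchy mean that
weights each layer equally regardless of its size is available.

**Spatial (entropy) term.**  For each hierarchy the responses of the
minibatch window form a sample set; the term is the summed log pre-normalised
density `log P(x) = log Q(x) - log Q'(x)`.  `Q` is an unnormalised Gaussian
kernel density estimate (the partition constant is irrelevant to the
minimiser and omitted).  `Q'` is the same estimate over pseudo-uniform
samples of the response domain and divides out the boundary-induced
depression of `Q` near the edges of the unit cube; under the *sparseness
constraint* the `Q'` samples are drawn on `[-1, 1]^dim` instead, which makes
low responses cheap and yields sparse codes.  Minimising the term maximises
response entropy.

Two density-estimation choices were genuinely open and were settled by which
variant reproduces the model's documented phenomenology (the contrasts
between the lambda = 0, 10, 1000 conditions):

- *Marginal, not joint* (`kde_mode="marginal"`, default): each unit's batch
  of scalar responses gets its own 1-D density (kernel width 0.1), so
  maximising entropy drives every unit's response distribution toward
  uniform, in the spirit of single-neuron infomax.  A joint full-dimensional
  KDE (width `0.1*sqrt(dim)`) is implemented as an option, but its kernels
  vanish once responses spread out, the entropy gradient dies, and the
  balanced and entropy-only conditions become indistinguishable — none of the
  condition contrasts survive.
- *Pooled over the window* (`pool_time_steps=True`, default): the sample set
  pools steps 2..5 of the window, so a response that merely repeats itself
  over time raises its own density.  This is what makes the entropy term a
  genuine antagonist of the temporal term: with per-step densities a static,
  image-indexed code satisfies both objectives at once, and the entropy-only
  condition never develops the temporal noisiness that distinguishes it.

Gradients flow through the KDE through both roles of the responses (query and
sample); the `Q'` samples are constants.  The number of compensation samples
(default 200) is a variance/cost trade-off: its Monte-Carlo error is small
against the batch-40 KDE noise.

**Balance parameter.**  `lambda = 0` leaves pure temporal smoothing (TEC),
`lambda = 10` the balanced regime (STEC), `lambda = 1000` entropy-dominated
coding (SEC); SEC plus the sparseness constraint emulates sparse coding.
`lambda = 5` with the sparseness constraint is an ordinary configuration
value.

## Gradients and optimisation

No automatic differentiation is used: the package computes exact gradients of
`L` with respect to every weight matrix and bias by backpropagation through
time across the whole window, treating the carried-in state as a constant
(truncation at the window boundary).  The implementation is validated against
central finite differences on small models to relative error below 1e-4
(`tests/test_acceptance.py`), for both KDE modes, with and without the
sparseness constraint.

Optimisation is Adam (`alpha 0.001, beta1 0.9, beta2 0.999, eps 1e-8`) on
minibatches of 40 images sampled without replacement in shuffled epochs.  The
schedule is organised in repetitions (5 x 10^4 iterations at full scale); at
each repetition boundary the Adam moments and step counter reset while the
weights persist — "restart" is read as restarting the optimiser, since
discarding weights would make repetitions pointless.  A full re-initialise
and keep-the-best-repetition variant is available (`restart_mode="full"`).
Training is single-threaded numpy and bit-reproducible for a fixed seed; all
randomness (initialisation, shuffling, compensation samples) fans out from
the one training seed.

## Synthetic stimuli

The generators emulate the study's inputs without shipping any data:

- *naturalistic*: Gaussian noise shaped to a 1/f amplitude spectrum
  (spectral exponent 1, the canonical second-order statistic of natural
  scenes), min-max rescaled per image.  They reproduce natural scenes'
  power-law statistics and the dominance of cardinal-ish energy at low
  frequencies, but none of their higher-order structure (edges, occlusions,
  objects); conclusions from passing tests transfer to real scenes only at
  the level of second-order statistics.
- *glyphs*: random blurred polyline strokes on a dark background — sparse,
  spectrally distinct stand-ins for handwritten digits as "unlearned" inputs.
- *bars*: a binary white bar at one of eight orientations (22.5 degree
  spacing), default width 4 px, swept perpendicular to its orientation in
  half-open bands that tile the frame exactly.
- *probes*: binary images with a single 16x16 block of ones at a uniform
  random position, for reverse-correlation receptive-field mapping.  Corner
  pixels are coverable by only one block position, so full-corner coverage
  needs many probes; uncovered pixels are flagged, never silently zero.

Readers for raw 16-bit IML scenes and IDX digit files downsize with
anti-aliased resampling and rescale to [0, 1] (per-image min-max; a constant
image maps to 0.5 to avoid division by zero).

## Evaluation battery

- *Receptive fields*: per unit, the mean final-step response over all probes
  covering a pixel.
- *Global image distance*: the holistic-descriptor reference behind the
  original distance is underspecified, so the package uses a GIST-style
  descriptor — oriented band-pass energy (4 orientations x 2 scales) pooled
  on a 4x4 grid, L2-normalised — with plain pixel distance as a pluggable
  alternative.
- *Local similarity / discriminability*: Pearson correlation of image- vs
  response-space distances to the nearest 1-4% of images; and the proportion
  of 99th-percentile-dissimilar responses among 99th-percentile-dissimilar
  images.
- *Confusion index*: `|f_t(s) - f_10(s)| / |f_10(s) - f_10(s'))|` with `s'`
  the nearest image under the global distance, Euclidean norm per hierarchy;
  values below 1 mean the trajectory is closer to its own steady response
  than to its most confusable neighbour's.  Zero denominators are flagged and
  excluded from means.
- *Neuronal noise*: leave-one-out KDE entropy (shifted; no partition
  function) of responses within 5-step blocks of a 25-step presentation,
  averaged over stimuli; densities are clipped to the kernel-peak ceiling of
  1 and degenerate all-identical blocks are flagged.
- *Decoding*: Gaussian naive Bayes with one class per image, trained on the
  steady steps 10-11 and tested on steps 1..9, over the concatenated
  responses of both hierarchies.  With two training samples per class the
  per-class variance is floored at 1e-3.  With exactly identical
  class-conditional statistics the tie-break makes accuracy exactly `1/K`.
- *Orientation preference*: bar frames presented as consecutive 5-step
  episodes with state carry-over; a unit's response per orientation is its
  largest step-5 response over positions, preference is the argmax (ties
  broken toward the lowest angle and counted), and the cardinal fraction is
  the share preferring 0 or 90 degrees.
- *Synaptic strength*: L2 norm of each unit's incoming weight column per
  pathway; the top-down/bottom-up balance onto hierarchy 1 summarises how
  entropy weighting shifts the pathways.
- *Response distributions*: histograms over [0, 1] per step and hierarchy,
  with a middle-mass summary (fraction of responses in [0.25, 0.75]).

Stimulus presentation during evaluation carries state between consecutive
images (as in training); for throughput the sequence is split across at most
40 parallel streams, each a faithful sequential presentation from the
midpoint state.

## Problem sizes

Full scale (the `paper` profile: 64+64 units, 4212 images, 5 x 10^4
iterations) is configured but not exercised by the test suite.  The tests and
the acceptance script use two desk profiles chosen as the package's own
scaled-down study conditions:

- *desk*: 32+32 units, 200 naturalistic 64x96 images, 2000 iterations,
  minibatch 40 — used for the confusion-index experiment.
- *small*: 16+16 units, 60 naturalistic 32x48 images (19x29 patches),
  4000 iterations, minibatch 20, seeds 11/12/13 — used for the
  condition-ordering and qualitative comparisons.

## Known limitations

- The lambda = 0 (pure temporal) condition does not reach the degenerate
  input-ignoring optimum at desk scale: because the temporal term embeds
  reconstruction error, pure temporal training also rewards image-specific
  responses, and with a small synthetic image set the available units can
  encode the stimuli well enough that responsiveness wins.  Across-image
  response variance therefore *grows* rather than collapsing in the
  scaled-down runs; the corresponding acceptance test documents this as a
  failing check rather than weakening it.  At full scale, where thousands of
  hard natural scenes meet 16 units per patch, the achievable reconstruction
  gain is far smaller and the degenerate optimum is plausible.
- Entropy values are shifted (no partition function) and comparable only
  across conditions computed with the same settings.
- The evaluation presents stimuli in dataset order split over streams;
  different stream counts give slightly different carried states (the means
  are insensitive, but bit-level reproducibility requires fixing
  `n_streams`).
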