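# stec — spatio-temporally efficient coding

`stec` implements and dissects a computational principle for bidirectional
visual hierarchies: a network that learns by simultaneously **smoothing its
response trajectories in time** and **maximising the entropy of its
responses across stimuli**.  It is aimed at computational neuroscientists who
want a small, fully reproducible sandbox for studying how a single balance
parameter assigns representational function to a hierarchy with bottom-up,
recurrent and top-down pathways — and at anyone who needs the accompanying
analysis battery (reverse-correlation receptive fields, confusion index,
KDE-based neuronal noise, population decoding, orientation preference).

## The model in brief

A two-hierarchy stack of sigmoid units sits above a clamped image layer.
Each step propagates the previous state through all pathways:

    X[h,t] = σ( W[h+1,h]ᵀ X[h+1,t−1] + W[h,h]ᵀ X[h,t−1] + W[h−1,h]ᵀ X[h−1,t−1] + b[h] )

with the top-down term absent at the top and the image layer's inference
kept as a reconstruction channel.  Learning minimises

    L = L_temporal + λ · L_spatial

where `L_temporal` is the squared difference between the `t`-step and
`(t+1)`-step compositions of the inference map over a 5-step window (at the
image layer this becomes reconstruction error), and `L_spatial` is a
kernel-density estimate of the negative response entropy,
`Σₙ log(Q(xₙ)/Q′(xₙ))`, with `Q′` a pseudo-uniform compensation density that
cancels the boundary bias of `Q` on the unit cube.  λ = 0 gives pure
temporal coding (TEC), λ = 10 the balanced regime (STEC), λ = 1000
entropy-only coding (SEC); SEC plus a sparseness constraint (compensation
samples on `[−1,1]^dim`) emulates sparse coding.  Gradients are exact
backpropagation through time, written in numpy and verified against finite
differences.  See `docs/methods.md` for every modelling choice.

## Worked example

Train the balanced condition at desk scale (16+16 units on sixty synthetic
1/f images, ~2 minutes on one CPU) and ask the three headline questions —
does the response stabilise, how noisy is it, and can the stimulus be read
back out?

```python
import numpy as np
import stec

cfg = stec.HierarchyConfig(units=(16, 16), image_shape=(32, 48), patch_shape=(19, 29))
stim = stec.generate_naturalistic(60, shape=(32, 48), seed=101)
obj = stec.ObjectiveConfig(lambda_reg=10.0)
tr = stec.TrainingConfig(iterations_per_repetition=2000, repetitions=1,
                         minibatch_size=20, seed=11)
params, log = stec.train(stim, cfg, obj, tr)
print(f"final objective: {log.l_total[-1]:.1f} "
      f"(temporal {log.l_temporal[-1]:.1f}, entropy term {log.l_spatial[-1]:.1f})")

ci = stec.confusion_index(params, stim, t_ref=10)
print("mean confusion index, hierarchy 1, t=1..9:",
      np.round(ci["mean_per_time"][1][:9], 2))

nn = stec.neuronal_noise(params, stim)
print(f"neuronal noise (post-onset blocks): {nn['entropy'][1:].mean():.3f}")

dec = stec.decode_over_time(params, stim)
print(f"decoding accuracy at steps 1/5/9: {dec['accuracy'][1]:.2f} "
      f"{dec['accuracy'][5]:.2f} {dec['accuracy'][9]:.2f} "
      f"(chance {dec['chance']:.3f})")
```

Output:

```
final objective: 2298.8 (temporal 2011.0, entropy term 28.8)
mean confusion index, hierarchy 1, t=1..9: [0.96 0.22 0.19 0.13 0.07 0.03 0.02 0.02 0.01]
neuronal noise (post-onset blocks): 0.011
decoding accuracy at steps 1/5/9: 0.02 1.00 1.00 (chance 0.017)
```

Reading it: one step after a new image appears the response is still almost
as close to the *wrong* steady state as to its own (confusion index 0.96),
but it stabilises within a few steps and ends two orders of magnitude below
the confusion threshold of 1.  The within-stimulus response entropy
("neuronal noise") is low, and the stimulus identity — one class per image —
is decoded perfectly from step 3 onward, while step-1 responses still carry
the previous image.  The test suite trains the same profile longer (4000
iterations) under both λ = 10 and λ = 1000 across three seeds: the
entropy-only condition comes out 12–23× noisier (0.29–0.51 vs 0.017–0.025)
with late-step decoding down at 0.71–0.83, so entropy alone does not give
stable, decodable codes.

A command-line interface wraps the same machinery:

```sh
stec gen --kind naturalistic --n 200 --out stim.npz
stec train --profile desk --out runs/stec
stec eval --checkpoint runs/stec/checkpoint.npz --images stim.npz \
          --metrics confusion,noise,decode,weights --out metrics.json
stec compare --profile desk --out runs/compare   # TEC / STEC / SEC / Sparse
```

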