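# disfluency

Automatic recognition of stuttering disfluencies in speech — blocks
(silent stops before words, typically before plosives), syllable
repetitions and sound-initial prolongations — versus fluent speech, for
speech-pathology researchers who need an objective complement to human
disfluency judgements.

## Method

The pipeline turns a 4-s mono utterance (22,050 Hz, 16-bit) into a
compact feature vector and classifies it:

1. **Auditory front-end.** The waveform is cut into 171 consecutive
   512-sample FFT frames (~23 ms), A-weighted, and summed into 21
   one-third-octave bands (nominal centres 100 Hz ... 10,000 Hz), giving a
   band-level matrix `X` of shape `d × m = 171 × 21` in dB — a coarse
   loudness-like picture of what the inner ear forwards to the brain.

2. **Per-utterance PCA with a residual-distance feature.** `X` is
   standardised column-wise, `z_ij = (x_ij − x̄_j)/σ_j`, and the `m × m`
   correlation matrix `S = E Λ Eᵀ` is eigendecomposed. The leading `l`
   components are retained — by default `l = 4`, or by the joint
   Kaiser–Guttman / cumulative-variance rule
   `l = max(#{λ_i > 1}, min{l : Σ_{i≤l} λ_i / m ≥ 0.75})`.
   With scores `G = Z E_l` and reconstruction `Y = G E_lᵀ`, each frame
   gets the residual distance

   ```
   d_i = sqrt( Σ_j (z_ij − y_ij)² / (m − l) )
   ```

   a Q/SPE-style statistic: frames that follow the utterance's dominant
   low-rank spectral structure (notably silence) score near 0, frames the
   model cannot express score high. The 171-long distance vector is the
   classifier input. Factor loadings `a_ij = √λ_i · e_ij` (correlations
   between bands and scores) and per-band contributions
   `S_j = 1 − var(residual_j)/var(z_j)` are available as diagnostics.

3. **SOM baseline.** For comparison, a 5 × 5 Kohonen map (100 epochs,
   learning rate 0.1, bubble neighbourhood shrinking 3 → 0) quantises the
   21-dimensional frames; an utterance becomes its 171-long sequence of
   winning-unit indices.

4. **Classifier.** A multilayer perceptron `171-8-4` (tanh hidden layer,
   softmax output) trained with full-batch BFGS on categorical
   cross-entropy; outputs are class-membership probabilities, and
   `acc = N_c/N_t`, `ε = 1 − acc` summarise a held-out test set split
   stratified per class (37/9/9, 36/5/5, 42/5/12, 25/10/3 for
   blocks/repetitions/prolongations/fluent; totals 140/29/29).

Because no labelled stuttering corpus is bundled, a seeded synthetic
generator produces speech-like waveforms carrying each class's acoustic
signature (leading silence + burst, repeated voiced bursts, sustained
high-frequency noise, continuous syllables), plus low-rank-plus-noise
band matrices for testing the component-selection rule.

## Worked example

```python
import numpy as np
from disfluency import (RunConfig, run_pipeline, generate_utterance,
                        analyze, extract_features, standardize, fit_pca,
                        select_components)

u = generate_utterance("prolongation", seed=1)     # 88,200 samples, 4 s
m = analyze(u)                                     # 171 x 21 band levels
model = fit_pca(standardize(m))
print(np.round(model.eigenvalues[:6], 2))
# [13.87  6.85  0.09  0.06  0.03  0.03]
print(select_components(model.eigenvalues))        # -> 2 (98.7 % variance)

fv = extract_features(m)                           # residual distances
print(fv.d.shape, fv.d.min().round(3), fv.d.max().round(3))
# (171,) 0.025 0.178

rep = run_pipeline(RunConfig(seed=0, class_counts={
    "block": 10, "repetition": 10, "prolongation": 10, "fluent": 10}))
print(rep)
# overall accuracy acc = 1.0000  (error rate eps = 0.0000, n = 4)
#   block         accuracy 1.0000
#   repetition    accuracy 1.0000
#   prolongation  accuracy 1.0000
#   fluent        accuracy 1.0000
```

The eigenvalue spectrum shows the two dominant spectral modes of this
synthetic prolongation (low-frequency voicing vs. the sustained
high-frequency sibilant); the distance vector is lowest in silent frames
and highest where the spectrum departs from those modes; the end-to-end
run reports the test-set confusion summary.

A command-line interface mirrors the stages:

```sh
disfluency synth --out runs/wavs --counts block=5,fluent=5 --seed 0
disfluency extract --in runs/wavs --out runs/bands
disfluency features --method pca --l 4 --in runs/bands --out runs/features.csv
disfluency pipeline --seed 0 --out runs/full
disfluency compare --seed 0 --out runs/cmp     # PCA arm vs SOM arm
```

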