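# Methods

This note records the model assumptions, parameter choices, numerical
conventions and known limitations of the `disfluency` package. Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from external measurements.

## Signal representation

Utterances are 4-s mono waveforms at 22,050 Hz (88,200 samples),
amplitudes in [−1, 1], clipped to ±0.99 before 16-bit WAV export to avoid
wrap-around. The front-end uses consecutive **non-overlapping 512-sample
rectangular-window FFT frames** (frame duration 512/22,050 ≈ 23.2 ms). A
4-s signal contains 172 complete frames; the final frame is dropped so
every utterance maps to exactly **171 frames**, which fixes the feature
dimensionality across the whole chain.

Band analysis uses **base-ten third-octave bands**: exact centres
10^(n/10) Hz for n = 20..40 (100, 125.9, 158.5, ..., 10,000 — the
standard nominal ladder 100, 125, 160, ...), edges fc·10^(∓1/20), so
adjacent bands tile the axis exactly and the edge ratio is 10^(1/10).
Per-bin powers are weighted by the IEC 61672 A-weighting magnitude
(renormalised to exactly unity at 1 kHz; ≈ −19.1 dB at 100 Hz) and summed
into bands **proportionally to the overlap between each bin's frequency
interval (width fs/512 ≈ 43 Hz) and each band**. A hard
bin-centre-to-band assignment is not usable at this resolution: the
100 Hz band is only ~23 Hz wide and contains no bin centre, so it would
sit permanently at the silence floor and become a zero-variance variable
that correlation-matrix PCA cannot accept. Overlap weighting conserves
in-range power (the white-noise partition check agrees within 1 %) and
keeps all 21 bands live.

Band levels are reported in dB, `10·log10(power + 1e-12)`; the floor
keeps silence finite (−120 dB) and makes levels shift by ≈ +6.02 dB when
the waveform doubles. Whether the original representation was linear
power, dB or a sone-like loudness could not be settled from first
principles; dB was chosen as the standard loudness-like scale.

## PCA feature model

PCA is computed on the **correlation matrix** (standardised variables,
sample d−1 convention throughout, which makes the variance of score
column i equal λ_i exactly). Eigenvalues are sorted descending and
clipped at 0; each eigenvector's sign is fixed by making its
largest-magnitude entry positive, so loadings are reproducible.

PCA is fitted **per utterance** (171 observations × 21 variables): each
distance vector measures departure from that utterance's own dominant
spectral structure, which is what lets silence (the best-modelled
"background" of an utterance) score near zero while bursts and
high-frequency events score high. A pooled mode (one model across
utterances) exists but is off by default.

Component count: default `l = 4`; the data-driven alternative is
`l = max(n_K, l_V)` with n_K = #{λ > 1} (Kaiser–Guttman, minimum 1) and
l_V the smallest count reaching 75 % cumulative variance. A v-fold
cross-validation selector is **not** implemented (no reproducible
specification was available); the Kaiser/variance rule is the selector,
and this is a known limitation.

The residual distance divides the squared residual by (m − l) — the
discarded degrees of freedom — and takes the square root, making it a
per-degree-of-freedom RMS residual that is exactly 0 for in-span
observations. Summation runs over all m variables. Factor loadings use
the √λ scaling, which is the form under which loadings equal the sample
correlations between variables and scores (verified by test); the
variance-weighted alternative without the square root does not have that
property. Reconstruction is `Y = G E_lᵀ` on the standardised scale, whose
mean is zero.

Degenerate inputs: constant columns raise a zero-variance error naming
the offending band; `l ≥ m` is rejected (no residual degrees of freedom);
non-finite inputs are rejected up front.

## SOM baseline

A 5×5 rectangular Kohonen grid, online updates, constant learning rate
0.1, 100 epochs, and a **bubble neighbourhood under the Chebyshev grid
distance** whose radius shrinks linearly (rounded) from 3 to 0 — the
simplest scheme consistent with "neighbourhood decreasing from 3 to 0";
at radius 0 only the winner moves. Winner indices are row-major
(row·5 + col). Frames are z-scored with the training pool's per-band
statistics before training and lookup, because the dB bands have very
unequal variances and raw Euclidean distances would be dominated by the
loudest bands. Codebooks are initialised uniformly inside the training
data's per-dimension bounding box, so updates (convex moves toward data)
keep them inside it. Presentation order is reshuffled every epoch from
the same seeded generator; training is bit-reproducible per seed. The
per-frame update loop is a numba-compiled kernel; a pure-python reference
step is kept and cross-checked against it in the tests.

## Classifier

A 171-8-4 MLP: tanh hidden layer, softmax output, categorical
cross-entropy (mean over cases of −Σ_c target_c·ln p_c). The hidden
activation is not dictated by the problem; tanh/softmax is the standard
pairing with cross-entropy for a 4-class output. Inputs are z-scored with
training-set statistics (zero-variance features guard to sd 1) — this
also makes SOM winner indices usable directly as features. Weights start
uniform in [−0.1, 0.1], seeded.

Training is full-batch **BFGS** (quasi-Newton with Wolfe line search,
analytic gradient, ≤ 100 iterations); the gradient is verified against
central finite differences, and accepted steps are non-increasing in
training loss. When a validation set is supplied, the weights with the
best validation loss seen along the trajectory are retained — the
interpretation adopted for "100 epochs with a validation set". The
learning-rate/momentum figures sometimes quoted alongside BFGS have no
role in a quasi-Newton method; a momentum-SGD fallback (`solver="sgd"`,
lr 0.1, momentum 0.3) accepts them.

Evaluation reports the 4×4 confusion matrix (rows = true class),
per-class accuracy (diagonal over row sum), overall `acc = N_c/N_t`,
`ε = 1 − acc` (exact complement by construction), and per-case certainty
(the maximum output probability).

The reference split plan is per class
(train/validation/test): blocks 37/9/9, repetitions 36/5/5, prolongations
42/5/12, fluent 25/10/3 — totals 140/29/29 of 198. Other compositions
fall back to a proportional 70/15/15 plan. Assignment is stratified
random per seed, exact to the plan.

## Synthetic data: what it emulates and what it does not

The generator produces the **acoustic signatures the analysis chain
relies on**, not speech: voiced segments are harmonic pulse trains
(class-specific fundamentals 110–190 Hz, raised-cosine envelopes),
unvoiced events are band-passed noise. Class templates: blocks start with
1.3 s of near-silence before a 90-ms broadband burst; repetitions open
with five 150-ms voiced bursts separated by 200-ms gaps; prolongations
hold 1.6 s of 3.2–10 kHz noise; fluent speech alternates ~220-ms
syllables with ~120-ms pauses. A faint broadband background (5·10⁻⁴ RMS)
keeps every band alive in silence. These values are the **easy**
difficulty — chosen so the classes are unambiguous, as befits acceptance
checks of the machinery; the **hard** profile shortens silences and
weakens the spectral emphasis so the classes genuinely overlap. All
synthesis is keyed on (label, seed) and bit-reproducible.

Consequences: passing end-to-end tests demonstrate that the chain
separates classes *whose band-level signatures differ as constructed*
(easy mode: ≥ 3 dB in ≥ 5 bands for every class pair). They do not show
that real stuttered speech — with speaker variability, coarticulation,
recording noise and far subtler class differences — would be classified
at the same rates; near-perfect synthetic accuracy is expected and is a
property of the generator's contrast, not a clinical claim.

The low-rank fixture (`generate_lowrank_filterbank`) draws
`rank` Gaussian-bump spectral profiles (fixed), mixes them with i.i.d.
standard-normal time-varying weights and adds noise (sd 0.3 by default,
rank 4 to match the default retained component count so parameter
recovery doubles as an acceptance check). With these defaults the
selection rule recovers rank 4 in ≥ 90 % of replicates and the retained
components explain ~91 % of total variance on average.

## Problem sizes

The acceptance study uses 50 low-rank replicates (171×21 each); the
end-to-end checks run the full 198-utterance reference composition over
five seeds for both feature arms; the classifier property tests share one
balanced 80-utterance corpus. These sizes were chosen as the smallest at
which the stochastic checks are stable.

## Known limitations

- The disfluency classes have no published acoustic definitions beyond
  their names; the generator's signatures are plausible stand-ins, not
  reconstructions of any corpus.
- Only 22,050 Hz input is accepted; no resampling, no overlapping-window
  spectrograms, no cochlear modelling.
- Component selection by cross-validation, robust/sparse/kernel PCA,
  hexagonal or Gaussian-neighbourhood SOMs, and deep classifiers are out
  of scope.
- Probability outputs are uncalibrated; "certainty" is simply the
  maximum softmax output.
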