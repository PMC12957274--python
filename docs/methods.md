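# Methods

This note documents the modelling choices behind `kansleep`: the signal
model, the network components and their defaults, the synthetic benchmark
and what it does and does not demonstrate, and the numerical conventions.

## Signal model and preprocessing

The unit of classification is the 30-second epoch of a multichannel PSG
recording.  The reference sampling rate is 100 Hz (Ts = 3000 samples per
epoch); recordings at other rates are polyphase-resampled before epoching
so that convolution kernel sizes keep a single temporal meaning.  Epochs
are half-open sample windows `[i·30·fs, (i+1)·30·fs)` with 0-based
indices; a trailing partial epoch is dropped, and a hypnogram longer or
shorter than the signal by one epoch is truncated rather than rejected
(a common off-by-one between signal and label files).

Filtering follows standard clinical practice: zero-phase (forward–
backward) Butterworth band-passes of order 4 — 0.3–35 Hz for EEG/EOG,
10–70 Hz for EMG (clipped below Nyquist) — plus an optional 50 Hz notch
(Q = 30) and optional wavelet shrinkage denoising (4-level `db4`
decomposition, soft universal threshold `σ√(2 ln n)` with σ from the MAD
of the finest detail level).  The filter order and phase handling are
package choices; only the bands are dictated by the problem.

Per-epoch z-scoring uses the population standard deviation (divide by
Ts): the statistic describes *this* epoch, not a sample from a longer
process.  Channels with σ < 1e-12 (flat or disconnected leads) map to
zeros with a warning instead of aborting a run.

## Dual-stream extractor

Branch layout is conv1 → pool1 → conv2 → conv3 → conv4 → pool2 with a
rectifier after every convolution and dropout 0.5 after each pool
(training only):

| branch    | channels     | kernels    | strides  | pools (k=s) |
|-----------|--------------|------------|----------|-------------|
| temporal  | 32-64-64-64  | 50-8-8-8   | 6-1-1-1  | 16, 8       |
| frequency | 64-64-64-64  | 400-6-6-6  | 50-1-1-1 | 8, 4        |

Convolutions use the zero-padded "same" convention (output
`ceil(L/stride)`, total padding split left-biased); pools are valid and
non-overlapping (`floor((L−k)/s)+1`).  This is the unique standard
convention pair under which the two branches emit 192 + 64 = 256 features
per channel at Ts = 3000, which is exactly the downstream KAN input width
`channels·256` — the width consistency is asserted in the test-suite.
One extractor is shared across input channels (channel-wise front-end);
per-channel weights would multiply parameters without changing any shape
contract.

Hand-crafted alternatives for comparison runs: differential entropy
`0.5·ln(2πe·σ_b²)` per band-filtered channel, STFT log mean band power
(2-s Hann windows), and six summary statistics (mean, variance, skewness,
kurtosis, min, max).  The default band plan is delta 0.5–4, theta 4–8,
alpha 8–13, sigma 11–16, beta 16–30 Hz.

## KAN core

Every edge carries `φ(x) = w_b·silu(x) + w_s·Σ c_i B_i(x)` with cubic
(k = 3) B-splines on a uniform G = 5 grid over [−1, 1], matching the
scale of standardized inputs; nodes sum.  The basis is evaluated by the
Cox–de Boor recursion on uniformly extended knots (G + 2k + 1 knots,
G + k basis functions); the right endpoint is folded into the last
interval so evaluation is total on the closed domain.  Outside the
domain the basis is clamped to the boundary value (zero spatial
gradient) and the silu term carries the signal — the grid is never
refined or moved during training, which keeps runs deterministic.

Initialization matters more than usual here.  silu is not zero-centered
(E[silu(x)] ≈ 0.23 for standardized x), so constant-sign base weights
accumulate a common output drift of order √n_in per layer; through two
layers this saturates the downstream GRU gates and learning stalls.  The
package therefore draws `w_b ~ N(0, 1/n_in)` (zero-mean, fan-in scaled),
sets `w_s = 1`, and draws spline coefficients `c ~ N(0, 0.1²)`.  Both
`w_b` and `w_s` are kept and trained even though they are formally
redundant with the coefficient scale.

Fitting is Adam on mean squared error (regression) or cross-entropy
(classification) with analytic gradients; gradient correctness against
central finite differences (1e-4 relative) is part of the test-suite.
As capability checks, a 1→8→1 stack recovers `sin(x)` on [−π, π] to
held-out RMSE ≈ 0.001 and a 2→4→1 stack recovers `x₁·x₂` to ≈ 0.003,
orders below the 0.05 / 0.1 bounds asserted in the tests.

## Temporal head

A unidirectional GRU (input 64, hidden 32, zero initial state) runs over
non-overlapping windows of 20 consecutive epochs (10 min); the context
length is configurable.  The gates follow the standard two-gate
equations, making each new hidden state a componentwise convex
combination of the previous state and the tanh candidate — a property
asserted directly in the tests.  A single affine softmax map produces
the five stage probabilities per step; nothing else sits between the GRU
and the scores.

## Two-stage training and ablations

Stage 1 trains the extractor end-to-end on single epochs with a
temporary two-layer softmax head (its final layer initialized at 0.1×
He scale so the initial loss starts near ln 5 instead of spending early
steps shrinking oversized logits).  Stage 2 freezes the extractor,
materializes features once per recording, standardizes them with
training-fold statistics, and trains the KAN + GRU + head on windows of
consecutive epochs.  Ablation variants are configuration diffs:
A = affine trunk + GRU (the two-layer-head model), B = KAN without GRU,
C = fixed-rectifier MLP mirroring the KAN widths + GRU, D = full model.

Optimizer settings (Adam, stage-1 lr 1e-3 / 500 steps / batch 32,
stage-2 lr 3e-3 / 400 steps / batch 8 sequences) are package defaults
chosen once for the synthetic benchmark scale (2000 epochs, 2 channels)
and are all overridable.  Training uses fixed seeded step budgets rather
than early stopping: byte-identical reruns under a fixed seed are a
package guarantee, asserted by running a reduced cross-validation twice.

Balancing is applied to training folds only (a flag enables balanced
evaluation): *sleep-state focus* keeps at most 60 wake epochs (30 min)
on each side of the sleep period; *oversampling* then raises every
present class to the recording's majority count by duplicating epoch
indices with replacement; *undersampling* draws every present class down
to the minimum present count without replacement, over the full label
set.  Plans are index selections, so they are auditable and leave the
data untouched.  When a selection is non-contiguous, sequence windows
for the GRU are built over the selected epochs in index order — a
modelling approximation at the gaps that only affects balanced training.

## Cross-validation

Two benchmark protocols are built in: 25 folds over 50 subjects whose
2-subject test sets form a seeded partition (each subject tested exactly
once; per-fold validation pairs drawn from the remainder), and 10 folds
over 153 sessions with test sizes 16/16/16/15…15 partitioning the
sessions and 13 or 14 validation sessions (13 when the test set has 16,
keeping the training set at 124).  Sessions, not subjects, are the split
unit in the second protocol: two nights of one subject are treated as
independent samples.  A generic k-fold covers synthetic cohorts.  Every
cross-validation run asserts a leakage guard — no test recording may
contribute to any training selection plan — and pooled confusion
matrices equal the elementwise sum of per-fold matrices by construction.

Metrics derive from the pooled 5×5 table: per-class precision/recall/F1,
overall accuracy, macro F1 (unweighted mean over classes with defined
F1), and Cohen's κ = (p_o − p_e)/(1 − p_e).  Classes absent from both
margins yield flagged undefined entries excluded from the macro mean;
single-cell tables make κ undefined and are reported as such.  All
metric code is cross-checked against scikit-learn on random tables.

## Synthetic benchmark: what it shows and what it does not

The generator produces stage sequences from a first-order Markov chain
(0.85 self-transitions for bout persistence, optional forced wake blocks
at the recording edges) and per-epoch signals as band-limited
oscillations plus 1/f noise with canonical stage signatures: 10 Hz alpha
and high tonic EMG in wake, low-amplitude 5 Hz theta in N1, theta plus
13 Hz 1-s spindle bursts (p = 0.8/epoch) in N2, high-amplitude 1.5 Hz
delta in N3, and REM with large slow EOG deflections and minimal EMG.
Each (epoch, channel) has an independent sub-seed derived from the
master seed, so recordings are reproducible sample-for-sample.

These templates are deliberately easy: a 1-nearest-neighbour classifier
on per-epoch band powers already separates the stages almost perfectly,
which guarantees the end-to-end pipeline *can* succeed and makes a
failing run diagnostic of a code defect, not of data difficulty.  The
default end-to-end benchmark — 4 recordings × 500 epochs, one EEG and
one chin-EMG channel, train on two recordings, test on one — reaches
held-out macro F1 ≈ 0.88–0.94 depending on seed.  Passing it
demonstrates that the implementation learns and generalizes across
recordings; it says nothing about performance on real PSG, where stage
signatures overlap, artifacts abound, and scorer disagreement sets a
ceiling.  Real-data evaluation requires EDF recordings plus hypnograms
and the cross-validation protocols above.

## Numerical conventions and degenerate inputs

float32 in the CNN path, float64 in the KAN/GRU path; ties in max-pool
take the first maximum; dropout is inverted (identity at inference);
non-finite inputs and losses raise instead of propagating; all-wake
recordings yield empty focus plans with a warning; every random draw
flows from an explicit seed through `numpy` `SeedSequence` spawning, and
no code path consults global random state.
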