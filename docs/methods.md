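# Methods

## Synchronization-index decoding

All four decoders share one statistic: the normalized eigenvalue entropy of
the whitened joint correlation matrix of an EEG epoch X (N_c × M) and a
harmonic reference Y_n (2N_h × M).  Both signal sets are standardized row
by row (zero mean, unit variance, population divisor M — consistent with
the 1/M covariance convention).  The reference time grid runs
t = 1/F_s … M/F_s; it deliberately starts at 1/F_s rather than 0, and the
convention is fixed in one place because an off-by-one shift changes every
sample at short windows.

Whitening uses symmetric eigendecompositions of C₁₁ and C₂₂.  Eigenvalues
below 1e-10 × λ_max are floored there before inversion.  This
regularization matters in two regimes: very short windows, where C₁₁ is
near-singular, and noiseless synthetic data, where every channel is a
scaled copy of one waveform and C₁₁ is exactly rank one.  The floor keeps
the whitening bounded; directions in the floored null space carry no
cross-correlation, so they inflate the entropy (lowering S) without
disturbing the argmax.

The entropy index is evaluated as

    S = 1 + (Σᵢ λ'ᵢ log λᵢ − log tr R) / log P,

algebraically identical to 1 + Σ λ'ᵢ log λ'ᵢ / log P (because Σλ'ᵢ = 1)
but exact in floating point at the two extremes: R = I gives S = 0 and a
rank-one R gives S = 1, with no residual rounding.  Eigenvalues are clamped
at zero, values below the eigensolver's relative machine-precision floor
(P·ε·λ_max) are treated as exact zeros, 0·log 0 := 0, and the natural log
is used — the ratio to log P makes the base irrelevant.  The final S is
clipped to [0, 1].  Ties in the argmax break toward the lower frequency
index, deterministically.

## Temporally local covariance

The TMSI covariance C′ = Z L Zᵀ / M uses the graph Laplacian of a tricube
adjacency with locality parameter τ, measured in samples (τ = 15 at
250 Hz spans 60 ms).  The pairwise-difference form with prefactor 1/(2M)
and the Laplacian form with 1/M are exactly equal for any symmetric
adjacency — the cross terms pair up — and the test suite asserts this
equality directly rather than relying on the scale invariance of the
index.  (Whitening does cancel any uniform covariance scaling, which is
separately exploited by the all-ones-adjacency collapse test: TMSI with a
uniform kernel equals plain MSI.)  Both the X- and Y-side blocks use the
same L.

## Filter bank

Only the EEG is decomposed; the full N_h-harmonic reference is reused in
every subband.  Subbands are extracted with zero-phase (forward–backward)
Chebyshev type-I IIR bandpass filters designed to: passband equal to the
subband, stopband edges 2 Hz outside each passband edge (lower edge
floored at 0.5 Hz), 0.5 dB passband ripple, 40 dB stopband attenuation,
minimal order meeting the spec.  These margins are not dictated by the
method itself; they follow the convention established for SSVEP filter
banks.  Designs are cached and regenerated from their declarative spec —
coefficients are never serialized.  Fusion is linear in the per-subband
indices with weights ω_l = l^{−a} + b; no renormalization by Σω_l is
applied since the argmax is invariant to it.

Scheme d ([8l, 88] Hz) is the default layout.  The degenerate N_sb = 1
case makes FBTMSI identical to TMSI on the [8, 88] Hz-filtered epoch,
which the tests assert.

## Synthetic data generator

The generator emulates the structure of the public 40-target benchmark
recordings: 40 frequencies from 8 to 15.8 Hz in 0.2 Hz steps, 250 Hz
sampling, nine parieto-occipital channels, 140 ms visual latency, and a
subject × block × target layout (35 × 6 × 40 at full scale).  Channel c of
a trial at frequency f is

    x_c(t) = g_c Σ_{k=1..K} k^{−γ} sin(2π k f (t − latency) + φ_k) + σ n_c(t)

with K = 4 harmonics and decay γ = 1 by default, per-subject channel gains
g_c ~ U(0.5, 1.5) and harmonic phases φ_k ~ U(0, 2π), and trial-wise
noise.  The latency is a pure delay of the evoked component only; noise is
not delayed.

The noise is a unit-variance mixture of white noise and a 1/f^α-shaped
component (white noise shaped in the frequency domain and renormalized),
with pink fraction 0.8 and α = 2 by default.  The steep aperiodic
background is deliberate and load-bearing: scalp EEG power falls roughly
as 1/f² over the 8–90 Hz range, and it is precisely this concentration of
noise at low frequencies that makes the higher subbands — where harmonics
sit on a quiet floor — worth isolating.  Under a flat or mildly sloped
background, band-limiting removes nothing useful and the filter-bank
variants lose their advantage; with the default spectrum the narrowband
SNR still decreases strictly with harmonic order (the white component
guarantees it), matching the premise that motivates the decaying fusion
weights.

What the generator does not model: dipolar forward physics and realistic
channel covariance (channels differ only by gain), alpha rhythm and other
oscillatory background, eye-blink/EMG artifacts, inter-trial phase
drift, and latency variability across subjects.  Passing tests therefore
show algorithmic correctness and the expected qualitative ordering of the
methods under a controlled spectrum — not performance on real recordings.

All randomness descends from a single master seed via spawned
`SeedSequence` streams, so any subject or trial can be regenerated
bit-identically in isolation.

## Evaluation protocol

Accuracy is N_correct / N_total over trials.  ITR uses the Wolpaw formula
with selection time T = TW + 0.5 s (gaze shift) + 0.14 s (visual
latency); sub-chance accuracy is clamped to 0 bits/min rather than mapped
to the symmetric positive value.  The SSVEP SNR at f is the periodogram
power at f over the mean of its m = 10 neighbors on a Δf = 0.2 Hz grid
(zero-padded periodogram; the spectral estimator is a package choice).

Cross-validation leaves whole subjects out (default 5 folds).  Parameters
are chosen by exhaustive grid search on the training subjects of each fold
only; fold membership is recorded in the report for audit.  A pooled
("global") search mode exists for reproducing single-optimum analyses but
is intentionally not the default, since it lets test subjects influence
the parameter choice.  Grid iteration order is ascending (N_h, N_sb, τ,
a, b) restricted to the axes a method consumes, and ties keep the first
maximum, so searches are deterministic.  Default grids are
τ ∈ [2:1:19], a ∈ [0.25:0.25:2.5], b ∈ [0:0.25:1] (900 combinations for
the temporally local filter-bank method at fixed N_h, N_sb).

## Problem sizes in the shipped tests

The test suite and the acceptance script run entirely on simulated data at
desk scale, as a deliberate package choice: trials of 1.2 s (only windows
up to 1 s are analyzed there), single blocks of 40 targets for accuracy
studies, 20 seeds × 3 noise levels (σ ∈ {6, 9, 12}, chosen to span the
accuracy range between floor and ceiling so that method ordering is
observable) for the robustness study, and 35 subjects × 4 targets with a
2-point τ grid for the cross-validation bookkeeping audit, where the
partition logic rather than decoding performance is under test.

## Known limitations

* The benchmark MAT reader is best-effort: the 64-channel montage order is
  baked in from the public cap layout and should be verified against the
  dataset's own channel file; the reader is excluded from the core tests.
* The entropy index saturates well below 1 for realistic epochs (S = 1
  requires a single shared component); absolute S values are not
  comparable across methods, only the argmax is.
* Filter designs near Nyquist (upper stopband edge ≥ F_s/2) are rejected
  rather than redesigned with a relaxed transition.
* The temporally local covariance is evaluated densely; for M in the
  thousands a banded implementation would be preferable (the kernel has
  bandwidth τ), but at M ≤ 750 the dense path is already fast.
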