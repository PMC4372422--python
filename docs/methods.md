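# Methods

## Overview

`ppgphylo` assesses physiological synchrony between two people from
simultaneously recorded finger pulse waves. The chain is: preprocessing →
all-pole spectral modelling → pairwise spectral distortion → UPGMA tree →
cherry rule → three-measure consensus. This note records the model
assumptions, the parameters that matter, the numerical choices, what the
synthetic generator does and does not emulate, and known limitations.

## Preprocessing

Raw finger-PPG amplitude drifts slowly as the optical sensor settles. The
baseline is estimated as the least-squares polynomial of degree 6 over the
sample index and subtracted. The abscissa is centered and scaled to
[−1, 1] before fitting (`numpy.polynomial.Polynomial.fit`): a degree-6
Vandermonde on raw indices of a several-thousand-sample record is
numerically singular. The detrended wave is then smoothed with a
Savitzky–Golay filter (scipy, `mode="interp"`, so boundary windows use
their own polynomial fits and low-degree polynomials pass through exactly
over the full length).

Parameters: `detrend_degree = 6`; `sg_window`/`sg_polyorder` default to
11/3, common settings for waveform denoising at ~100 samples/s. The
smoothing window should span a fraction of one pulse period: for records
at the ~10 samples/s regime the synthetic study uses window 5, order 3
(`SYNTH_PREPROCESS`), since an 11-sample window there covers more than a
full beat and flattens the pulse itself. Both are config-exposed. The
pipeline detrends first and smooths second; the reverse order would smear
the drift estimate but not change any qualitative behaviour.

## All-pole modelling

One LPC model of order p = 12 is fitted per whole record by the
autocorrelation method: biased sample autocorrelation r(0..p) (the 1/N
normalization keeps the Toeplitz matrix positive semi-definite), then the
Levinson–Durbin recursion. No framing or windowing is used — the records
are stationary on the 3-minute scale for the purpose of an envelope
comparison, and a single model per signal keeps every downstream quantity
deterministic. The recursion also yields the reflection coefficients; all
|k_i| < 1 guarantees a minimum-phase polynomial and hence a strictly
positive model spectrum. Degenerate inputs (zero power, non-positive-
definite autocorrelation) raise errors naming the failing order and the
signal label.

The model cepstrum is computed by the standard coefficient recursion

    c_0 = log σ²,  c_n = −a_n − (1/n) Σ_{k=1}^{n−1} k·c_k·a_{n−k},

with a_k = 0 for k > p. (Printed versions of this recursion sometimes
carry two typographical slips — the running coefficient c_k appearing as
c_n inside the sum, and "a_k = 1 beyond p"; the recursion implemented here
is the one consistent with c_n being the Fourier coefficients of
log|S(ω)|², which the FFT-based oracle test verifies to 1e−6.)

## Distortion measures

All spectral integrals are (1/2π)∫_{−π}^{π} of even integrands, evaluated
by trapezoidal quadrature on G = 1024 uniform points over [0, π]
(config-exposed). Power spectra include the gain σ²; logs are natural.

* ISD: `(1/2π)∫ [P/P′ + log(P′/P) − 1] dω` — asymmetric divergence, ≥ 0,
  zero iff the spectra coincide.
* ID: computed by the closed form `log(aᵀR′a / σ′²)` with R′ the Toeplitz
  matrix of the second signal's stored autocorrelation and σ′² recomputed
  as a′ᵀR′a′. The recomputation makes the self-comparison exactly zero in
  floating point. The equivalent spectral-integral form
  `log[(1/2π)∫ |A|²/|A′|² dω]` is kept only as a test oracle. (Where this
  ratio appears printed upside down in the literature, the closed form
  fixes the orientation.) ID ≥ 0 because a′ minimizes the quadratic form
  over monic vectors.
* ID_s: the arithmetic mean of the two ID directions.
* LSD: `[(1/2π)∫ |log P − log P′|^m dω]^{1/m}` with m = 2 by default. The
  1/m root is applied — that is what makes the m = 2 case the
  root-mean-square log-spectral distortion.
* WCD: `Σ_{n=1}^{L} w(n)(c_n − c′_n)²`, w(n) = 1 + h·sin(nπ/L), defaults
  L = p − 1 = 11, h = L/2 = 5.5. The weight multiplies the squared
  difference once, no outer root; c_0 is excluded, so WCD is
  gain-invariant.

Matrices fed to tree building are always symmetric: ID enters as ID_s,
ISD as its two-way mean; LSD and WCD are symmetric by construction.
Round-off can leave distortion values at ~−1e−16 on near-identical model
pairs; matrix assembly clips at zero.

## UPGMA and the cherry rule

True size-weighted UPGMA (not WPGMA): at each step the pair of clusters
with the smallest mean pairwise leaf dissimilarity is merged, the new node
is placed at half the merge dissimilarity, and distances to the merged
cluster are size-weighted averages. Ties in the minimum are broken by the
lexicographically smallest pair of cluster names (a cluster is named by
its smallest leaf label) for cross-platform determinism. The result is a
rooted binary ultrametric tree, serialized to Newick with children ordered
by smallest descendant label and branch lengths formatted to 12
significant digits.

A measure supports the care-giver's influence when `Care-giver` and
`During care` form a cherry. An optional relaxed rule (disabled by
default, always reported separately) also credits support when the
care-giver leaf's sibling subtree merely contains `During care`; it
formalizes "the care-giver attaches next to the during-care branch"
topology readings, which are weaker evidence than the strict clade.

Consensus = round(100 · supporting/3) ∈ {0, 33, 67, 100}. The consensus
table renders an empty support set as "None".

## Synthetic sessions

The generator emulates exactly the features of a preprocessed finger-PPG
record that the pipeline is sensitive to — the spectral envelope and its
finite-record variability — and nothing else.

One pulse generator ("identity") is parameterized by: fundamental f0
(uniform over pulse_rate·[0.75, 4/3]/100 cycles/sample, i.e. roughly
54–96 beats/min), geometric harmonic decay (U(0.35, 0.75)), and one
log-amplitude tweak per harmonic (N(0, 0.4)) — people differ in pulse
rate, harmonic roll-off and fine harmonic balance, and those are the
dimensions an order-12 envelope resolves. A rendered record is

    Σ_h amp_h · (1 + am·w_t) · sin(h·φ_t + offset_h)  + background + drift + noise

with φ_t the integral of f0·(1 + fm·z_t); z and w are independent
stationary AR(1) processes (unit variance, correlation time `fm_tau`).
Defaults: n = 1800 samples (3 minutes at an abstract ~10 samples/s — the
regime of downsampled pulse data in which the harmonics occupy the band
the way formants do in speech), fm_depth = 0.02 (≈2% pulse-rate
variability, which broadens each harmonic line), fm_tau = 15 samples
(≈2 beats), am_depth = 0.2 (beat-scale amplitude variability),
background = 0.25 of pulse RMS as 80% flat / 20% low-pass noise (vasomotor
plus measurement-chain background; it keeps the harmonic peaks ~20 dB
above a smooth continuum and the all-pole fit well conditioned even with
no sensor noise), drift = 0.5 (degree-6 random polynomial, removed exactly
by the detrending stage), noise_sd = 0.1 white sensor noise.

Three of these choices matter and were design decisions, not defaults
copied from anywhere:

1. Pulse-rate variability is a stationary frequency modulation, not a
   random-walk phase. A random-walk hands every realization a residual
   net frequency offset comparable to its own line width, so two
   recordings from the *same* generator can look spectrally different —
   the opposite of what a synchrony benchmark needs.
2. A broadband, signal-proportional background is always present. An
   all-pole model fitted to a pure line spectrum over an empty floor has
   poles hugging the unit circle, and its envelope (especially the log
   spectrum in empty bands) is hypersensitive to realization noise.
3. The band placement (f0 ≈ 0.12 cycles/sample). If the harmonics are
   crammed into the bottom few percent of the band, the truncated
   cepstrum (L = 11) cannot resolve them and WCD loses nearly all
   discriminative power; at the chosen regime all three measures resolve
   identity differences.

A session draws the care-giver identity and three independent identities
for before/during/after; the during identity is the convex combination
(1 − κ)·own + κ·care-giver. κ = 1 means identical generators with
independent noise, jitter and modulation realizations; κ = 0 means fully
independent. Everything is reproducible from the integer seed.

What the generator does **not** emulate: pulse-wave morphology
(dicrotic notch, asymmetric upstroke), non-stationary arousal dynamics,
motion artifacts, sensor saturation, or any actual physiological coupling
mechanism. Passing the coupling-recovery tests therefore shows that the
pipeline detects planted spectral-envelope similarity at realistic
record lengths and noise levels — not that real care sessions produce
such similarity.

## Validation and problem sizes

The test suite checks each stage against an independent oracle:
least-squares detrending against a direct normal-equations solve;
Savitzky–Golay against explicit per-window polynomial fits;
Levinson–Durbin against scipy's Toeplitz solver; the cepstral recursion
against the DFT of the model log-spectrum (oracle models are drawn by
pole placement with radius ≤ 0.95 and carry exact theoretical
autocovariances, so oracle agreement at 1e−6 is meaningful); the Itakura
closed form against high-resolution quadrature of |A|²/|A′|²; UPGMA
against a brute-force implementation that re-evaluates the size-weighted
objective over all cluster pairs at every step, against scipy's average
linkage, and against exact recovery of random ultrametric matrices.

The end-to-end study runs 100 sessions per coupling level κ ∈ {0, 0.5, 1}
(plus 100 low-noise sessions at κ = 1), about 15 s in total: mean
consensus must be monotone in κ, fully coupled low-noise sessions reach
100% consensus in ≥95% of seeds, and at κ = 0 the care-giver/during
cherry occurs no more often than any other pair's (the four signals are
exchangeable under the null). `scripts/acceptance.py` recomputes these
statistics from scratch with a caller-supplied master seed.

The batch workflow (MAT v5 bundle loading → per-participant assessment →
consensus table) is exercised on synthetic stand-in bundles written at
test time; published bundles of real preprocessed recordings, where
available, go through the identical path via `read_supplementary_bundle`
and `assess_bundles`.

## Limitations

* The MAT bundle loader is a convention (largest numeric array, shorter
  axis = participants); bundles with a different internal layout need
  manual loading.
* ID requires both models to share one LPC order; mixed-order comparison
  is not supported.
* The consensus is a coarse 4-level statistic; with only three measures
  it cannot distinguish strong from marginal cherry support. Branch-length
  margins are available from the trees for finer analysis.
* Bootstrap-style confidence values on the trees are deliberately absent:
  resampling spectral-coefficient vectors has no column-exchangeability
  justification, unlike sequence alignments.
* With a continuous identity prior, two independently drawn "individuals"
  are occasionally near-identical spectrally; uncoupled sessions then
  produce chance cherries. This is a property of the null, not a defect:
  the same confound exists for real pulse recordings of two people with
  similar pulse rate and shape.
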