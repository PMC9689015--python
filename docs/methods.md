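# Methods

## Problem and pipeline

The package discriminates two neonatal pathology groups — sepsis and
Respiratory Distress Syndrome (RDS) — from expiratory cry segments.
The pipeline is: segment acquisition → per-segment feature extraction
(GFCC and/or harmonic-ratio statistics) → fusion by concatenation →
z-normalisation (train-fitted) → 55/15/30 stratified
train/validation/test split → exhaustive grid search on the validation
partition → final training → test-set evaluation (accuracy, precision,
recall, F1, ROC/AUC with septic as the positive class).

## Signal acquisition

Recordings are PCM WAV (the target corpus: 16-bit, 44.1 kHz, 2-channel
handheld recorder). Stereo collapses to mono by the channel mean; no
channel policy is implied by the data. Expiratory intervals come from
plain-text label files, one whitespace-separated `start end tag` line
per interval, times in seconds, column order configurable. Slices are
half-open `[round(start·sr), round(end·sr))` so adjacent intervals
never share a sample. An optional energy trimmer removes leading and
trailing frames whose RMS falls below −40 dB of the segment's peak
frame RMS (10 ms frames); the original corpus was silence-trimmed
externally by unspecified means, so this stage is a declared
re-implementation, not a reconstruction.

## GFCC

* Framing: 10 ms Hamming frames, 3 ms overlap read as overlap *length*,
  hence a 7 ms hop; both rounded to the nearest sample.
  `n_frames = floor((L − W)/H) + 1`.
* Spectrum: power spectrum with FFT size the next power of two ≥ the
  frame length (512 bins at 44.1 kHz).
* Filterbank: N = 64 Gammatone filters, 50 Hz – 8 kHz (capped just
  below Nyquist for lower-rate audio), centres uniform on the ERB-rate
  scale `21.4·log10(1 + 0.00437 f)`. Each row is the magnitude
  response of a 4th-order Gammatone filter,
  `[1 + ((f − fc)/b)²]^(−2)` with `b = 1.019·ERB(fc)`,
  sampled at the FFT bin frequencies and scaled to unit peak. N is a
  package default (common GFCC practice), not a corpus-derived value.
* Compression and cepstrum: per-frame energies are floored at
  `1e−12 ×` the frame's maximum filter energy (silence-safe and
  scale-aware; an absolute floor of `1e−12` applies when every energy
  is below 1), log-compressed, then transformed by the orthonormal
  DCT-II over the 64 log-energies. The first M = 13 coefficients are
  retained — the classifier input width for the cepstral modality.
* Aggregation: the per-segment vector is the frame mean. The upstream
  design feeds one fixed-width vector per segment and names no
  alternative; mean pooling is this package's choice.

Consequences used as test oracles: a global gain g shifts only
coefficient 0 (log turns gain into an additive constant; the DCT puts
constants into coefficient 0); an all-silent frame yields a constant
log spectrum, hence zeros in coefficients 1..12.

## Harmonic ratio

`HR = max_{τ ∈ [sr/f0_high, sr/f0_low]} r(τ)/√(E_head(τ)·E_tail(τ))`,
clipped to [0, 1]; zero-energy frames are defined as 0. The
autocorrelation is computed by zero-padded FFT and matches the
explicit double loop to 1e−9 (tested). HR uses its own framing —
40 ms frames, 10 ms hop — because a 10 ms frame cannot contain one
period of a low cry fundamental; the search band defaults to
150–1000 Hz (infant cry F0 and then some). The per-segment vector is
(mean, median, IQR, std) of the HR series; IQR interpolates linearly
between order statistics, std uses the n−1 denominator.

## Fusion, normalisation, split

Fusion is plain column concatenation: 13 GFCC + 4 HR = 17. The
normaliser is per-feature z-scoring with std floored at 1e−12, fitted
on **training rows only** and applied unchanged elsewhere — the
fitting population is a package decision made to exclude information
leakage. The split draws global partition sizes `round(n·frac)`
(adjusted to sum to n) and allocates per class by largest remainder
under both row and column budgets, so per-class counts stay within one
row of exact proportionality. The split unit is the segment, mirroring
the original random-per-sample protocol; because one newborn
contributes several segments, this lets a subject span train and test.
A `by_subject` split mode exposes that leakage risk as a switch
without resolving it.

## Classifiers

* **SVM**: soft-margin RBF kernel via scikit-learn's SVC with solver
  tolerance 1e−7 (stable under training-row permutation). The ROC
  score is the signed margin mapped through the logistic function.
* **MLP**: input → dense(128) → per-example standardisation of the 128
  activations (the design names a "normalization layer" without a
  type; per-example standardisation is this package's reading) → tanh
  → dense(2) → element-wise sigmoid. The two sigmoids are independent
  class scores, *not* softmax-normalised; the decision is the argmax
  and the septic node's sigmoid is the ROC score. Training: full-batch
  RMSprop (ρ = 0.9, ε = 1e−8), cross-entropy summed over the two
  output nodes plus `l2·(‖W1‖² + ‖W2‖²)`, default learning rate 0.001
  and 120 epochs, seeded He-style initialisation, fully deterministic
  per seed. Analytic gradients (including the standardisation-layer
  backward pass) are verified against finite differences in the test
  suite. A final training loss that fails to drop below the chance
  level 2·ln 2 raises a convergence warning rather than failing
  silently — low-dimensional inputs (the 4 HR features) are the known
  risk case.
* **Grid search**: exhaustive; γ ∈ {0.1, 0.25, 0.26, 0.3, 0.5},
  C ∈ {0.5, 1, 2, 4, 5} (25 combinations) for the SVM. The continuous
  MLP ranges are discretised to learning rate {1e−4, 1e−3, 1e−2, 1e−1,
  1} (log-spaced), L2 {1e−4, 5.5e−4, 1e−3}, epochs {50, 100, 150,
  200}. Selection is by validation accuracy; ties break to the
  earliest combination in (C asc, γ asc) / (lr, l2, epochs asc) order,
  preferring smoother models deterministically.

## Evaluation

Accuracy `(TP+TN)/n × 100`, precision `TP/(TP+FP)`, recall
`TP/(TP+FN)`, F1 `2TP/(2TP+FP+FN)`; accuracy is reported as a percent
and the other three as fractions. Zero denominators report 0 with a
degenerate flag instead of raising, so batch experiments survive
pathological splits. The ROC sweeps all distinct score thresholds with
ties grouped, plus the (0,0) and (1,1) endpoints; AUC is the
trapezoidal area and equals the Mann–Whitney pairwise ranking
probability to 1e−12 (tested against a double-loop oracle and
scikit-learn). A symmetric RDS-positive report is one call away
(`positive_class="rds"`).

## Synthetic corpus: what it emulates, what it does not

The generator emulates: expiratory segment durations (≈0.5–0.95 s,
mean ≈0.72 s, matching the 0.71/0.74 s class averages of the target
corpus), a 400–600 Hz fundamental with a 30-partial 1/k harmonic
series, vocal-tract formants as second-order resonators, aspiration
noise, and balanced classes with grouped subject ids (5 segments per
synthetic newborn).

Default study conditions (frozen; `default_corpus_spec`):

| parameter | septic | rds |
|---|---|---|
| F0 band (Hz) | 400–600 | 400–600 (identical — pitch carries no label) |
| formant centres (Hz) | 1100, 3200 | 1240, 3390 |
| formant jitter (per segment) | ±9% | ±9% |
| harmonic-to-noise ratio (dB, per segment uniform) | +3 … +14 | −7 … +5 |
| duration (s, uniform) | 0.50–0.92 | 0.53–0.95 |
| segments per class | 200 | 200 |

The class contrast is deliberately split across modalities: the HNR
offset is visible mainly to the HR statistics, the formant offset to
the cepstrum. Two design choices make that decoupling real:
per-segment parameter draws (HNR interval, formant jitter) give each
class genuine within-class spread — with fixed per-class values every
classifier saturates at 100% and nothing can be compared — and the
noise is filtered through the *same* formant stack as the harmonic
source (aspiration noise traverses the same vocal tract), which keeps
the spectral envelope nearly independent of HNR. With plain white
noise instead (`noise_through_formants=False`), the noise floor
flattens the spectrum as HNR falls and the cepstral features absorb
the harmonicity cue, making the HR features largely redundant. The
requested HNR is realised exactly (component powers measured before
summation; tested to 0.1 dB), and a manifest of per-segment draws
makes every corpus regenerable bit-for-bit.

What it does **not** emulate: real vocal-tract physiology (no glottal
pulse shapes, no source-filter interaction), inspiration phases,
hiccups, background chatter, recording-channel effects, or any
clinically measured parameter distribution — the two class
specifications are test scaffolding, not clinical claims. Passing
tests therefore demonstrate that the pipeline recovers class structure
of the kind it was designed to measure; they say nothing about
clinical accuracy on real cries, and the original study's clinical
numbers (computed on a private corpus) are deliberately not treated as
reproduction targets.

## Numerical choices and degenerate inputs

FFT sizes are powers of two; hop/frame lengths round to the nearest
sample; the DCT is the orthonormal variant (transform matrix times its
transpose is the identity to 1e−10); silence maps to finite features
everywhere (GFCC via the energy floor, HR by the zero convention);
fully silent segments are an error at trim time ("segment empty after
trim"); segments shorter than one frame are an error at framing time.
One global experiment seed fans out through `SeedSequence` into
named sub-seeds (corpus, split, MLP initialisation), each below 2³¹,
so stages can be varied independently and identical configurations
produce byte-identical outputs.

## Problem sizes

Unit and property tests run on segments of 0.25–1 s and corpora of
≤50 segments, mostly at 16 kHz where the sample rate is immaterial.
The end-to-end checks use the default 200-per-class corpus at
44.1 kHz; the no-leakage control uses 120 per class at 16 kHz; the
fusion-benefit replication runs 20 independent 200-per-class corpora.
The full test suite completes in a few minutes on one CPU; the
acceptance script in about three.

## Known limitations

* The fusion benefit is real but marginal under the frozen default
  conditions: across independent corpus seeds the tuned fused SVM beats
  or ties the best single modality in roughly 80–90% of replications,
  with failures concentrated where the cepstral features alone already
  exceed 98% accuracy (a one-test-sample difference at n = 120). The
  20-corpus replication in the acceptance script reports the measured
  fraction for its seed.
* HR saturates near 1 above ≈+20 dB HNR and, with formant-shaped
  noise, floors near 0.4 below ≈−10 dB (resonator ringing is itself
  weakly periodic), so the HR–HNR map is monotone only between those
  regimes; the strict five-level monotonicity property holds for white
  background noise.
* The MLP's "normalization layer" interpretation (per-example
  standardisation) and the mean-pooling of cepstral frames are
  declared package decisions; other readings (batch-norm-style
  statistics, median pooling) were not benchmarked.
* Grid ranges are fixed categorical sets; no refinement or continuous
  optimisation is attempted, by design.
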