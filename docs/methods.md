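# Methods

## CPP extraction

The extractor computes, per 1024-sample Hamming-windowed frame (hop 128),
the real cepstrum `Re{IFFT(log|FFT(x·w)|)}` with the natural logarithm, a
causal 7-tap quefrency-direction smoothing, the band-limited peak
prominence over quefrencies 22–400 samples, and a causal 7-tap
frame-direction smoothing of the resulting CPP vector.

Numerical and design choices, with rationale:

- **Log base.** Natural log, the cepstrum convention. Any other base
  rescales every CPP by a constant factor and cannot change a
  rank-/threshold-based classification.
- **Log-of-zero guard.** Spectral magnitudes are floored at
  `log_floor = 1e-10` before the log so an all-silence frame yields a
  finite cepstrum (an impulse of `log(1e-10)` at quefrency 0) rather
  than −∞.
- **Smoother coefficients.** Both smoothing filters use the same unit-sum
  Hamming-shaped coefficient vector. Only the temporal filter's shape is
  externally prescribed; using the identical shape in the cepstral
  direction is a symmetry choice, documented here because it is genuinely
  open.
- **Edge policy.** The causal FIRs renormalize over the taps actually
  applied at indices `n < l−1`, so constants are preserved exactly at the
  edges too (a zero-padded edge would bias the first six frames/quefrencies
  downward). A causal 7-tap filter delays a peak by up to 6 quefrency
  samples; peak-localization guarantees therefore refer to the unsmoothed
  cepstrum.
- **Prominence definition.** The band maximum minus the mean of the band
  with the single maximum value removed (denominator `Tmax − Tmin`, which
  equals the count of remaining band samples). Exactly one value is
  excluded even if the peak lobe spans several quefrencies; regression-line
  baseline variants of CPP are deliberately out of scope. Because the
  maximum is taken inside the band, CPP ≥ 0 always.
- **No dB conversion, no pre-emphasis, no amplitude normalization, no
  voicing detection.** The extractor processes every frame of curated
  sustained phonation; quality control is the caller's responsibility.
  Feature values on clean synthetic vowels are of order 0.05–0.3 in linear
  log-magnitude units.
- **Sampling rates other than 16 kHz** are accepted; `tmin`/`tmax` are
  interpreted as quefrency samples at the actual rate, and a warning is
  logged because the defaults encode a 40–727 Hz fundamental range only at
  16 kHz.

## Prime windowing

`nprime` is the prime in `[3, nmin]` minimizing the total discarded tail
`Σ count_i mod p`. Ties are broken toward the **larger** prime: at equal
loss, wider rows carry more information per training sample; the choice is
logged when invoked. Values enter subgroups in original temporal order and
the tail is discarded; there is no shuffling, no overlap, and no mixing
across speakers. The restriction to prime sizes is taken as given.

A worked-example caveat: for per-speaker counts [14, 21, 24] the
minimization rule selects 3 (losses {3: 2, 5: 9, 7: 3, 11: 15, 13: 20});
a reference narrative for this example reports a different total for size 3
(treating 24 mod 3 as 3 rather than 0) and settles on 7. The implementation
follows the stated rule; size 7 is reproduced by forcing
`PrimeWindower(nprime=7)`, and the acceptance checks for the size-7
partition (three subgroups of the 24-value speaker, three values lost)
condition on 7 being given.

## SMOTE balancing

Minority rows are topped up to `target_ratio × majority` (default 1.0,
integer-rounded) by uniform interpolation toward one of the seed row's
k nearest minority neighbors (Euclidean distance on the CPP features only;
k = 5 capped at `n_minority − 1`). Seed rows are cycled in order so every
minority row contributes. Sex/Group metadata of a synthetic row are copied
from its seed row; neighborhoods are not stratified by metadata — with
features this low-dimensional, stratification would mostly shrink the
neighbor pool. Synthetic rows are flagged and named `synthetic.<class>.<j>`
so the evaluation layer can prove they never reach a validation fold.
The minority class is determined per fold, not assumed.

## Classifiers

Four supervised methods behind one `ModelSpec` contract: random forest
(100 trees), SVM (RBF kernel, C = 1), LDA (no shrinkage), k-NN (k = 5,
uniform weights) — library defaults as the baseline, every hyperparameter
overridable, with a small grid-search helper for exploration. The original
tuned combinations behind the reference results are unpublished and no
attempt is made to reverse-engineer them. Feature rows are the CPP columns
only; Sex and Group are metadata. Unsupervised methods (GMM, K-means) are
out of scope.

## Evaluation protocol

One fold per speaker: all of that speaker's windowed rows form the
validation set. Each fold runs for `n_iterations` (default 10) distinct
seeds; with SMOTE on, a fresh augmentation of the training fold is drawn
per (iteration, fold) from a seed derived deterministically from the
iteration seed and fold index, so whole runs are bit-reproducible. With
SMOTE off, deterministic models make all iterations identical — the
repeated iterations only matter for the stochastic case study.

Accuracy is reported per held-out speaker (fraction of that speaker's
windows classified correctly), with per-speaker mean ± sample sd over
iterations and an overall mean over speakers.

**Rank-sum comparison.** For each speaker and method pair, the two
10-value iteration vectors are compared with a two-sided independent-sample
Wilcoxon rank-sum (Mann–Whitney) test, `U = ΣR₁ − n₁(n₁+1)/2` with
midranks for ties. Sidedness is two-sided because the question ("do the
methods differ on this speaker?") is symmetric. The independent-samples
test is used, following the protocol's naming, even though iterations are
paired by seed. p-values are exact by full enumeration (a dynamic program
over the rank-sum null distribution) for tie-free samples with
`n₁ + n₂ ≤ 20`; 10-vs-10 accuracy vectors almost always contain ties, so
in practice the tie- and continuity-corrected normal approximation is used,
matching common references. When every element of both vectors is one
identical constant the test carries no ordering information and the p-value
is reported as the literal `NA` — the convention that produces all-NA rows
for speakers at uniform 100 % (or 0 %) accuracy under every method. A
nonstandard printed variant of the U formula involving the second sample's
median exists in the source material; it is not any recognized statistic
and is not implemented. Significance is flagged at p ≤ 0.05.

## Synthetic data

Two decoupled fixture paths:

- **Audio path.** `synth_vowel` renders a sustained vowel as a harmonic
  series with 1/h roll-off, per-cycle frequency jitter and amplitude
  shimmer (relative Gaussian perturbations, in %), plus white noise scaled
  to a requested harmonics-to-noise ratio, peak-normalized to 0.9. It is a
  source-only model: no vocal-tract formants, no breath-group dynamics.
- **Table path** (default for protocol tests, fast). `synth_cohort` samples
  per-speaker CPP streams directly from Gaussian cells. The stated world:
  24 speakers, 12 affected / 12 control, balanced 3-speaker cells over
  sex × age group (young = 5–7 y, older = 8–12 y); per-speaker counts
  uniform on [40, 110] (matching a reference total of ~2,700 values over
  24 speakers with variable durations); control cell mean 0.050, affected
  0.030, within-speaker sd 0.004, with the young-female affected cell
  raised to 0.036 to emulate the reported greater overlap in that subgroup,
  and a 0.002-sd per-speaker random effect for realism.

What a green table-level test establishes: protocol correctness (fold
hygiene, balancing arithmetic, reproducibility) and that the pipeline
separates classes whose CPP distributions are separated. It does **not**
establish clinical performance: the direct sampler has no temporal
autocorrelation, session effects, or audio artifacts, and the synthetic
separation is far cleaner than real pediatric voice data. The end-to-end
experiment's ≥ 0.9 accuracy threshold is the package's own acceptance
property for this stated world, not a clinical claim: headline accuracies
from the private patient cohort are not reproducible here.

## Known limitations

- CPP defaults are calibrated for 16 kHz; other rates work but shift the
  f0 range the band covers.
- The exact software condition that produced occasional NA entries at
  non-degenerate accuracies in the reference tables is unknowable; only
  the stated zero-distance rule is implemented.
- The windowing worked-example discrepancy above means automatic prime
  selection can differ from the reference choice on the same counts.
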