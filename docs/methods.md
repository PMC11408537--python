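# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `megms`, in the package's own terms.

## Signal model and modality semantics

A recording is a channels × frames matrix with a sampling rate and a
modality tag. Three tags exist:

- `meg`: combined planar gradiometers. Each channel is the magnitude
  √(gx² + gy²) of a gradiometer pair (`preprocess.combine_planar`), so the
  data are nonnegative, reference-free, and polarity carries no meaning.
- `eeg`: average-referenced potentials; signed, polarity ignored by the
  microstate machinery (a topography and its negation are the same state).
- `grad`: signed planar-gradiometer data before combination. Band
  filtering belongs here: a 1–30 Hz band-pass removes the mean, so the
  canonical order is filter/resample the signed data, then combine.

These tags drive every mode-dependent choice:

| quantity | eeg | meg |
| --- | --- | --- |
| GFP | spatial SD after per-frame demeaning | spatial RMS, no demeaning |
| similarity | abs. Pearson correlation | uncentered cosine |
| k-means template update | leading eigenvector of the scatter | clamped (≥ 0) normalized mean |
| criterion distance | 1 − sim² | 1 − sim |

The EEG distance uses sim² so that anticorrelated maps are identical
(polarity invariance); the MEG distance uses plain 1 − sim because cosines
of nonnegative vectors already live in [0, 1].

## Synthetic-data generator

The generator emulates what the analysis assumes about real data:

- **State sequence.** A semi-Markov chain: run durations uniform on a
  configurable dwell range, default 50–150 ms (the classic microstate
  duration range); next state drawn from coverage weights with no immediate
  self-transition. Because forbidding self-transitions biases run-level
  sampling, the sampling weights are solved from the fixed point
  v_i(1 − v_i) ∝ w_i so that empirical coverage converges to the requested
  weights. Coverages above 0.5 are unreachable without self-transitions and
  saturate near 0.5. The tail of a sequence is closed by merging or
  splitting the final runs so every run respects the dwell bounds exactly.
- **Envelope.** A rectified sinusoid, default 10 Hz, reflecting the
  alpha-band amplitude waxing/waning that dominates resting M/EEG; GFP
  peaks therefore arrive ≈ 20/s, mimicking the peak rate of alpha-band
  filtered data.
- **Noise.** SNR is clean-signal RMS over noise SD. EEG noise is Gaussian,
  followed by average-referencing each frame; each run gets a random ±1
  polarity (per run, not per frame, since the analysis is polarity-blind).
  MEG noise is half-normal (|N(0, σ)|) so magnitudes stay nonnegative — a
  deliberate emulation of the noise floor of combined gradiometers.
- **Events.** Oddball schedules start with a standard and never place two
  deviants adjacently, so every deviant has a flaggable preceding standard.
  A deviant "boost" relabels the 150–300 ms post-onset window to the
  deviant state with a per-event probability, emulating deviance detection.
- **Parcels.** Source magnitudes are baseline + δ(parcel, state) + noise,
  clipped at zero — the structure the parcel permutation test assumes.

What the generator does **not** emulate: 1/f spectra, spatially correlated
sensor noise, ocular/cardiac artifacts, head-position effects, volume
conduction, or realistic 306-channel geometry (layouts are Fibonacci
hemispheres). Passing tests therefore demonstrate the correctness and
calibration of the algorithms under the stated model, not robustness to
every pathology of real recordings.

## Identification

Maps are taken at strict local maxima of the GFP (ties between nearby peaks
resolved toward the larger peak when a minimum separation is requested) and
unit-normalized (EEG: centered first). Whether to normalize peak maps
before clustering is an open choice in the literature; normalization makes
the similarity objective scale-free and is adopted here.

The modified k-means maximizes the mean squared similarity of maps to their
assigned template. Restarts use k-means++-style seeding in the
mode-specific geometry (next seed ∝ squared distance to the nearest seed):
with tightly clustered peak maps, uniform seeding frequently placed two
seeds in one cluster and stalled in local optima; distance-weighted seeding
removes that failure mode. Defaults: 100 restarts, tolerance 1e-6 on the
relative change of explained variance, ties in assignment to the lowest
template index (determinism). Empty or degenerate clusters are reseeded
from the worst-fit map.

Validity criteria operate on the pairwise mode-specific distance matrix.
Davies–Bouldin uses medoid scatter and medoid separation (a distance-space
formulation, since the criterion distances are not Euclidean) and is stored
negated so every curve is maximize-better. Krzanowski–Lai uses the pairwise
within-dispersion W(k) = Σ_c Σ_{i<j∈c} d_ij / n_c and is undefined at the
grid ends. Gamma and Point-Biserial subsample at most 50 000 seeded pairs;
Gamma's concordance counts are computed exactly on the subsample by sorted
search. For tractability the per-subject peak-map collection can be
subsampled (seeded) before the O(N²) criteria; the pipelines use 3000 maps.

The meta-criterion min-max normalizes each curve, takes the per-criterion
argmax plus the argmax of the elementwise median curve as candidates, and
returns the median candidate, rounding half-down and snapping to the grid
(lower value on ties). Flat or all-NaN curves are excluded; fewer than two
valid criteria raise a selection error. This implements the published
one-sentence description of the consensus rule; no equivalence with any
proprietary toolbox implementation is claimed.

Group-level identification pools the individual template maps and repeats
the procedure; with a single subject the group set is that subject's
individual set (the pooled problem would be degenerate).

## Fitting and smoothing

Back-fitting is per-frame competitive assignment with a similarity floor
(default 0.50). Zero-power frames get similarity 0 and stay unlabeled.
Smoothing minimizes (1 − sim²) − (λ/2b)·N_m(t) per labeled frame,
synchronously, until a fixed point (or 100 sweeps). The published
parameters are names and values only (half window 3, factor 10); the
functional form is the classic segmentation-smoothing cost with 1 − sim² as
the data term (polarity-safe in both modes) and the λ/2b normalization
keeping the printed λ meaningful across window sizes. Sub-threshold frames
are frozen — they neither change nor attract labels — which is the
conservative reading of applying the floor and smoothing jointly. No
minimum-duration rejection is applied. Metrics are computed on the final
smoothed labels.

## Statistics

- **Segment shuffle.** Run-length encode (unlabeled runs included), permute
  run order uniformly, concatenate. Run-count and run-duration multisets
  per label are preserved exactly by construction; in the concatenated view
  same-label runs landing adjacently merge, which is inherent to the
  procedure (the run list is available to verify conservation).
- **Parcel permutation test.** Observed statistic: unweighted mean parcel
  amplitude over frames labeled by a state (the correlation-weighted
  variant belongs to vertex-level averaging, out of scope). z-scores use
  the permutation sample mean/SD (normal reference), matching the
  z-threshold framing of the protocol; the default criterion |z| ≥ 3.6 is
  kept as a configurable parameter (the two-sided normal quantile of
  0.05/204 is ≈ 3.66; the printed 3.6 is used as given). Zero-SD cells and
  states without labeled frames are flagged undefined, never significant.
- **Coverage contrasts.** Paired t per state; Bonferroni thresholds stored
  as exact fractions (0.05/6, 0.05/204) and only rounded for display.
- **Alpha-change index.** Averaged periodograms over non-overlapping 2-s
  Hann windows (0.5 Hz resolution), channel-averaged over a configurable
  occipital selection; the index is the most prominent negative local
  minimum of the eyes-open minus eyes-closed spectrum in 8–12 Hz, 0 with a
  flag when no negative excursion exists.
- **Evoked statistics.** Detection-rate curves count labeled events per
  epoch-relative frame, with the unlabeled class as row 0 so columns sum to
  the event count. The mismatch statistic is the per-event-normalized
  deviant minus standard mean in-window rate; with equal event counts it
  sums to zero over all classes. MMN peak amplitudes z-score each epoch by
  its 200-ms baseline, rectify, average deviants and deviant-preceding
  standards, and take the most prominent negative in-window local minimum
  of the standard-minus-deviant difference; the direction is exposed as a
  switch because the classic mismatch convention is deviant-minus-standard.
  Window edges convert to frames as [ceil(lo·fs/1000), floor(hi·fs/1000)].
  The lateralization score is right minus left.
- **Cross-modal.** The MEG labeling is permuted, the EEG held fixed; per
  subject z from the permutation SD; group association requires
  subject-mean z > 3, with the unlabeled row/column reported but excluded
  from the decision. GEV correlations use Pearson r with Benjamini–Hochberg
  FDR across all state pairs and a positive-and-significant mask.

## Problem sizes in tests and the acceptance script

Map-recovery and meta-criterion checks run at the stated study conditions
(K = 6, 240 s at 250 Hz, SNR 10, 20 seeded runs, 3000 peak maps, 10
restarts). Null-calibration checks use 120-s segmentations with 1000
permutations per seed (pooled over seeds) and 60-s paired recordings for
the co-occurrence null — sizes chosen so that permutation SDs are estimated
to a few percent while the whole suite remains desk-scale. Orchestrator
tests run smaller recipes (tens of seconds of data) because they verify
wiring and determinism, not statistical power.

## Known limitations

- The artifact-rejection statistic (per-channel z, channel-summed,
  epoch max) is a documented simplification of toolbox z-value routines;
  equivalence with any specific tool is not claimed.
- Published cohort-level numbers (six microstates on real cohorts, ~12%
  coverages, 87.4 ms mean duration, specific τ_b and t values) depend on
  request-only raw data and are out of reach of a synthetic harness; the
  package instead verifies the analytically forced constants, calibration,
  conservation laws, and parameter recovery under known ground truth.
- EEG fitting is polarity-invariant only; polarity-strict variants and
  per-frequency-band fitting are not implemented.
- No forward/inverse modelling: parcel-level series are consumed (and
  synthesized), never estimated from sensors.
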