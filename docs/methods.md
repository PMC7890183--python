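# Methods

This package replicates, end to end on synthetic data, an analysis of
balance-skill transfer in older adults: behavioral outcomes from
center-of-pressure (COP) posturography, cortical network reorganization
from EEG phase synchronization summarized by minimum-spanning-tree (MST)
graph measures, and paired multivariate statistics comparing pre- vs
post-training sessions. This note documents the models, the tunable
parameters, the synthetic ground truth, and the numerical choices.

## Posturography

COP (and stabilometer plate-angle) series are conditioned with a 4th-order
Butterworth low-pass at 6 Hz. The filter is applied forward–backward
(zero phase): the convention in posturography, since phase distortion of
slow sway would bias time-domain metrics. DC gain is exactly 1, so stance
offset survives filtering and is removed only where a metric demands it.

Per-trial outcomes:

- **RMS sway** (cm) — RMS of the mean-removed series. Demeaning is
  deliberate: "sway amplitude" measures dispersion, while the offset
  reflects foot placement.
- **95% confidence-ellipse area** (cm²) — under a stationary bivariate
  Gaussian sway model, `CEA = π · χ²₂(0.95) · √det S` with S the AP/ML
  sample covariance and χ²₂(0.95) = 5.991. A degenerate covariance
  returns area 0 with a warning.
- **Mean frequency** (Hz) — power-weighted centroid of the Welch spectrum
  (Hanning taper, 15 s windows, 25 % overlap) over (0, 6] Hz with DC
  excluded. Segments are zero-padded to a 0.02 Hz bin spacing; a 15 s
  window alone would only give ≈ 0.067 Hz.
- **Sample entropy** — `−log(ΣA/ΣB)` with template length m = 2,
  tolerance r = 20 % of the SD of the analyzed series, Chebyshev
  distance, self-matches excluded, both A (length m+1) and B (length m)
  counted over the first N−m template start points. The series is first
  decimated to 100 Hz through an anti-aliasing filter (plain subsampling
  would alias high-frequency noise into the template counts). Pair
  counting uses KD-trees under the max-metric; because Chebyshev
  distances involve no accumulation, the counts are bit-identical to a
  naive O(N²) double loop. ΣA = 0 raises a dedicated
  `UndefinedEntropyError`, distinct from parameter errors.
- **Task error** (degrees) — RMS of the plate-minus-target mismatch over
  seconds 3–42 of a 45 s stabilometer trial, *without* demeaning (a
  constant offset from the target is real error). Practice-round errors
  are standardized to percent of round 1.

Per-subject values are means over the three trials of a session.

## EEG preprocessing

Fixed stage order: broadband filter → EOG regression → epoching →
artifact rejection → sub-band filtering.

- **Broadband filter**: zero-phase FIR band-pass 1–60 Hz. The kernel is a
  Kaiser-window design whose low-frequency transition spans half an
  octave below the 1 Hz edge at ≥ 65 dB, i.e. ≥ 60 dB one octave down;
  it is applied in a single pass with the symmetric kernel's group delay
  compensated (FFT convolution), which is exactly zero-phase.
- **Ocular correction**: bipolar VEOG (supra − infraorbital) and HEOG
  (right − left canthus) derivations, then per-channel OLS of the EEG on
  (VEOG, HEOG, intercept); the fitted ocular part is subtracted and the
  coefficients are reported. Near-collinear EOG regressors (|r| > 0.999)
  warn and fall back to the least-norm fit.
- **Epoching**: contiguous, non-overlapping 2 s epochs by exact sample
  arithmetic, after discarding the first 2 s of each run; a partial tail
  is dropped.
- **Artifact rejection**: an epoch is dropped iff any scalp channel
  exceeds ±100 µV (configurable). The amplitude criterion is the
  standard automated rule; visual inspection is out of scope. Rejection
  reasons are recorded per epoch; rejecting everything is an error that
  names the threshold.
- **Sub-bands**: theta 4–8, alpha 8–13, beta 13–20 Hz, 4th-order
  Butterworth applied forward–backward per epoch with 0.5 s reflection
  padding (2 s epochs are short relative to a theta period; padding
  bounds the filter transient). Content below 4 and above 20 Hz is not
  analyzed.

Linked-mastoid referencing is assumed already applied to the input.

## Connectivity

Instantaneous phases come from the analytic signal (Hilbert transform)
of each band-limited epoch; the first and last 10 % of samples are
excluded from all expectations to bound edge transients. The phase-lag
index is `PLI = |E{sgn Δφ}|` with Δφ wrapped to (−π, π]. The weighted
PLI defaults to the imaginary-cross-spectrum estimator

    wPLI = |E{Im Z}| / E{|Im Z|},   Z = z_x · conj(z_y),

which weights each sample by amplitude × |sin Δφ|, maximal at ±90°
lags and insensitive to zero-lag (volume-conducted) mixtures. A purely
phase-based variant `|E{Δφ}| / E{|Δφ|}` is available as
`wpli_variant="phase-lag"` for sensitivity analysis. A denominator below
machine tolerance (an exactly zero-lag pair) is defined as 0 — the
"no phase synchronization" convention. Both indices live in [0, 1], are
invariant to (positive) amplitude rescaling and to swapping the inputs.

A caveat the tests make explicit: per-epoch wPLI is an absolute-value
statistic with a positive finite-sample floor of order 1/√n_eff (≈ 0.3
for an alpha-band 2 s epoch). Averaging over epochs does not remove the
bias; only longer epochs do. Group comparisons are unaffected because
the floor is common to both sessions.

## MST metrics

The "minimum spanning tree" of a synchrony matrix follows the field
convention of keeping the *strongest* connections: Kruskal on descending
weight (equivalently the MST of 1 − w), with deterministic lexicographic
(i, j) tie-breaking and exact float comparison. NaN entries (degenerate
channels) are treated as weight 0; if the positive-weight graph is
disconnected, zero edges complete the tree under a warning.

Four topology-only measures, normalized into [0, 1] (normalization is
configurable off):

| metric | definition | normalizer |
| --- | --- | --- |
| diameter | longest path, in edges | N − 1 |
| leaf fraction | number of degree-1 nodes | N − 1 |
| avg. eccentricity | mean longest distance per node | N − 1 |
| BC_max | max betweenness centrality | (N−1)(N−2)/2 |

A star is maximally integrated (leaf fraction = BC_max = 1, small
diameter/eccentricity); a path is maximally dispersed. Metrics are
averaged over the epochs of a trial first, then over trials — with
unequal epoch counts this differs from the pooled mean, and the nesting
order is asserted by test. The normalization constants place 30-channel
values on the scale of published group tables (edge-count diameters near
10 of 29 ↦ ≈ 0.34) but cannot be cross-checked against the original
recordings, which were never released.

## Statistics

All comparisons are within-subject (pre vs post), per group:

- paired t (two-sided) on the differences; a zero-variance nonzero shift
  is reported as an infinite statistic with p = 0.
- one-sample Hotelling T² on the difference vectors:
  `T² = n · d̄' S⁻¹ d̄`, `F = (n−p)/(p(n−1)) · T²` on (p, n−p) df, with
  Wilks' Λ = (1 + T²/(n−1))⁻¹. Requires n > p and a nonsingular
  difference covariance; an exactly-zero difference matrix returns
  T² = 0, Λ = 1, p = 1.
- Simes post-hoc within each Hotelling family: reject H₍ᵢ₎ iff
  p₍ᵢ₎ ≤ i·α/m over the ordered p-values. Exact level α under
  independence — verified empirically at 0.050 over 10⁵ null replicates.

Families mirror the study layout: (RMS, MF, SampEn) per COP direction,
a separate paired t on CEA, and per MST metric the (theta, alpha, beta)
triple.

## Synthetic ground truth

The original recordings are unavailable, so every stage is validated
against generators with known truth:

- **Coupled EEG** — narrowband sources are band-passed Gaussian noise;
  a lagged partner is the analytic signal rotated by the requested phase
  lag, which pins the phase difference exactly at band center. Partial
  coupling c mixes the lagged copy with an independent narrowband
  process as `c·lagged + √(1−c²)·independent`, giving zero-mean phase
  jitter that grows continuously as c falls; wPLI recovery is monotone
  in c (rank correlation 1.0 over a strength grid). A channels × sources
  mixing matrix adds instantaneous common sources (volume-conduction
  surrogate): such pairs show high amplitude correlation but wPLI near
  the finite-sample floor. Sensor noise is set by an SNR in dB.
  `source_mode="shared-first-node"` makes all pairs of one hub reuse a
  single rhythm — spokes are then mutually zero-lagged, and the wPLI
  skeleton is a star; the default draws a fresh source per pair, and a
  chain of pairs yields a path-like skeleton.
- **EOG artifacts** — blinks are 200 ms raised-cosine pulses at a Poisson
  rate, saccades 50 ms step-ramps with a plateau; each scalp channel
  receives a known per-channel gain times the true VEOG/HEOG trace, and
  the clean recording is kept so correction error is measurable
  sample-by-sample. Periocular channels split the blink 70/30 between
  supra- and infraorbital sites so the bipolar derivations reproduce the
  true traces exactly.
- **COP trials** — built in the frequency domain with a *deterministic*
  amplitude spectrum and random phases: a Gaussian slow-sway bump plus a
  0.5–5 Hz broadband component whose variance share is
  `0.04·(1 − regularity)`. Deterministic amplitudes make the slow/fast
  power split exact in every draw; a time-domain filtered-noise design
  was tried first and rejected because the ~20 spectral dof of the slow
  band at 60 s let the realized split fluctuate enough to break
  mean-frequency recovery. The bump center is solved (fixed point, 4
  iterations) so the total spectral centroid equals the requested value;
  recovery at 0.3 Hz is 0.302 ± 0.015 Hz over 20 seeds. The two axes are
  demeaned, Gram-Schmidt decorrelated within each spectral class (mixing
  same-class signals leaves the class unchanged) and colored by the
  eigen square root of the target covariance, so the sample covariance
  equals the specification exactly and the analytic ellipse area
  π·5.991·√det is recovered. Higher `regularity` lowers SampEn
  monotonically (0.134 → 0.068 from 0 to 0.9 at unit variance).
- **Null p-values** — i.i.d. Uniform(0,1) matrices for multiple-testing
  calibration.

What the generators do *not* emulate: biophysical head geometry and
dipole forward solutions, 1/f background spectra, nonstationary
vigilance drift, heavy-tailed artifact distributions, and real
inter-subject covariance structure. Passing tests therefore demonstrate
that the estimators recover known structure under the stated models, not
that the physiological effect sizes of any particular cohort would be
reproduced.

## Cohort simulation and seeding

A `StudyConfig` holds every tunable with the analysis defaults above and
the synthetic-cohort ground truth: two groups (SV, control) of 16
subjects, 3 trials per session, 60 s trials at 1 kHz, 30 channels.
Per-subject baselines (sway covariance, centroid, regularity, coupling
strength) are drawn from `SeedSequence([master, group, subject])` so pre
and post share each subject's baseline — the pairing the statistics rely
on — while each trial's noise comes from
`SeedSequence([master, group, subject, session, trial])`. Identical
config + seed therefore reproduces byte-identical output tables. The
pre→post shifts default to the direction of the published group effects
(control: AP sway down ~7 %, centroid up ~14 %, regularity down;
SV: sway unchanged, centroid up ~25 %; control connectomes shift from
chain to hub coupling) without asserting their magnitudes.

Test and acceptance runs scale the cohorts down (5-subject groups, 30 s
COP at 100 Hz, 6–8 channels at 250 Hz, 10–12 s EEG trials, 20 cohorts of
4 subjects for the integration-direction check) — chosen as the smallest
sizes at which every qualitative claim is stable across seeds.
Calibration checks run at full statistical size: 10⁵ Simes replicates,
10⁴ Hotelling null replicates (n = 16, p = 3), 600 s CEA recovery.

## Known limitations

- The artifact-rejection criterion and the epoched fraction of each run
  are not constrained by the source description; both are config-exposed.
- MST metric normalizations reproduce published value ranges but are not
  verifiable against the original toolbox output.
- The paper-literal wPLI variant is provided for sensitivity only; all
  defaults use the cited cross-spectrum estimator.
- EDF export is 16-bit with a single 1 s record size and requires an
  integer sampling rate.
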