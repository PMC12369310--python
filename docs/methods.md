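# Methods

## Data model and conventions

All times are seconds; window parameters are milliseconds relative to the
spike trigger and are converted at use sites.  Trials are half-open
intervals `[stim_on, stim_off)`; the sample index of time `t` at rate `fs`
is `floor((t − t0)·fs)`.  SpTA windows are endpoint-inclusive at 1 ms
resolution, so the −30…+50 ms window has exactly 81 samples.  Percentiles
use linear interpolation between order statistics (numpy's default), both
in the implementation and in every test oracle.  Across-condition
comparisons run only for units with enough usable spikes in both
conditions.

## EMG conditioning

Raw bipolar EMG is resampled to 1 kHz by polyphase filtering with an
anti-alias FIR cutting at 0.45× the target rate, then high-pass filtered
(50th-order FIR, 50 Hz, nudged to an exact null at DC), rectified, and
low-pass filtered (50th-order FIR, 20 Hz).  Filters are applied
forward-backward (zero phase): a causal 50th-order filter at 1 kHz has a
~25 ms group delay, which would shift post-spike latencies out of the
3–16 ms test window.  "Variance normalized" is interpreted as
divide-by-SD without mean subtraction, since mean subtraction would break
the non-negativity the factorization requires.

Signals that are already envelopes (the simulator's output domain) skip
the filter stage entirely: a 51-tap 20 Hz low-pass at 1 kHz attenuates a
5 ms (10 ms) FWHM post-spike transient to 0.17× (0.33×) of its peak, so
re-filtering envelope-domain data would destroy the very feature the SpTA
measures.  Percentage increments are invariant to per-channel scaling, so
the envelope-domain chain (artifact replacement + variance normalization)
leaves muscle fields essentially unchanged.

Motion-artifact screening, done visually in typical experiments, needs a
deterministic surrogate here.  Thresholding raw amplitude at 8 channel-SDs
flags genuine spike-locked EMG peaks on strongly driven muscles (they
reach that amplitude), so detection instead thresholds the residual from a
5 ms running median at 8 residual-SDs, dilated ±5 ms: sharp isolated
deflections are caught, smooth physiological transients are not.  Flagged
samples are replaced by the channel's 99.9th percentile computed over
unflagged samples; a mask covering more than half a channel is rejected.

## Spike-triggered averaging

The increment procedure: find the trace maximum within 3–16 ms
post-trigger (ties broken toward the earlier latency), grow a contiguous
region in both directions while the trace stays strictly above
baseline mean + 2·baseline SD (baseline −30…−10 ms), and report
`100·(region mean − baseline mean)/baseline mean`.  A peak at or below
threshold gives increment 0 and no significant effect.  Onset latency is
the earliest sample of that region (it may precede the trigger); PWHM is
measured at baseline + half the peak elevation with linear interpolation
at the crossings, clipped at the window edge when a flank never crosses.
Negative (suppression) increments are recorded but clamped to zero in the
muscle field, which is matched against non-negative synergies.

Significance uses circular-shift surrogates: the whole spike train is
shifted by uniform random offsets (segments gathered with circular
indexing so observed and surrogate statistics are exchangeable), and the
observed test-window peak elevation must exceed the surrogates' 97.5th
percentile.  On null units (no spike-locked kernel, stimulus-unlocked
firing) the empirical rate is ~1–3% at a nominal 2.5%, slightly
conservative.

## Synergy extraction

`D [muscles × samples] ≈ W Cᵀ` with `W ≥ 0 [muscles × N]`,
`C ≥ 0 [samples × N]`.  Each model order is fitted from 100 random
initializations with entries uniform on (0, max D), multiplicative
updates under the Frobenius/SSE objective (the same loss `R²` is defined
with), tolerance 1e-6 or 1000 iterations; the restart with the lowest SSE
wins.  `R² = 1 − SSE/SST`, SST taken around each muscle's mean.  The
model order is the smallest N whose best-of-restarts R² reaches 0.80.
Reported W columns are L2-normalized with the scale moved into C (a gauge
choice; reconstruction and R² are unchanged).  Extraction runs per
condition on the concatenated response windows (stimulation onset to
offset + 100 ms — motor responses outlast the 200 ms train; the margin is
configurable and reused identically for firing rates so the two
quantities are comparable).

## Matching, clustering, modification taxonomy

Similarity between non-negative muscle-space vectors is the scalar
product after L2 normalization (no centering).  Preferred-synergy ties go
to the lowest index.  Across-condition matching maximizes the total
scalar product via the Hungarian algorithm; with unequal set sizes the
smaller set is fully assigned.  k-means (50 seeded restarts per k) runs
for k = 2…10 capped at n−1; the selected k is the first local maximum of
mean silhouette in ascending k (a global-max reading would make "first"
redundant); the full silhouette curve is stored so either convention is
auditable.

The modification classifier evaluates merging first, then preserved, then
unmatched.  Merging requires the NNLS reconstruction of the target
preferred synergy from all source synergies to (a) resemble the target at
scalar product ≥ 0.8, (b) have ≥ 2 contributors with coefficient > 0.2,
and (c) include the unit's own source-preferred synergy among the
contributors.  The 0.8 reconstruction threshold is the package's
completion of an under-specified rule: the coefficient rule (0.2) and the
preserved/unmatched split (0.8) are established, but no
reconstruction-goodness bound is, so the same 0.8 similarity bound is
reused and exposed in the configuration (`merge_reconstruction_sp`).
NNLS runs on L2-normalized target and sources and the coefficients are
compared to 0.2 as-is.

## Rate–coefficient correlation

Per locus, the firing rate is the across-trial mean of spike count over
the response window divided by its duration; coefficient amplitude is the
across-trial mean of the time-averaged activation coefficient over the
same window.  Pearson correlations are taken across loci; signed r is
stored, the absolute value is used only where selection demands it
(`C_corres`, `C_prefer`).  The pooled regression is ordinary least
squares of amplitude on rate over all valid unit-locus points, reporting
slope, R², and the slope's t-test p-value.

## The synthetic generator

The generator defines what the analysis should recover:

* **Synergies.** Muscles are partitioned across N = 3 planted synergies;
  each column has one dominant muscle (0.8–1.0 before normalization),
  moderate weights (0.3–0.5) on its other group members, and weak
  participation elsewhere, re-sampled until pairwise scalar products are
  ≤ 0.6 and every muscle carries weight > 0.25 somewhere.  The
  dominant/secondary contrast matters: with equally strong group members,
  every non-negative vector is explainable by a synergy mixture at
  sp ≥ ~0.7 and genuinely "unmatched" fields cannot exist.
* **Activations.** Each trial contributes one smooth bump (sin², 300 ms)
  per synergy, scaled by a smooth per-locus Gaussian tuning profile
  (floor 0.02), the trial's laser power, and a per-trial lognormal-like
  jitter (CV 0.3).  The jitter and low floor are what make the three
  activation series linearly independent; without them the factorization
  is rank-deficient and non-identifiable.
* **Spiking.** Inhomogeneous Poisson with a 1 ms dead time: background
  10 Hz, 80 Hz × the unit's locus gain during the 200 ms train.  The
  unit's gain profile equals its preferred synergy's locus tuning, which
  is what the rate–coefficient stage should detect.
* **Post-spike kernels.** Raised cosine `0.5(1+cos(π(t−L)/T))` with peak
  latency L = 8 ms and FWHM T exactly the configured PWHM (5 ms for
  pure-type units, 10 ms for synchrony-type), scaled by amplitude 1.5 and
  the unit's condition-dependent field direction.
* **Rewiring.** Per unit and condition, the field is preserved, merged
  (coefficients ≥ 0.3 on ≥ 2 synergies including its own; merging
  dominant under SSAT), or replaced by a fresh pattern rejected until no
  NNLS mixture of planted synergies reaches sp 0.6 (dominant under CoST).
* **Background.** A tonic level of 0.5 gives the SpTA a positive baseline
  (percentage increments require one); Gaussian noise (SD 0.1) is added
  and the signal clamped at zero.  Optional isolated artifact spikes
  (10× channel SD, 0.1% of samples) exercise artifact replacement.

Amplitudes were fixed once by pilot runs so that recovery is achievable
but not trivial: the kernel (1.5) must stand above the stimulus-locked
envelope drift — with stimulus-locked firing, E[envelope | spike] rises
through the SpTA window, a genuine synchrony-type confound the generator
deliberately reproduces.  That drift is also why validation experiments
that probe kernel shape (pure/synchrony classification, significance
calibration) use stimulus-unlocked firing: with locked firing even
narrow-kernel units carry a real early-onset synchrony component and the
classifier is *correct* to call them synchrony (as anaesthetized
preparations overwhelmingly are).

What the generator does not emulate: raw motor-unit interference patterns
(EMG is produced directly in the post-rectification envelope domain; the
filter chain is validated separately on synthetic carrier bursts),
conduction-delay anatomy, inhibitory fields (everything is non-negative),
and cross-animal variability in muscle geometry.  Passing tests therefore
demonstrate correctness of the analysis machinery under the assumed
generative structure, not robustness to every property of real EMG.

## Validation experiments and problem sizes

The validation suite (`synergy_state.evaluation`, exercised by the test
suite and `scripts/acceptance.py`) uses study-scale protocol parameters
(13 loci × 5 trials, 200 ms trains, 1000 ms intertrial) with single-animal
recordings, chosen to keep each experiment in the seconds-to-minute
range: 20 units for field recovery (500 spikes each), 40 for effect
classification, 200 nulls × 200 shuffles for significance calibration,
one 100-restart factorization for model-order selection (its planted-
synergy dataset drops the tonic background, which would otherwise demand
a fourth component for an exact fit, and scores recovery in the
variance-normalized coordinates the factorization actually sees), 50
units for modification classification (target fields perturbed by the
generator's noise SD), and 30 units for rate–coefficient recovery.

## Known limitations

* Muscle-field recovery is bounded by the stimulus-locked drift: a
  minority of units (typically ≤ 10%) recover at sp 0.8–0.9 rather than
  ≥ 0.95.  Percentage increments also divide by per-muscle baselines, so
  fields are recovered up to a mild per-muscle distortion ∝ 1/mean.
* The significance test is mildly conservative (~1–3% empirical rate at
  nominal 2.5%).
* On full-pipeline synthetic runs, "unmatched" rewiring is rarely
  recovered end-to-end: the EMG of the target condition is still composed
  of the planted synergies, so the extracted target synergy set does not
  contain the fresh field and the classifier sees a merging-like or
  preserved pattern instead.  The classifier itself is validated directly
  on planted constructions, where it is exact in the noiseless case.
* PWHM is clipped at the window edge when a broad effect never crosses
  half-maximum inside −30…+50 ms, biasing extreme widths downward.
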