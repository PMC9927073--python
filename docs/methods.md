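# Methods

This note documents the models, defaults and numerical choices behind
`abrsig`, and what the synthetic-cohort tests do and do not establish about
real ABR data.

## Micro-movement spike (MMS) normalization

A trial's waveform `x(t)` (µV, sampled uniformly over a −2…+12 ms epoch
around stimulus onset) is first rectified as absolute deviations from its
own empirical mean, `v(t) = |x(t) − x̄|`.  The mean is per-trial, not
per-session, because the fluctuation statistics are nonstationary across a
session.  Each strict local maximum of `v`, flanked by its nearest local
minima (series endpoints act as minima sentinels), is normalized as

    MMS = Peak / (Peak + A),

with `A` the arithmetic mean of *all* samples from the left flanking
minimum to the right flanking minimum, inclusive of the peak itself.
Consequences worth stating:

* `MMS ∈ [0, 1]` always, and `MMS < 1` strictly, because `A` includes the
  peak sample; an isolated impulse on a widening zero background approaches
  1 in the limit.
* MMS is exactly invariant under `x → c·x`, `c > 0` (both numerator and
  denominator scale by `c`), which is the precise sense in which the
  normalization scales out allometric amplitude differences.
* Degenerate flat peaks (`Peak + A = 0`) are skipped with a warning.
* Amplitude ties between neighbouring samples resolve to the earliest
  sample (latency-conservative, deterministic).

Whether deviations or the raw rectified waveform are normalized is exposed
as a switch (`rectify="deviations" | "absolute"`); deviations are the
default.

## Peak detection, featurization and labelling

Peak detection uses topographic prominence and width at half prominence
(scipy's `find_peaks` machinery) on the series at hand.  For *labelling*
peaks I–VII on raw waveforms, the waveform is first lightly smoothed with a
Gaussian kernel (default σ = 0.08 ms): evoked ABR peaks are a few tenths of
a millisecond wide while acquisition noise is broadband, so smoothing
suppresses spurious local maxima without displacing symmetric evoked peaks.
Candidates above a prominence floor (default 0.04 µV, chosen above the
prominence ceiling of smoothed baseline noise at the default noise level)
and inside the physiological 0.8–9.5 ms range are labelled **sequentially**:
the seven most prominent candidates, sorted by time, receive labels I–VII.
Sequential labelling tolerates global and group-specific latency shifts
that fixed windows cannot (a shared IV/V window boundary cannot separate a
delayed group's peak IV from an undelayed group's peak V).  When fewer than
seven candidates survive — typically peak IV merged into dominant peak V's
flank — the missing label is inferred by least-squares matching of
candidate times to a canonical latency template with a free common shift,
and the remaining peaks are still labelled.  Window-based assignment (most
prominent candidate per non-overlapping latency window) remains available
as `label_mode="windows"`.

A merged peak is unmeasurable, so its trial is missing for that label; this
truncates the label's latency sample slightly (the draws closest to the
dominant neighbour are lost).  Under default conditions this residual bias
is ~0.02–0.03 ms for peak IV and negligible elsewhere.

## Stochastic signatures

Candidate families are Gamma, lognormal, normal, Weibull and exponential;
positive-support families are fitted with location fixed at 0 (latencies
and MMS are positive by construction).  Selection is by raw maximum
log-likelihood, not AIC/BIC; the exponential's one-parameter disadvantage
under that rule is accepted, and ties break by the fixed candidate order.
A minimum of 100 samples per signature is enforced (high-confidence
estimation), overridable with `allow_small` for toy data.

Gamma 95% CIs use the asymptotic observed-information method: the inverse
per-observation Fisher information

    I(a, b) = [[ψ′(a), 1/b], [1/b, a/b²]]

divided by n, mapped to (log a, log b) by the delta method, with normal
quantiles exponentiated back.  This keeps CIs positive and contains the
point estimate by construction.  Calibration is verified by simulation: at
n = 500 the shape CI covers the truth ~94–96% of the time.  Moments are
closed forms of the estimates (mean a·b, variance a·b², skewness 2/√a).

Log–log signature scatters are fitted by OLS of log₁₀(scale) on
log₁₀(shape); per-point "deltas" are the absolute vertical residuals.  A
vertical scatter (all shapes identical) is rejected rather than fitted.

## Nonparametric comparisons

* **EMD** is the 1-Wasserstein distance — in one dimension, the area
  between empirical CDFs.  The sample-based (binless) path is the default;
  histogram inputs are compared via bin centers weighted by frequencies,
  with Freedman–Diaconis binning on pooled samples when the package builds
  the histograms.  Matrix entries are normalized by the maximum entry
  (an all-zero matrix is returned unchanged).
* **Bootstrap KS** for unequal group sizes draws the smaller set's size
  from the larger set 100 times and reports the median two-sided
  two-sample-KS p.  Draws are *without* replacement by default
  (subsampling keeps the two samples exchangeable under the null; a flag
  enables with-replacement).  Samples are canonically sorted before seeded
  drawing, so results are independent of input element order.  The
  median-of-p statistic is conservative: under the null its rejection rate
  at 0.05 is well below 0.05.  Equal-size inputs fall back to a single
  plain KS test.
* **Rank-sum** comparisons use the two-sided Wilcoxon rank-sum
  (Mann–Whitney) test, exact for small untied samples and
  continuity-corrected asymptotic otherwise.
* Lower-triangular matrices carry the pairwise values; p-value metrics are
  star-coded `**` (p < 0.01) / `*` (p < 0.05), exactly consistent with the
  stored p values.  No multiple-testing correction is applied across cells.

## Trajectory statistics

* **Curve length** is Σ|x[i+1] − x[i]| over a trial.  The *unsigned* sum
  telescopes to (end − start) and carries no variability information, so
  absolute first differences are used; the statistic is then
  shift-invariant and scales linearly with amplitude.
* **Interaural difference** is |right − left| of each subject's minimum
  peak V latency per ear (per-trial pairing is configurable).
* **Weekly cross sections** take, per (group, postnatal week), the median
  across subjects of each subject's minimum peak V latency; the
  within-subject minimum is taken first, so duplicating trials cannot move
  the median.  Empty cells are missing, never zero.
* **Growth law** `BW = α·exp(β·EGA)` is fitted by least squares of
  log(BW) on EGA (log-linear, not nonlinear least squares); α = exp of the
  intercept, σ is the residual sd on the log scale.

## Synthetic cohort generator

The generator produces the study conditions the analysis is tested under;
its defaults are fixed once:

| parameter | default | rationale |
| --- | --- | --- |
| subjects | 20 + 20 (ASD-like / non-ASD-like) | two-group neonatal cohort at desk scale |
| trials | 3 dB levels (70/75/80) × 2 ears × 2 trials | ≥ 100 latency samples per (group, peak) cell |
| sampling | 25 kHz, epoch −2…+12 ms | neonatal acquisition convention |
| non-ASD latency means (ms) | 1.6, 2.7, 3.8, 4.9, 5.6, 6.6, 7.6 | canonical neonatal I–VII landmarks |
| ASD-like delay (ms) | +0.20, 0.25, 0.05, 0.30, 0.25, 0.29, 0.40 | sums to 1.74; largest at VII, smallest at III |
| latency sd | 0.15 ms; ASD-like ×0.5 | trial-scale jitter; narrowed dispersion in the ASD-like group |
| latency law | Gamma with the above mean/sd | positive support; the family the MLE fit should recover |
| peak shape | Gaussian bump, FWHM 0.30 ms | simplest shape with controllable latency/prominence/width |
| amplitudes (µV) | 0.20, 0.25, 0.20, 0.25, 0.50, 0.30, 0.25 | peak V dominant |
| dB scaling | (dB − 60)/10, linear | arbitrary but monotone; only ordering is asserted |
| noise | 0.02 µV white | residual noise of averaging-grade traces |
| allometric scale | lognormal, σ = 0.15, per subject | head-circumference proxy the MMS must scale out |
| BW–EGA | α = 52 g, β = 0.105 /wk, lognormal σ = 0.10, EGA ~ U(24, 41) | ~650 g at 24 wk to ~3.9 kg at 41 wk |
| weekly drift | 0 by default; WBN −0.05 ms/wk in maturation scenarios | default emulates a single-visit neonatal cohort |

Every latent draw is recorded in a truth ledger keyed by
(subject, trial, ear, dB, peak), enabling recovery tests.  A single seed
fully determines the output; the pipeline derives per-stage substreams by
stable hashing (CRC-32) of the stage name, so stage order is irrelevant.

**What the generator does not emulate:** realistic electrode noise spectra,
stimulus-level-dependent latencies, within-subject latency correlations
across trials, artifacts, or missing data.  Passing tests therefore
demonstrate correctness of the *computations* under the assumed statistical
structure, not clinical validity on recorded cohorts.

## Delay summary conventions

"Per-region delay" is the ASD-like minus non-ASD-like difference in fitted
Gamma mean latency; "cumulative delay" is the sum of the seven per-region
delays; "net cumulative latency" per group is the mean peak VII latency —
the arrival time of the response at the last brainstem region.  Both the
cumulative delay and the net-latency difference are reported, since they
answer different questions (summed per-region slippage vs end-to-end
arrival difference) and need not coincide.

## Granularity

Signatures can be pooled per group (all trials of all subjects in a
context cell) or fitted per subject and then summarized; both are
supported via context labels.  The pipeline default pools per group, which
is the granularity at which the ≥100-sample rule is naturally met at desk
scale.

## Known limitations

* Peaks that merge below the detector's resolution are missing, not
  imputed; their labels' latency samples are slightly truncated (see
  above).
* The clinical-deposit adapter is a stub: the deposit's file schema is not
  documented alongside the study, so mapping onto the package's CSV
  schemas is left to the user.
* Bootstrap-KS p-values are conservative; they should be read as ranking
  evidence, not as calibrated error rates.
* The exponential's nested relationship to the Gamma means model selection
  between them at small n can be close; selection frequency (not
  certainty) is the tested property.
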