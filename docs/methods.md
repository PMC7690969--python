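# Methods

This note documents the models and procedures the package implements,
the choices made where the design was genuinely open, and what the
synthetic data do and do not establish.

## Consensus coding and reliability

Each comment carries ≥3 coder labels from the closed five-category
scheme (happiness, sadness, anger, fear, neutral). The consensus is the
*strict plurality*: the single most frequent label. When two or more
labels tie for the top count there is no majority to resolve the
conflict, and the item is marked unresolved rather than assigned by any
priority order among emotions — an imposed order would bias category
shares toward whichever emotion ranked first. Unresolved items are
excluded from the five per-day emotion series and tracked in a residual
series, so per day and overall: Σ(5 categories) + unresolved = total.

Reliability is Fleiss' κ (chosen over Cohen's because raters number ≥3
and need not be the same individuals across items): observed agreement
is the mean over items of pairwise rater agreement, expected agreement
the sum of squared marginal category proportions. When every rating in
the matrix falls in one category, chance agreement is 1 and κ is
undefined; the package raises an explicit degenerate-agreement error
instead of propagating NaN. Interpretation uses the Landis–Koch bands.
Items may carry different rater counts ("at least 3"); since Fleiss' κ
needs a constant count, `subsample_raters` deterministically keeps each
item's first k labels (k = the minimum common count) — no resampling, so
results are reproducible.

## Case calibration

Inputs are daily records of nucleic-acid-confirmed and clinically
diagnosed counts. Given a change date (the first day whose reporting
includes clinical diagnoses at the steady ratio) and one or more ratio
days on/after it, the per-day ratios ρ_d = clinical_d / nucleic_d are
averaged *unrounded* (rounding each ratio to 2 dp before averaging would
discard information for no reason; the displayed 2-dp values are a
presentation concern). Every day strictly before the change date is
replaced by nucleic × (1 + mean ρ); days on/after pass through as
reported, which also removes the two-day backlog spike from the
pre-change segment. The two dump days themselves are passed through
unchanged by default; calibrated values stay real-valued for downstream
correlation (an integer option rounds half-to-even).

The multiplier is stored as 1 + mean ρ and the mean ratio derived from
it, so the invariant multiplier = 1 + mean_ratio holds exactly in
floating point.

## Series construction

All count series are gap-free daily vectors; days with no events are 0,
not missing. Sources with different windows are trimmed to their date
intersection — the only resolution that needs no imputation. Category
shares are 100·count/total rounded half-up at display precision (1 dp
for rumor categories, 2 dp for comment emotions). Before correlation,
every series is transformed x ↦ ln(x+1): daily counts over an epidemic
window are roughly exponentially distributed, the log stabilizes the
variance, the +1 keeps zero days defined (and maps them to 0), and
Pearson correlation is invariant to the log base, so the choice of
natural log is inconsequential downstream.

## Lagged cross-correlation

r(k) = corr(x_{t+k}, y_t) over the n−|k| overlapping days, for
k = −K..K (K = 10 by default). The sign convention — positive k means x
follows y — is fixed algebraically and documented everywhere, since
verbal lead/lag statements are ambiguous. p-values are two-sided t tests
with n−|k|−2 degrees of freedom (via `scipy.stats.pearsonr`); a
zero-variance window raises an explicit undefined-correlation error at
that lag (a silent r = 0 would be wrong), and a scan where *every* lag
is undefined raises. The 95% envelope is the large-sample white-noise
band z₀.₉₇₅/√(n−|k|) per lag; no formula beyond this approximation is
claimed for it. The peak is the maximum |r| among lags with p < α
(α = .05 default, uncorrected across the 21 lags to match the original
threshold; Bonferroni available but off). Using |r| surfaces negative
peaks with their sign. Ties break toward the smallest |lag| (most
parsimonious lead/lag), then toward the negative lag — documented,
arbitrary. The reported peak p is the per-lag p; peak selection inflates
it, which the summary does not correct for.

The standard comparison set is 10 pairs: the two regional case series
vs total rumors, each of the 4 emotions vs total rumors, and each
emotion vs same-emotion rumors.

## Synthetic generator

The generator emulates the structure of the non-deposited source
streams; its defaults are documented constants chosen to echo the
published setting, not estimates from any dataset.

* **Epidemic**: latent mean grows exponentially (rate 0.22/day from 60
  cases) to a peak on day 17, then decays (0.07/day), over 50 days from
  2020-01-20. Counts are gamma-mixed Poisson (negative binomial) with
  extra-Poisson CV `noise_scale` = 0.15; `noise_scale = 0` keeps the
  latent expectations as reals, which is what makes the noise-free
  recovery identities exact to double precision (integer rounding would
  break them at the last ulp). Clinical cases arise daily at the true
  ratio 0.91 of nucleic counts; before the shock day (23) they are
  withheld from the reported totals, and the accumulated backlog is
  released 0.8/0.2 over the shock day and the next — mirroring a two-day
  clearance — so total reported equals total true cases. A second
  region at 0.6 scale has no clinical component and no shock.
* **Comments**: daily volume is negative binomial (dispersion 6,
  heavy-tailed) around 20,000/day — about one million over the window,
  the scale at which full runs stay cheap; shares, not totals, drive
  the analysis. Each comment's latent label follows the day's category
  mix: base probabilities (0.0141, 0.0127, 0.0482, 0.0135, 0.9115) with
  gain 0.15 · ln(1+national cases) added to the anger and fear log-odds
  (a tilt on odds keeps probabilities valid for any gain). These
  constants were solved so the window-averaged shares reproduce the
  observed ordering and magnitudes (neutral ≈ 81%, anger ≈ 13% > fear
  ≈ 3.6% > happiness ≈ 1.25% ≈ sadness ≈ 1.13%). Each of the 3 coders
  reports the true label with probability 0.955, else one of the other
  four uniformly; 0.955 was solved analytically so Fleiss' κ under the
  default mixture is ≈ 0.77 ("substantial"), and full runs land there
  (κ ≈ 0.766–0.769).
* **Rumors**: the standardized log negative-emotion count, shifted by
  `rumor_lag_days` (positive: rumors lead emotions; the scan of
  (emotion, rumors) then peaks at +lag), is mixed with independent
  Gaussian noise with weight ρ, exponentiated into a log-normal
  intensity (sd 0.7) around 5.5 rumors/day, and Poisson-sampled.
  Poisson sampling attenuates the latent correlation on the log1p
  scale; ρ is boosted by the analytic factor √(s² + m/(1+m)²)/s
  (conditional log1p-Poisson variance ≈ m/(1+m)²) so the realized
  cross-correlation at the injected lag approximates the configured
  strength (measured: ≈ 0.54 realized for a target of 0.6 — the
  approximation undershoots slightly, which recovery tests absorb).
  Edge days outside the shift window fall back to pure noise
  (edge-held index). Tags are i.i.d. from a neutral-modal mix.

All randomness flows from one seed through fixed per-stage substreams
(`SeedSequence(seed, spawn_key=(stage,))`), so adding a stage never
perturbs earlier stages' draws, and identical configs give bit-identical
outputs.

### What the synthetic data do not show

The generator couples rumors to emotions through a single lagged linear
channel with stationary mixing weights; real streams have breaking-news
bursts, platform moderation, weekday effects, and feedback from rumors
to emotions, none of which are modelled. Comment counts carry no text.
Passing recovery tests therefore shows the *pipeline* is correct and
well-calibrated — not that the original correlation estimates would
replicate on re-collected data.

## Monte-Carlo validation

Since the source streams are not deposited, the inferential step is
validated by parameter recovery at a study-like scale: coupling strength
0.6 injected at each lag in −3..+3 over 200-day windows, 200 replicates
per lag (the scan recovers the injected lag in ~100% of replicates;
the requirement is ≥95%), and zero-strength worlds in which |r| at the
single pre-stated lag must stay inside the per-lag 95% envelope in ≥90%
of replicates (measured ≈ 93–97%). The rate of *no spurious peak at any
of the 21 lags* is also reported (~55–60%): with 21 uncorrected tests
per scan the family-wise rate is necessarily inflated — the per-lag
envelope makes a per-lag claim, not a family-wise one — and correcting
it is deliberately left off by default to match the original threshold.

Problem sizes throughout (50-day default windows, 200-day recovery
windows, 200 replicates per condition, 1000 oracle instances) are the
package's own choice of a scale at which Monte-Carlo rates are stable to
a few percent while full runs complete in seconds.

## Known limitations

* Variable per-item coder counts are handled by deterministic
  subsampling to the minimum common count, which discards information
  relative to a mixed-rater agreement model.
* The envelope is a large-sample white-noise approximation; for short,
  strongly autocorrelated series its per-lag coverage is approximate
  (the null experiment measures it at ≈ 93–97% for epidemic-shaped
  nulls).
* The calibration assumes the post-change clinical/nucleic ratio also
  held before the change; that is an identifying assumption, not a
  testable fact, and the pipeline only propagates it.
* Peak p-values are not adjusted for peak selection across lags.
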