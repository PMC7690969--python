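# infodemic

Infoveillance analysis of the relationship between public emotions
expressed in social-media comments and online rumors during an epidemic.

During the early COVID-19 outbreak in China, large volumes of comments
under official news posts were manually coded into five emotion
categories (happiness, sadness, anger, fear, neutral), daily fact-checked
rumor counts were collected, and official daily case counts were
corrected for a mid-series change in diagnosis criteria. The question is
one of lead and lag: do daily emotion counts and rumor counts move
together, and which moves first? This package implements that pipeline as
tested, reusable code — for epidemiologists and computational social
scientists who want to run the same analysis on their own coded streams,
or probe its behaviour on synthetic data with known structure.

## The method

**Consensus coding.** Each comment is labelled by ≥3 coders; the final
category is the strict plurality, with ties kept as an explicit
unresolved residual (never force-assigned). Reliability is Fleiss' κ
over the five categories: κ = (P̄ₒ − P̄ₑ)/(1 − P̄ₑ), with P̄ₒ the mean
pairwise rater agreement per item and P̄ₑ = Σⱼ p̄ⱼ², interpreted on the
Landis–Koch bands (0.61–0.80 "substantial").

**Case calibration.** When a region switches to also counting clinically
diagnosed cases, the accumulated backlog clears over ~2 days (a reporting
spike) and earlier days undercount. With post-change clinical/nucleic
ratios ρ_d, every pre-change day's nucleic-acid count is scaled by
(1 + mean ρ_d); days on/after the change pass through as reported.

**Lagged cross-correlation.** All daily series are log-stabilized,
x ↦ ln(x + 1), then for each pair (x, y) and each integer lag
k ∈ {−10, …, +10}:

    r(k) = corr(x_{t+k}, y_t)   over the n − |k| overlapping days,

with a two-sided t-test p-value (df = n−|k|−2) and the white-noise 95%
envelope ±1.96/√(n−|k|). **Sign convention:** positive k means x
*follows* y by k days; negative k means x leads. The peak is the lag of
maximum |r| among lags with p < .05 (no multiplicity correction across
lags, matching the original threshold; a Bonferroni option exists).

**Synthetic generator.** Because the source streams (comment feeds,
fact-checker rumor lists, official counts) are not redistributable, a
seeded generator produces all three tables with known structure: an
epidemic curve with the criteria-change shock, coder-labelled comments
whose negative-emotion odds rise with log case counts, and rumor counts
coupled to the negative-emotion signal at a configurable lead/lag and
target correlation strength. Every claim the pipeline makes is tested
against this generator's ledger of latent truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on a default
synthetic world (50 days from 2020-01-20, shock on day 23, true clinical
ratio 0.91, ~20k comments/day, rumors coupled to negative emotions at
lag 0 with target strength 0.5):

```bash
python analysis/01_simulate.py
python analysis/02_code_emotions.py
...
python analysis/06_recovery_experiments.py
```

which prints, stage by stage:

```
Coded 875864 comments with 3 coders: kappa=0.769 (substantial), 3791 unresolved ties (0.43%).
Estimated clinical/nucleic ratios 0.88, 0.91 -> mean 0.89, multiplier 1.89.
Reported-series peak 19263 vs calibrated peak 4783: the criteria-change spike is removed.
Comment emotion shares (%): {'happiness': 1.28, 'sadness': 1.18, 'anger': 13.03, 'fear': 3.69, 'neutral': 80.81}
emotion_anger~rumors_total               peak r=+0.46 at lag +0 (p=0.00071)
emotion_fear~rumors_fear                 peak r=+0.34 at lag +1 (p=0.016)
```

Read: the three simulated coders agree substantially (κ≈0.77); the
criteria-change spike is removed by the estimated multiplier (≈1.89 on
this noisy draw; exactly 1.91 in the noise-free limit); anger dominates
the non-neutral comment mix; and the scan finds the injected lag-0
emotion–rumor coupling at r ≈ 0.5 while pairs with no injected coupling
mostly stay inside the envelope. The same pipeline runs from the shell
(`infodemic run --seed 1 --out out/`, or `simulate`/`code`/`calibrate`/
`series`/`ccf` stage by stage) and on your own `comments.csv`,
`rumors.csv`, `cases.csv` via `--mode files`.

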