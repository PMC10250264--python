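# Methods

## The measurement problem

A two-condition RT task scores each participant with a difference of
condition means (here the flanker effect, incongruent − congruent). The
reliability of that difference score across people is limited by trial
noise: with per-trial RT variance `V` and `L` valid trials per condition,
the error variance of the score is about `2V/L`, so reliability is
`ρ(L) = σ_d² / (σ_d² + 2V/L)` where `σ_d²` is the between-person variance of
the true effect. This family is exactly the Spearman–Brown prophecy
formula's, which is why reliability-vs-length curves are fit against it.

## Generative model (`flankrel.synthetic`)

Each participant i has a baseline speed `b_i ~ N(mu_congruent, sd_between²)`
and a true congruency effect `d_i` with mean `mu_effect`, SD `sd_effect`,
and correlation `effect_baseline_corr` with the baseline. A correct trial's
RT is

```
RT = b_i + [incongruent]·d_i − [session 2]·session2_speedup
     + N(0, sigma²) + Exp(tau) + [contaminant]·contaminant_shift
```

with the contaminant indicator Bernoulli(`contaminant_rate`). Responses are
incorrect with a per-condition error rate (incongruent ≥ congruent). Both
sessions share `b_i` and `d_i` — the trait is stable; session 2 is only a
uniform speed-up. Trial order is a seeded uniform shuffle within each block
of the fixed design (8 practice trials balancing direction × condition; two
main blocks each crossing direction × condition × 10 fixation durations
four times, i.e. 160 trials per condition per session).

Defaults (ms): `mu_congruent 450, sd_between 50, mu_effect 40, sd_effect 15,
sigma 80, tau 60, session2_speedup 12, contaminant 1% at +300,
error rates 0.3%/1.0%, effect_baseline_corr 0.9`. These were chosen so the
scored output matches the descriptive profile typical of online flanker
studies: mean correct RTs ≈ 500–560 ms, flanker effect ≈ 30–40 ms
(between-person SD ≈ 15–20 ms), a median 3–5% slow tail per condition caught
by the 3·MAD rule, ≤ 1% errors, and a 0.97–0.98 correlation between
per-participant congruent and incongruent mean RTs. The last of these forced
the positive baseline–effect correlation: with independent `b_i` and `d_i`
the correlation cannot exceed ~0.90 at these variances, while real flanker
data sit near 0.98 (slower participants show larger interference). The
marginal variance of `d_i`, and hence every reliability statement, is
unaffected by that correlation.

Injected high-leverage participants (`n_outlier_participants` with
`outlier_effect_sd_multiplier`) redraw their effect **independently per
session** with inflated SD. Leverage outliers are only interesting when
they are extreme *and* inconsistent — that is the configuration whose
exclusion raises a test–retest ICC, which is what the leverage analysis is
built to detect; stable extreme traits would instead legitimately raise it.

What the generator does **not** emulate: device/browser timing noise,
sequential effects (post-error slowing, congruency sequence effects),
learning or fatigue trends within a session, RT–accuracy trade-offs, and
error-trial RT dynamics (error RTs are drawn from the same distribution as
correct ones and then discarded by scoring). Passing parameter-recovery
tests therefore shows the estimators are correct for a stationary
trait-plus-noise world, not that real flanker data satisfy that model.

## Ground-truth reliability

`true_reliability` returns the population reliability of the *scored*
effect. Two refinements beyond the naive closed form matter:

1. **Effective error variance.** The exclusion pipeline (3·MAD trim of the
   slow tail, 100 ms floor, error removal) changes both the per-trial
   variance and the valid trial count, so `var_e` is measured by a
   deterministic Monte Carlo: thousands of pseudo participant-sessions with
   trait variation switched off are pushed through the actual scoring code
   and the variance of their scores is taken (`effect_error_variance`).
   This includes threshold-estimation noise, which no analytic formula for
   the trimmed ex-Gaussian captures cleanly.
2. **Attenuation.** With the default pooled (per participant-session) MAD
   threshold, a larger true effect pushes more of the incongruent
   distribution above the shared cut and shelters more of the congruent
   tail below it, so the scored effect grows with slope `a < 1` in the true
   effect (≈ 0.88 under default noise; `effect_attenuation` measures it by
   central difference). The reported truth is `a²σ_d² / (a²σ_d² + var_e)`.
   Per-condition thresholds (`ScoringConfig(mad_scope="condition")`) remove
   the attenuation entirely.

Supplying `trial_variance` explicitly bypasses both refinements and gives
the textbook `σ_d² / (σ_d² + 2·trial_variance/L)`.

`with_true_reliability` inverts the relation to set `sd_effect` for a target
reliability at a given length — the basis of the parameter-recovery tests,
which check that mean test–retest ICC and mean permutated SB-adjusted
split-half across 200 replicate datasets (n = 200, 160 trials/condition,
truth 0.60) land within ±0.03 of truth.

## Scoring rules and their open conventions

The slow-trial rule is implemented as `rt − median > 3·MAD` with the
unscaled MAD (no 1.4826 factor), computed once on the pre-exclusion set —
no iterative re-flagging. The literal phrase "RTs greater than three times
the MAD" cannot be meant absolutely (it would exclude every trial), and the
upper-tail deviation reading matches how the companion percentage
("% RT > 3MAD") is reported alongside a separate sub-100 ms count. Two
conventions are genuinely underdetermined and exposed as switches with
these defaults: the MAD pools both conditions of a participant-session
(`mad_scope="session"`; the rule names the individual, not the condition),
and error trials are left out of the threshold-defining set
(`mad_on_correct_only=True`; error RTs come from a different process).
The accuracy rule is strict-below: exactly 60% is retained.

## Estimators

* **ICC(A,1)** from two-way ANOVA mean squares (single measure, absolute
  agreement). Chosen because individual scores, not session means, are the
  objects whose reliability is at issue; absolute agreement penalizes the
  session speed-up if it leaked into scores. Verified against an
  independent statsmodels ANOVA assembly and pingouin's ICC2 to 1e-9.
* **Split-half**: per replication, each participant-session's valid trials
  are split within condition × direction strata; each half is scored by the
  standard scoring rules; the halves' effects are correlated across
  participants (Pearson) and stepped up with Spearman–Brown (n_ratio = 2).
  Permutated halves are disjoint (odd stratum: extra trial to a random
  half). Monte Carlo halves are independent with-replacement samples of
  ⌈stratum/2⌉ trials — the sampling scheme is not fully pinned down in the
  split-half literature, so the half-length-with-replacement reading is the
  default and `mc_half_size="full"` is available. Because Monte Carlo
  halves share trials, their errors correlate and the estimate is inflated,
  increasingly so at short lengths; reproducing that signature is a test.
* **Aggregation** over replications: simple mean by default; Fisher-z mean
  optional (differs by < 0.01 in practice, which is also asserted).
* **Split-half session**: session 1 by default, selectable.

## Length curves

Shortened tasks draw `L/4` trials per condition × direction stratum without
replacement from each participant-session's *valid* (exclusion-flagged)
trial pool, with flags computed once on the full data. Rationale: the
threshold estimated from ~300 trials is far more stable than one
re-estimated inside every 40-trial replication, the exclusion set stays
constant across lengths (so the curves vary only in trial count), and the
cost drops by orders of magnitude. Consequently the "full-length" point is
the valid set (slightly under 320 trials) in randomized order, and
per-stratum draws are capped at availability inside the curve driver;
the standalone `subsample_trials` keeps strict errors. Test–retest curves
draw independent subsamples per session per replication — mirroring how a
shorter task would actually have been administered twice; split curves use
one fresh split of each subsample per replication.

The Spearman–Brown grid fit evaluates all 101 candidates 0.00, 0.01, …,
1.00, scores each by the sum of squared differences over lengths, and
breaks ties toward the smaller candidate (conservative). On noiseless
prophecy curves every grid value is recovered with sse exactly 0.

## Numerical and performance choices

Resampling is vectorized: per replication chunk, stratum contents (grouped
by stratum size) are row-permuted with `Generator.permuted`, so a prefix of
each permuted stratum is simultaneously a uniform subsample and a random
half; sums are accumulated per participant × condition. RT values are
permuted as float32 (sums in float64); the ~1e-4 ms rounding is far below
every tolerance used. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; same seed, same result, bit for bit.
Replication counts in the test suite (hundreds to a few thousand, and 200
replicate datasets at 1000 splits for parameter recovery) were sized so
Monte Carlo error is several times smaller than the tolerance being
asserted.

Degenerate inputs: fewer than 4 threshold-defining trials raises (MAD cut
undefined); a condition with zero valid trials makes the score undefined —
reported and dropped; zero between-participant variance yields NaN
coefficients with a warning; replications with zero variance are dropped
and counted; |r| ≥ 1 is rejected by the Fisher transform (and clipped at
1 − 1e-12 only inside the Fisher-mean aggregator).

## Known limitations

* The attenuation correction linearizes the pooled-MAD shrinkage around
  `mu_effect`; for effect SDs far larger than the default range the slope
  varies across the trait distribution.
* `required_n_per_group` is the analytic normal-approximation solve; it
  reproduces standard power-software output for the two-sample Fisher-z
  test but inherits the approximation for tiny n.
* Split-half and curve machinery assume the 2 × 2 condition × direction
  stratification exists in the data; other designs need `stratify_by`.
* Only permutated and Monte Carlo splitting are first-class; first–second
  and odd–even splits are deliberately out of scope.
* No confidence intervals for ICCs, and no trial-level hierarchical
  (e.g. diffusion-model) scoring.
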