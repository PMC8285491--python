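# Methods

## Event model and interval arithmetic

A session is a set of bouts — one animal, one behavior, one half-open
interval `[t_start, t_stop)` in seconds from session start. Half-open
intervals make abutting bouts non-overlapping and all duration arithmetic
exact: the duration of a bout is `t_stop − t_start`, and the duration
inside a window is the measure of the interval intersection. Zero-length
bouts are rejected at parse time (they are annotation errors, not data),
and bouts of the same animal and behavior may not overlap; overlaps are
reported, not silently merged.

Pushing bouts carry a manual `successful` / `unsuccessful` label — whether
the push displaced the partner from the resource. The pipeline never
infers this from timing; it trusts the annotation, because the
categorization can only be made once a bout has ended and is therefore an
annotator's judgment.

## Session schedules and windows

Trial-structured tests (`mFC`, `mFCD`, `SCI`) run five cycles of a 60-s
inter-trial interval followed by 120 s of reward access (session 900 s,
nominal time-0 values 60/240/420/600/780 s). Because the door or bottle is
operated by hand, realized time-0 values jitter; the analysis therefore
quantifies a conservative window of 40 s before to 80 s after time 0, and
accepts per-trial observed time-0 values to anchor the windows. Bouts that
span a window boundary are clipped, not dropped, so duration mass inside
windows is preserved exactly. Continuous tests (`SC`, `WC`) are one 600-s
block; the "window" is the whole session and phase labels (anticipatory
vs reward) are undefined.

Consumption percentages are normalized by the effective consumption
observation time: 80 s × 5 trials = 400 s for trial tests, 600 s for
continuous ones. Consumption durations in trial tests are restricted to
the reward phase (the resource does not exist during the inter-trial
interval); exploration is split at time 0 into anticipatory and reward
phases, which sum exactly to the windowed total.

Ratios with empty denominators are missing, never zero: an animal that
never pushed has an undefined — not a 0% — success rate, and missing
values are excluded from downstream statistics rather than zero-filled.

## Indices

* `DI = 100 (C_A − C_B) / (C_A + C_B)`; missing when the pair consumed
  nothing. Classification uses an inclusive noise band: |DI| ≤ 10 →
  unstable. Inclusivity at the boundary keeps the band consistent with its
  definition as "less than a 5% difference from equal consumption".
* Tube-test DI counts completed trials only. Incomplete ("resistant")
  trials — the loser refuses to enter the tube — are excluded from both
  numerator and denominator but reported as a count, since refusal is
  itself a subordination signal worth keeping visible.
* `CRI = DI / mean latency over completed trials of the session`. The
  aggregate is the session mean because it is the least-structured choice
  and preserves the intended behavior (fast decisive wins score highest);
  a per-trial DI would be ±100 by construction and carry no extra
  information.
* Conflict index: pair pushing time ÷ pair drinking time (bottle tests) or
  ÷ mean latency-to-all-pellets over trials (food tests). Computed per
  day, averaged over days.
* Where a test ran on two days, DI is computed per day and averaged, with
  one exception: dominant/submissive classification for the food
  competition criterion uses day-2 DI alone, because conflict (and hence
  the test's discriminative power) is higher on day 2.

## Peak-conflict epoch

In the water competition both animals drink to satiation in long
alternating bouts, so whole-session DI is uninformative. The pipeline
slides a 120-s window in 1-s steps across the session and selects the
window maximizing the summed pair drinking + pushing duration, ties
breaking to the earliest window. The epoch length defaults to one
trial-length of access (120 s) and both length and step are configurable;
drinking and pushing are weighted equally in the objective. Within-epoch
drinking yields an epoch DI, and within-epoch pushing bouts (any bout
overlapping the epoch) yield per-animal success percentages.

## Statistics

The Wilcoxon signed-rank test drops zero differences, midranks ties, and
for n ≤ 15 computes the exact two-sided p by full sign-flip enumeration
(p = min(1, 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w)))); enumeration is exact under
tied magnitudes, where tabulated distributions are not. Beyond n = 15 a
normal approximation with tie and continuity corrections is used. A z
value is always reported. Bonferroni families must be declared explicitly;
the pipeline's default family is the set of behavior comparisons within
one test. Paired t, Kruskal–Wallis, one-way ANOVA with Tukey HSD, Pearson
correlation and a Kolmogorov–Smirnov normality gate wrap the corresponding
scipy/statsmodels routines behind the same result type.

Cross-test reliability is the Pearson correlation of DI between each test
pair over the dyads with both values defined; cells with fewer than three
overlapping pairs are reported missing.

## Weight-controlled regression

Body weight strongly influences who wins the first tube-test encounters
but not home-cage competition for food. To relate food-competition rank to
tube outcome net of weight: (1) pellets eaten are regressed on each
animal's own weight across all animals, keeping residuals; (2) day-1 tube
CRI is regressed on the within-pair weight difference (A − B, grams),
keeping residuals; (3) the CRI residuals are regressed on the within-pair
difference of pellet residuals (A − B). The weight covariate for the
pair-level step is a genuinely open choice; the within-pair difference is
used because CRI is inherently relational, and both within-pair
differences negate under A↔B relabeling, making the final slope invariant
to which animal is called A. All fits are ordinary least squares with an
intercept; a constant regressor raises an error rather than returning a
meaningless fit.

## Synthetic cohorts

The generator produces event logs and tube-trial tables with the
statistical structure the real tests exhibit, plus a ground-truth table
for recovery testing. Each pair carries a latent dominance strength
`delta ∈ [−1, 1]` (positive: animal A dominant), shared across tests by
default — hierarchy as a stable trait; an ablation draws an independent
delta per test, giving the reliability analysis a true negative.

Per test: food-competition trials split their 10 pellets
Binomial(10, 0.5 + 0.2·delta) and finish with a lognormal pair latency
(median 20 s; ×0.8 on day 2, ×0.6 under deprivation); sucrose drinking
shares follow 0.5 + 0.2·delta with 0.05 noise; water-competition totals
are near-equal (share 0.5 + 0.015·delta, noise 0.02) while the
subordinate emits more and longer pushing bouts and per-bout success is
logistic in the pusher's signed delta (gain 3, or 5 in the water test,
where dominants succeed almost always). Subordinates groom more;
dominants show more anticipatory feeder exploration. Tube-test day-1 win
odds are logistic in 5·delta + 0.25·(weight difference in %); winners
repeat with probability 0.9; latencies settle at a 3.5-s median after the
first trial, scaled up ×(1 + 2.5·contestedness) for evenly matched pairs;
strongly ranked pairs (|delta| ≥ 0.5) refuse ~9% of day-2 trials. Cohorts
draw delta uniform on [−1, 1], body weights around 450 g with within-pair
differences capped at 8% (under the 10% matching criterion).

These effect sizes live in one `CohortConfig` block and are calibrated
defaults — chosen so the generator reproduces the qualitative patterns
above at realistic sample sizes — not estimates of any real cohort's
generative parameters. The delta→tube-odds gain (5.0) and the
contested-latency gain (2.5) were calibrated against the
weight-controlled regression's recovery power at 16 pairs. Bout-duration
and latency distributions (lognormal, exponential) are stand-ins: real
bout-duration statistics for these tests are not published. The generator
does not model spatial behavior, bout-merging ambiguity, annotation error
or aggressive escalation, so passing recovery tests demonstrate that the
pipeline's inference is correct under the stated generative assumptions,
not that those assumptions exhaust real data.

Randomness: each pair's stream derives from
`SeedSequence(seed, spawn_key=(pair_index,))`, so cohorts are
reproducible byte-for-byte and extensible without perturbing existing
pairs.

## Problem sizes

Validation suites run at the sizes the analyses target: 1000 random
inputs for formula checks, 200 random logs against a 0.01-s discretized
overlap oracle, exhaustive 2^n Wilcoxon enumeration up to n = 10, 500
replicates for dominant-identification recovery, and 200 simulated
cohorts (20 pairs for reliability, 16 for the regression) for the
cohort-level properties.

## Known limitations

* Dyads only; group hierarchies (Elo, David's score) are out of scope.
* The pipeline trusts bout annotations; no inter-rater modeling and no
  bout smoothing or merging.
* The peak-conflict epoch definition (length, step, equal weighting of
  drinking and pushing) is a reasonable default, not a canonical one.
* Day aggregation beyond two days is untested territory; the study design
  never exceeds two.
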