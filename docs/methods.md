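# Methods

## Data model and units

Grooming events are directed intervals timed to the second inside discrete
observation sessions. Times are stored as non-negative integer seconds from
session start: seconds are the recording resolution, integers avoid float
drift, and reporting layers convert to minutes. Events must lie within
their session, self-grooming rows and duplicate identical rows are rejected
(duplicates are more plausibly transcription errors than data), and dyads
are canonical unordered pairs (lexicographically ordered ids).

## Pairing rules

A reciprocation pair is a role-reversed pair of events of one dyad within
one session, summarized as (X, Y, Δ) with Δ = reply start − first-event end.
Choices a reader should know:

- **Most-recent-X.** Each candidate reply pairs with the most recent
  opposite-direction event starting at or before it. Ties on identical
  starts are broken by earlier end, then groomer id — the earlier event in
  that ordering is "first".
- **One-to-one matching (default).** An event already claimed as some
  reply's X is unavailable to later replies, which fall back to the most
  recent unclaimed candidate. This prevents one grooming act from being
  counted as the X of several triples; `reuse_x=True` restores unlimited
  reuse. An event may still serve once as a reply and once as a later
  pair's X — chains of alternating grooming naturally produce this.
- **No session bridging.** Reciprocation across a session boundary is never
  counted: the observer was absent in between, and pairing across the gap
  would invent evidence.
- **No bout threshold.** Events of the same direction are not merged by
  default (a merge gap is available as pre-processing); Δ itself carries
  the delay information, so no arbitrary cutoff delimits "bouts".

`pair_events_bruteforce` re-derives the pair set by exhaustive enumeration
over all ordered event pairs and is kept as a permanent oracle; a property
test asserts exact agreement on random logs under both reuse policies.

## Asymmetry testing

Per-unit asymmetry uses the notched-boxplot convention: median ±
1.58·IQR/√n (the constant is configurable). For nonnegative data the lower
limit is floored at the sample minimum, so a unit whose median is exactly 0
can never be flagged. Note the flooring makes the test liberal for units
whose every ρ is strictly positive: with continuous noise and no exact
ties, any unit has min > 0 and is flagged. On second-resolution data exact
ties (ρ = 0) are common and carry the non-rejections. In the
per-individual analysis each pair is credited to both participants.

## Repeated-measures ANOVA

The F test is a two-stratum decomposition on dyad-by-condition cell means
(mean ρ per dyad per condition), restricted to dyads observed in both
conditions: SS_total over cells = SS_dyad + SS_condition + SS_error, with
F(1, n_both − 1) = MS_condition / MS_error. Dyads seen in only one
condition cannot contribute a within-dyad contrast and are excluded from
the F test; they still enter the effect sizes, which are computed on the
full per-pair records: η² = SS_condition/SS_total of the one-way split,
mean difference of condition means, and Cohen's d with the pooled-SD
denominator. The decomposition is cross-checked in the test suite against
an independent repeated-measures ANOVA implementation on balanced data.

## Mixed time-matching regression

Y ~ X + (1|dyad) is fit by `statsmodels` MixedLM: REML for estimates and
standard errors, ML refits for the likelihood-ratio test against the
random-effects-only null (χ²₁ reference). A near-zero random-intercept
variance, or a single-dyad input (which degrades to OLS), sets a
`singular` flag rather than raising. At study scale (~100 dyads, ~600
pairs) simulation shows the 2-SE interval covers a known slope at its
nominal rate; with few dyads (~30) the standard errors run ~10% small, a
known small-sample property of plug-in mixed-model SEs.

## Windowed aggregation and the bootstrap null

Windows are consecutive, non-overlapping, anchored at each session's start,
and never span sessions; a pair belongs to the window containing its X
event's start. Within a dyad-window, sums are oriented canonically (seconds
a→b vs b→a), so P = |ΣX − ΣY|/(ΣX + ΣY) is label-invariant. Rows with a
one-sided zero sum cannot arise from pair aggregation (each pair deposits
positive time in both directions) but would be excluded from log-log fits
and counted; log-log fits report adjusted R².

The null model replaces each pair's X with a draw (with replacement) from
the X-actor's cross-section of X-role durations over the whole dataset, and
Y likewise from the Y-actor's Y-role cross-section, holding the calendar —
dyads, sessions, window assignments, conditions — fixed. The bootstrap
estimator is the median of P across dyad-windows; 2.5/97.5 percentiles of
the replicate medians (inclusive linear interpolation, so critical values
are reproducible across implementations) form the 95% band, and rejection
means the empirical median falls *below* the lower critical value. The
default is 10⁵ replicates; replicate streams are chunk-vectorized with a
fixed chunk size so a given seed yields bit-identical results. Under the
i.i.d. generator regime the band covers the empirical median at its nominal
rate (checked at 200 datasets × 1,000 replicates in the test suite).

## Synthetic generator

The generator emulates the empirical shape of a dense short-term
observational study of one captive group: 26 individuals, 26 sessions
drawn uniformly from 15–320 minutes, log-normal durations with mean ≈ 256 s
(μ = 4.94, σ = 1.1 on the log scale), seed events arriving homogeneously at
0.39 per observed minute, replies with probability 0.5, and a 75% share of
overlapping replies — together ≈ 2,500 events, ≈ 1,000 pairs at a ≈ 70/30
within-bout/delayed split, and grooming-hours exceeding observation hours.
Regimes differ only in the reply's timing and duration: `null_iid` draws
every duration independently (the bootstrap's null, by construction);
`within_bout_matcher`/`delayed_matcher` set the reply duration to
X + Normal(0, match_noise_sd) truncated positive; `mixed` matches
overlapping replies and leaves delayed replies i.i.d., mirroring the
cliff-edge profile. Replies are clipped at session end and the truncated
duration is what is logged, as a live observer would record it.

What the generator does **not** emulate: partner choice (dyads are uniform,
so nearly all 325 dyads are active, unlike the ~45% typically seen),
polyadic grooming cliques, dominance/kinship structure, diurnal rate
variation, and bout-internal pause structure. Passing tests therefore
show the pipeline's statistics behave correctly under known regimes, not
that real groups behave like the generator.

### Censoring attenuation

Because replies are censored at session end, a noiseless within-bout
matcher does not yield a slope of exactly 1: censored replies (~4% of
within-bout pairs at default settings) have large X and small Y and are
high-leverage under heavy-tailed durations, attenuating the fitted slope to
≈ 0.9 (≈ 0.98 among uncensored pairs). Tests of the matcher regime
therefore accept the slope within 0.15 of 1 and lean on the cliff-edge
contrast — the i.i.d./noised-delayed slope is ≈ 0 and the bootstrap never
rejects there — rather than on exact unity. The same censoring exists in
real session-bounded data.

## Problem sizes in tests

The suite runs the pairing oracle on 1,000 random logs (≤ ~40 events), the
type-I calibration on 200 full-size i.i.d. datasets at 1,000 bootstrap
replicates, and slope recovery on 100 study-scale datasets (100 dyads × 6
pairs); examples and the reproduction script use 2,000–20,000 replicates.
These sizes were chosen so the whole suite completes in about a minute
while keeping Monte-Carlo error well inside the asserted bands; the
library default of 10⁵ replicates matches the analysis the package
implements.

## Known limitations

- The delayed-reply delay distribution is exponential (mean 600 s); real
  inter-bout gaps are heavier-tailed.
- The notch-CI asymmetry test is a screening device, not a calibrated
  hypothesis test; see the flooring caveat above.
- With `reuse_x=False` the pairing is greedy in time order; it is not a
  globally optimal matching, and the "most recent unclaimed" fallback
  matters only in dense alternating chains.
- The bootstrap conditions on the observed event calendar; it does not
  model uncertainty in who groomed whom or when, only in durations.
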