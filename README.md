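# deltagroom

Time-matching analysis of dyadic allogrooming from session-structured
behavioral event logs.

Grooming is the canonical currency of primate social exchange, and a basic
question about any exchange is whether it is repaid in kind: does twenty
seconds of grooming buy twenty seconds back, and if so, how quickly?
`deltagroom` analyzes logs of directed grooming events — who groomed whom,
from when to when, inside which observation session — and asks whether
grooming durations are *time-matched* within dyads, separately for
reciprocation that starts while the original grooming is still running
(mutual grooming) and reciprocation that comes after a break.

The package is aimed at behavioral ecologists working with continuous
all-occurrence sampling data: event tables timed to the second, collected in
discrete observation sessions that must not be bridged when inferring
reciprocation.

## The method

**Delta-scale pairing.** Within each session and dyad {A, B}, every
role-reversed pair of events is reduced to a triple (X, Y, Δ):

- X — seconds A groomed B (the first event),
- Y — seconds B groomed A (the reply),
- Δ — the signed gap between the end of X's event and the start of Y's:
  Δ < 0 means the reply began during the original grooming (*within-bout*);
  Δ ≥ 0 is *delayed* reciprocation.

Each reply is paired with the most recent opposite-direction event starting
at or before it (most-recent-X), one-to-one by default so no grooming act is
counted twice. Pairs never span sessions.

**Reciprocity.** Per pair, ρ = |X − Y| / (X + Y) ∈ [0, 1]; ρ = 0 is perfect
time-matching. Asymmetry of a dyad or individual is judged from the notched
95% CI of its median ρ (reject symmetry when the lower limit is strictly
positive). Condition-level inference uses a one-way repeated-measures ANOVA
of ρ on condition with the dyad as the random effect, and the mixed model
Y ~ X + (1|dyad) with a likelihood-ratio test against the
random-effects-only null.

**Aggregate matching and the law of large numbers.** Durations summed over
time windows look balanced merely because i.i.d. sums concentrate. For each
dyad-window the windowed reciprocity is P = |ΣX − ΣY| / (ΣX + ΣY); the test
statistic is the median of P across dyad-windows. A bootstrap null redraws
every pair's durations from the per-individual empirical duration
distributions (10⁵ replicates by default) and takes the 2.5/97.5 percentiles
of the replicate medians as critical values: only an empirical median *below*
the band is evidence of genuine aggregate time-matching.

A synthetic generator (`SynthConfig`/`generate`) produces session-structured
logs under controllable regimes — i.i.d. null, within-bout matcher, delayed
matcher, or a mixed study-like profile — so the full pipeline is testable
end to end.

## Worked example

```bash
python examples/windowed_null_test.py
```

prints (seed 42, 5,000 bootstrap replicates):

```
window  condition    n    adjR2   P_med  [2.5%, 97.5%]  reject
    20  within_bout  762   0.66    0.07  [0.47, 0.54]  True
    20  delayed      307  -0.00    0.52  [0.44, 0.55]  False
    40  within_bout  760   0.66    0.07  [0.46, 0.53]  True
    40  delayed      304  -0.00    0.52  [0.44, 0.55]  False
    60  within_bout  754   0.66    0.07  [0.47, 0.53]  True
    60  delayed      303  -0.00    0.52  [0.44, 0.55]  False
   240  within_bout  721   0.67    0.07  [0.46, 0.53]  True
   240  delayed      285   0.01    0.50  [0.43, 0.55]  False
```

Within-bout grooming is strongly time-matched — the log-log regression of
ΣY on ΣX explains two thirds of the variance and the median windowed
reciprocity (0.07) sits far below the null band, at every window size.
Delayed grooming shows no matching at all: its median P is exactly what
i.i.d. random durations produce. `examples/reciprocity_stats.py` shows the
same cliff edge per pair (mixed-model slope 0.98 within bouts vs 0.01 after
a delay), and `examples/full_pipeline.py` produces the complete JSON report.

The same stages are available from the shell:

```bash
deltagroom simulate --seed 42 -o events.csv --sessions-out sessions.csv
deltagroom pair --events events.csv --sessions sessions.csv -o pairs.csv
deltagroom nulltest --pairs pairs.csv --window 20 --condition delayed --reps 100000 --seed 17 -o boot.json
deltagroom run --config run.yaml
```

## Layout

- `src/deltagroom/io_model.py` — data model, CSV I/O, validation
- `src/deltagroom/pairing.py` — Delta-scale pairing (+ brute-force oracle)
- `src/deltagroom/metrics.py` — ρ, median CIs, ANOVA, mixed regression
- `src/deltagroom/windows.py` — windowed aggregation, bootstrap null
- `src/deltagroom/synth.py` — synthetic event-stream generator
- `src/deltagroom/pipeline.py`, `cli.py` — end-to-end report and CLI
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
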