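# dyadrank

Dominance scoring for dyadic competition tests in pair-housed rats (and
other laboratory rodents), from timestamped ethogram event logs.

Established social hierarchies between familiar cage mates are maintained
through subtle interactions, not overt fights, which makes them hard to
measure. A family of home-cage competition tests addresses this: pairs of
animals compete for a limited resource — palatable pellets behind a
one-animal feeder (modified food competition, `mFC`, with a deprived
variant `mFCD`), 1% sucrose solution with continuous (`SC`) or
intermittent (`SCI`) bottle access, water under deprivation (`WC`) — plus
the classic tube test, where the first animal to retreat loses the trial.
`dyadrank` turns the annotated behavioral bouts from such sessions
(consumption, pushing, feeder exploration, grooming) into quantitative
dominance measures, and ships a synthetic dyad generator so every step of
the pipeline can be validated against known ground truth.

## The indices

For a pair (A, B), with `C_A`, `C_B` the resource consumption of each
animal (pellets eaten, seconds of drinking, or tube-test wins):

- **Dominance Index**: `DI = 100 · (C_A − C_B) / (C_A + C_B)` ∈ [−100, 100].
  Positive means A has priority access. |DI| ≤ 10 (a < 5% deviation from
  equal consumption) is treated as noise — no reliable hierarchy.
- **Conflict Resolution Index** (tube test): `CRI = DI / T̄`, where `T̄` is
  the mean latency to resolve a completed trial. Fast, decisive wins score
  higher than slow contested ones.
- **Conflict Index**: pair pushing time divided by pair consumption time
  (bottle tests) or by the mean latency to finish all 10 pellets (food
  tests) — how much conflict a test format induces.
- **Pushing efficiency**: percent of an animal's pushing bouts that
  actually displaced its partner. Dominants push *efficiently*, even when
  subordinates push more.

Trial-structured tests are quantified in windows spanning the last 40 s of
the inter-trial interval and the first 80 s of reward access around each
trial's "time 0" (the moment the feeder door opens or the bottle appears),
with consumption normalized by the effective observation time (400 s for
trial tests, 600 s for continuous ones). For the water competition, where
both animals drink near-equal totals, a sliding **peak-conflict epoch**
(default 120 s) locates the moments of maximal combined drinking and
pushing, where rank differences show.

The pipeline also computes cross-test reliability (Pearson correlations of
DI between tests, over pairs), and a weight-controlled regression: pellets
eaten and day-1 tube CRI are each residualized on body weight, and the CRI
residuals regressed on the within-pair pellet-residual difference — body
weight strongly affects early tube-test outcomes but not home-cage food
competition, so the residual slope isolates the shared hierarchy signal.

## Worked example

Simulate a 6-pair cohort and analyze it end to end:

```bash
dyadrank simulate --out data/ --n-pairs 6 --seed 1
dyadrank analyze --events data/events.csv --tube data/tube_trials.csv \
    --weights data/weights.csv --out report/
```

or equivalently from Python:

```python
from dyadrank.simulate import simulate_cohort
from dyadrank.pipeline import run_analysis

cohort = simulate_cohort(n_pairs=6, seed=1)
bundle = run_analysis(list(cohort.events), list(cohort.tube_trials),
                      list(cohort.weights))
print(bundle.dominance[["pair_id", "test_code", "di", "label"]].head(6))
print(bundle.reliability_r.round(2).loc["mFC", ["SC", "SCI", "WC", "tube"]])
```

which prints (pair 1 has a clear A-dominant hierarchy):

```
  pair_id test_code         di       label
0  pair01        SC  16.583980  A_dominant
1  pair01       SCI  11.978965  A_dominant
2  pair01        WC  -0.927473    unstable
3  pair01       mFC  32.000000  A_dominant
4  pair01      mFCD  24.000000  A_dominant
5  pair02        SC  19.907583  A_dominant
SC      0.72
SCI     0.79
WC      0.34
tube    0.89
```

Reading it: the food- and sucrose-competition DIs agree on who is dominant
(and correlate strongly across tests — hierarchy behaves as a stable
trait), while the water-competition DI sits inside the ±10 noise band:
deprived animals drink to satiation in alternating bouts, so consumption
totals equalize even in strongly ranked pairs. The `report/` directory
contains the behavior summaries, dominance results, reliability matrices,
the dominant-vs-submissive Wilcoxon table, the weight-controlled
regression report and a manifest sufficient to reproduce the run.

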