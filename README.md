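# calvehmm

Predicting calving time from hourly posture-change counts in pre-partum
cattle, using a two-state hidden Markov model over discretized activity
levels.

Cows become restless in the hours before parturition: they alternate
between lying and standing far more often than usual. On farms where
pregnant heifers are monitored in calving pens, the hourly count of
posture changes (standing bouts + lying bouts) is a cheap, robust signal
of approaching calving. `calvehmm` turns a 72-hour record of such counts
into a probabilistic calving-time prediction, for researchers and
precision-livestock engineers who want a transparent, data-light
alternative to black-box classifiers.

## The model

Hidden states are the behavioural regimes **NC** (non-calving) and **C**
(calving). The observed counts n are discretized into ordinal activity
levels relative to the sample mean μ and sample standard deviation σ of
the record:

- hourly: **L** if n < μ, **M** if μ ≤ n < μ+σ, **H** if n ≥ μ+σ;
- 3-hour window sums s: **L** if s < μ_w+σ_w, **M** if μ_w+σ_w ≤ s < μ_w+2σ_w,
  **H** if s ≥ μ_w+2σ_w.

The HMM λ = (A, B, Π) is estimated without EM:

- **Emissions B.** For each regime segment (a 60 h NC prefix and a 12 h C
  suffix of the training record) count consecutive level pairs into a 3×3
  co-occurrence matrix, row-normalize it into a level-transition chain,
  and take that chain's stationary distribution π (πP = π, Σπ = 1) as the
  regime's emission row.
- **Transitions A.** Duration-based: a regime expected to last d hours
  has self-transition d/(d+1), so A = [[60/61, 1/61], [1/13, 12/13]].
- **Initial Π** defaults to the uninformative [0.5, 0.5].

Decoding offers the Viterbi joint-mode path and forward–backward
smoothed posteriors γ_t(C) = P(state_t = C | all observations). Because A
is strongly persistent, the Viterbi path is deliberately conservative;
the default calving-time strategy is therefore `max_posterior`, the
interval maximizing γ_t(C).

## Worked example

The package ships a reference record: 72 hourly posture-change counts
from a Holstein first-calf heifer, hours −72..−1 before calving.

```python
import calvehmm as ch

series = ch.load_example_cow()
stats  = ch.summary_stats(series.counts)      # mu=1.931, sigma=1.967
params = ch.build_hmm(ch.hourly_levels(series), ch.SegmentSpec(60, 12))
result = ch.predict_calving_time(params, ch.discretize(series, window=3))
```

Running `python examples/fit_worked_example.py` prints the fitted model:

```
transition matrix A (rows: from NC, from C):
 [[0.984 0.016]
 [0.077 0.923]]
emission matrix B (columns L, M, H):
 [[0.472 0.393 0.135]
 [0.231 0.462 0.308]]
```

i.e. a calving hour shows High activity with probability 0.308 versus
0.135 for a non-calving hour. `python examples/decode_and_predict.py`
then decodes the record at 3-hour resolution: the smoothed posterior of
the calving state rises from ~0.002 mid-record to 0.104 in the final
window, and the `max_posterior` prediction is interval 24 — the last
three hours before the true calving time. The `threshold_accuracy`
summary of the same fit is 91.0599% (μ+σ = 3.897 h of elevated activity
against a 3-h horizon).

The other examples (`simulate_and_recover.py`, `evaluate_metrics.py`)
cover the synthetic two-regime count generator with parameter recovery,
and interval-level sensitivity/precision scoring.

A thin CLI wraps the same library:

```
calvehmm fit --input cow.csv --output model.json
calvehmm decode --model model.json --input cow.csv --output decoded.csv
calvehmm simulate --n-animals 25 --seed 1 --output sim.csv
calvehmm evaluate --truth truth.csv --predicted decoded.csv
```

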