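# Methods

## Model and estimation procedure

`calvehmm` models the final ~72 hours before calving as a two-state
hidden Markov chain: a long quiescent non-calving regime (NC) followed
by a short restless calving regime (C). The only observable is the
hourly posture-change count (standing bouts + lying bouts), reduced to
an ordinal activity level L/M/H.

Estimation is moment-style, not maximum-likelihood; there is no
Baum–Welch step. It assumes the training records come with a fixed
segmentation — by default the first 60 h are labelled NC and the final
12 h C — and proceeds:

1. **Discretize** each record with thresholds μ and μ+σ computed from
   that record's own counts (sample standard deviation, n−1
   denominator).
2. **Count** consecutive level pairs within each segment into a 3×3
   co-occurrence matrix. Pairs that straddle the NC/C boundary are
   counted in neither segment, so a 60 h segment contributes exactly 59
   pairs and a 12 h segment 11. With several training animals the pair
   counts are pooled across animals per segment before normalizing
   (pooling is equivalent to weighting each animal by its pair count;
   with equal-length records all animals weigh equally).
3. **Normalize** rows to get a first-order level-transition chain per
   regime. An all-zero row (a level that never occurs as a pair origin)
   is imputed as uniform and logged; this keeps sparse segments usable
   while making the imputation visible.
4. **Emissions** are the stationary distribution of each regime's level
   chain: the long-run occupancy of L/M/H while the animal stays in that
   regime. The linear system πM = π, Σπ = 1 is solved on the unrounded
   matrix entries (count ratios); solving on 3-decimal rounded entries
   shifts the third decimal of the result.
5. **Transitions** come from the segment durations alone: a regime
   expected to persist d hours gets self-transition d/(d+1), the
   geometric-sojourn matching of a mean d-hour dwell observed at 1-hour
   resolution.

The stationary solver requires an irreducible level chain. A reducible
chain is rejected with a `DegeneracyError` naming the communicating
classes, even in cases (e.g. a single absorbing level) where πM = π
still has a unique solution: such a solution puts exactly zero mass on
transient levels, which as an emission row would assign zero probability
to observable symbols and make decoding brittle. Constant-count records
hit this path (all hours discretize to H), which the CLI surfaces as
exit code 3.

## Discretization conventions

The level bands are half-open: L = [0, μ), M = [μ, μ+σ), H = [μ+σ, ∞).
Counts landing exactly on a threshold are assigned to the upper band;
with non-integral thresholds (the generic case for count data) the
choice is unobservable, but it must be fixed for σ = 0 inputs, where the
M band is empty and any n ≥ μ maps to H.

At 3-hour resolution, counts are summed over non-overlapping windows and
the thresholds move one band up: L below μ_w+σ_w, M in [μ_w+σ_w,
μ_w+2σ_w), H above, with μ_w, σ_w computed on the window sums by the
same estimator. The shift reflects that window sums concentrate around
w·μ — a plain μ_w threshold would label half the baseline Medium —
whereas one-standard-deviation excursions of the 3-h sum are what mark
genuinely elevated activity. This windowed rule is a package convention
(logged on every use); the hourly rule, by contrast, is the standard
mean/mean-plus-sd banding.

The resolution question — fit on hourly labels, decode on 3-h labels
with the same B — is left to the caller as an explicit `window`
parameter. The default pairing (hourly fit, 3-h decoding) matches the
worked example in the README; both label tiers are produced by the same
code path and tested exhaustively on the reference record.

## Decoding and the choice of prediction strategy

Viterbi runs in log space with −∞ sentinels (the calving-segment level
chain contains exact zeros). Ties break toward NC, so a calving claim
always requires strictly positive evidence. Forward–backward uses
per-step scaling; both decoders are stable on 10,000-step sequences and
are verified against exhaustive path enumeration (T ≤ 12) and exact
path-sum marginals (T ≤ 10, tolerance 1e−10), plus an independent
implementation (hmmlearn) on the reference record.

Under the duration-based A, staying in NC (0.984) is so much cheaper
than entering C (0.016) that the joint-mode path never leaves NC on the
reference record, even at its high-activity final window: the Viterbi
decoder is structurally conservative here. The package therefore ships
three explicit prediction strategies instead of a single hard-coded
rule — `viterbi_onset`, `max_posterior` (default), and
`posterior_threshold(τ)` — with `max_posterior` the default because the
smoothed posterior aggregates evidence over all paths and correctly
peaks in the true calving window of the reference record (γ_C = 0.104
at the final 3-h interval vs ≤ 0.072 elsewhere). This is retrospective
smoothing over a complete record, not online filtering.

## Evaluation

Sensitivity and precision are computed per decoded interval with C as
the positive class — the simplest convention consistent with
interval-level decoding; event-level (per-calving) scoring is a
documented alternative we do not implement. Undefined ratios (empty
denominators) are returned as NaN with explicit flags, never as silent
zeros, so cross-animal averages are not corrupted.

`threshold_accuracy` scores how close the fitted activity threshold μ+σ
lands to a fixed pre-calving horizon h (default 3 h):
accuracy = (1 − (|h − (μ+σ)|/h)²)·100. It is a descriptive figure of
merit, not a proper scoring rule — it compares a dispersion threshold to
a time horizon — and is implemented for comparability. By default μ+σ
enters at 3-decimal reporting precision, the precision at which summary
statistics are quoted (the reference fit gives 91.0599%; at full
floating precision, 91.0526%). `decimals=None` selects full precision.

## Synthetic data

`simulate_symbols` draws (state, symbol) paths from a fitted λ and
underpins the Monte-Carlo estimation checks (empirical NC→C frequency
within 3 binomial SEs of 1/61 at 100,000 steps; within-state symbol
frequencies within 0.01 of B).

`simulate_counts` emulates the raw measurement: per animal, 60 h of
Poisson counts at a low rate then 12 h at an elevated rate. Defaults
(1.7 and 3.2 posture changes/h) equal the empirical segment means of the
reference record; a negative-binomial option with dispersion parameter r
(p = r/(r+mean)) covers over-dispersed animals. One root seed spawns
independent per-animal streams, so animal i's record does not depend on
cohort size. The generator reproduces the features the model relies on —
a rate step at a known changepoint with independent integer counts — and
deliberately omits circadian rhythm, tail-raising/head-turning
behaviours, inter-animal rate heterogeneity and annotation error.
Passing tests on synthetic cohorts therefore demonstrate correctness of
the estimation and decoding machinery, not field performance on real
barn recordings.

Fixed-seed checks at these conditions: two independent 200-animal
cohorts agree on each emission row within 0.05 total variation, and with
strongly separated rates (1.5 vs 6.0, a 4× step) the `max_posterior`
prediction falls inside the true 12-h calving segment in ≥ 90% of 500
held-out animals.

## Numerical choices and limitations

- All arithmetic at full double precision; rounding to 3 decimals only
  at reporting boundaries.
- Stochasticity of matrix rows enforced within 1e−9 at construction and
  on model load.
- The stationary solve uses least squares on the stacked system
  (Mᵀ−I; 1ᵀ), clipping negligible negative components before
  renormalizing.
- Model files are plain JSON at full float precision and round-trip
  bit-identically.
- The estimator presumes the training segmentation (60/12) is correct;
  mislabelled segment boundaries bias both B rows. Durations are
  configurable but not estimated from data.
- Emissions assume within-regime stationarity of the level process; a
  gradual activity ramp before calving violates this and smears the C
  row toward the NC row.
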