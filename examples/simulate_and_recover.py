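"""Simulate a cohort of two-regime count records and refit the model.

Each synthetic animal emits Poisson hourly posture-change counts: 60 h
at a low non-calving rate, then 12 h at an elevated calving rate. The
fit recovers an emission matrix with the expected ordering and a
transition matrix fixed by the regime durations.
"""

import numpy as np

import calvehmm as ch

cfg = ch.SimulationConfig(nc_rate=1.5, c_rate=6.0, n_animals=50, seed=42)
cohort = ch.simulate_counts(cfg)
print(f"simulated {cfg.n_animals} animals x {cfg.nc_hours + cfg.c_hours} h "
      f"(rates {cfg.nc_rate} -> {cfg.c_rate} posture changes/h)")

params = ch.build_hmm([ch.hourly_levels(s) for s in cohort],
                      ch.SegmentSpec(cfg.nc_hours, cfg.c_hours))
print("recovered emission matrix B (columns L, M, H):\n", np.round(params.B, 3))
print(f"P(H|C) = {params.B[1, 2]:.3f} exceeds P(H|NC) = {params.B[0, 2]:.3f}: "
      "the elevated calving regime is recovered from counts alone.")

# Decode a held-out animal and check the prediction lands in its true
# calving segment (the final 12 hours).
(held_out,) = ch.simulate_counts(
    ch.SimulationConfig(nc_rate=1.5, c_rate=6.0, n_animals=1, seed=4242)
)
res = ch.predict_calving_time(params, ch.hourly_levels(held_out))
in_segment = res.predicted_interval is not None and res.predicted_interval >= 60
print(f"held-out animal: predicted calving at hour offset "
      f"{res.predicted_interval - 72}, inside true calving segment: {in_segment}")
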