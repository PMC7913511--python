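"""Fit the two-state calving HMM from the packaged reference heifer.

Walks the whole estimation chain on the 72-hour posture-change record:
summary statistics, hourly L/M/H labels, per-segment co-occurrence
counts, row-normalized level chains, their stationary distributions
(the emission rows), and the duration-based transition matrix.
"""

import numpy as np

import calvehmm as ch

series = ch.load_example_cow()
stats = ch.summary_stats(series.counts)
print(f"mu = {stats.mu:.3f}, sigma = {stats.sigma:.3f}  "
      f"(level thresholds: L < {stats.mu:.3f} <= M < {stats.mu + stats.sigma:.3f} <= H)")

hourly = ch.hourly_levels(series, stats)
print("hourly labels:", "".join(hourly.symbols))

seg = ch.SegmentSpec(nc_hours=60, c_hours=12)
nc, c = ch.segment_counts(hourly, seg)
print("non-calving pair counts:\n", nc)
print("calving pair counts:\n", c)

params = ch.build_hmm(hourly, seg)
print("transition matrix A (rows: from NC, from C):\n", np.round(params.A, 3))
print("emission matrix B (columns L, M, H):\n", np.round(params.B, 3))
print()
print("Each B row is the stationary distribution of that regime's level")
print("chain: calving hours are far likelier to show High activity")
print(f"(P(H|C) = {params.B[1, 2]:.3f} vs P(H|NC) = {params.B[0, 2]:.3f}).")
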