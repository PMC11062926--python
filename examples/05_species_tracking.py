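"""Do species range shifts keep pace with the isotherms?

Observed elevational shift velocities are paired with the isotherm
velocity at each study's centroid; repeated subsamples of 30 records are
tested with a two-tailed Wilcoxon signed-rank test, and the tracking
probability is the share of 1,000 subsamples in which the biological and
climatic velocities are statistically indistinguishable (p >= 0.05).
"""

import numpy as np

from isovel import sensitivity_n, tracking_probability, wilcoxon_signed_rank

rng = np.random.default_rng(42)
velocities = rng.uniform(3.0, 8.0, 200)  # isotherm velocities, m/yr
noise = rng.normal(0.0, 2.0, 200)        # study-level scatter

for lag in (0.0, 2.0, 5.0, 50.0):
    shifts = velocities - lag + noise
    res = tracking_probability(shifts, velocities, n_resample=30,
                               iterations=1000, alpha=0.05, seed=7)
    print(f"tracking deficit {lag:5.1f} m/yr -> probability {res.probability:.3f}")
# With no deficit the probability sits at 1 - alpha = 0.95 (the test is
# calibrated); a 50 m/yr deficit is detected in essentially every
# subsample, so the probability collapses to zero.

stat, p = wilcoxon_signed_rank([0.4, 1.3, 2.2, 3.1, 4.5])
print(f"\nfive positive differences: W+ = {stat:.0f}, exact p = {p:.4f}")
# 2/32: the smallest two-tailed p-value five untied pairs can produce.

shifts = velocities - 3.0 + noise
table = sensitivity_n(shifts, velocities, n_grid=(10, 20, 30, 50, 100),
                      iterations=300, seed=7)
print("\nsensitivity to the resample size n:")
print(table.to_string(index=False))
# Power grows with the resample size n, so the probability declines and
# then stabilises once the deficit is detected in essentially every
# subsample -- the basis for fixing n = 30 in the headline analysis.
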