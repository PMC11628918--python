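"""Compare two multivariate samples with the probability-binning statistic.

Bins are built on a reference by recursive variance-guided quantile splits
until each holds an equal share of reference events; the test sample's bin
occupancies give a standardized chi-square T that is ~0 when the samples
share a distribution and grows with any difference.
"""

import numpy as np

from walklineage.analysis import permutation_null_T, probability_binning_T

rng = np.random.default_rng(7)
reference = rng.normal(size=(10_000, 5))

same = rng.normal(size=(10_000, 5))
stat_same = probability_binning_T(reference, same, n_bins=100)
null = permutation_null_T(reference, same, n_bins=100, n_perm=200, seed=1)
print(f"same distribution:    T = {stat_same.T:6.2f} "
      f"(permutation null 99th pct = {np.quantile(np.abs(null), 0.99):.2f})")

for shift in (0.1, 0.3, 0.6):
    shifted = rng.normal(size=(10_000, 5)) + shift
    stat = probability_binning_T(reference, shifted, n_bins=100)
    print(f"location shift {shift:.1f}:   T = {stat.T:8.2f}")
# T for matched samples stays inside its permutation null; a growing
# location shift drives T up monotonically.
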