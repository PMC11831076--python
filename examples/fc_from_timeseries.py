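"""From ROI time series to edge features.

Simulates a subject's regional BOLD series with superimposed nuisance
signals (global/tissue/motion), cleans them (nuisance regression, linear
detrend, 0.01-0.1 Hz zero-phase band-pass), computes the Fisher-z Pearson
FC matrix and flattens it into the canonical edge vector.
"""

import numpy as np

from memconn.connectome import (
    detrend_and_bandpass,
    fisher_z,
    pearson_fc,
    regress_nuisance,
    vectorize,
)
from memconn.synthetic import SimulationConfig, add_nuisance, simulate_cohort

cohort = simulate_cohort(
    SimulationConfig(n_subjects=1, n_nodes=90, n_timepoints=230,
                     fc_mode="timeseries", random_seed=5)
)
clean = cohort.time_series[0]
dirty, regressors = add_nuisance(clean, amplitude=1.5, seed=9)
print(f"series: {clean.shape[0]} nodes x {clean.shape[1]} timepoints "
      f"(8 min at TR = 2 s, first 10 volumes discarded)")
print(f"nuisance regressors: {regressors.shape[1]} "
      "(global + 3 tissue-like + 6 motion-like)")

cleaned = regress_nuisance(dirty, regressors)
filtered = detrend_and_bandpass(cleaned, 0.01, 0.1, tr_seconds=2.0)
z = fisher_z(pearson_fc(filtered))
features = vectorize(z)
print(f"FC matrix: {z.n_nodes} x {z.n_nodes} (z-space), "
      f"feature vector length {features.values.size}")

z_clean_same_pipeline = vectorize(
    fisher_z(pearson_fc(detrend_and_bandpass(regress_nuisance(clean, regressors))))
).values
err = np.abs(features.values - z_clean_same_pipeline).max()
print(f"max |z difference| vs running the same pipeline on the "
      f"uncontaminated series: {err:.2g}")
print("The injected artifacts lie exactly in the regressor span, so the "
      "clean-up removes them to numerical precision.")
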