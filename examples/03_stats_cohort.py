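"""Hierarchical cohort statistics: pooled fit vs mixed models.

Draws a synthetic 10-participant cohort whose inhibition durations shorten
by 15 ms per extra pps of discharge rate with strong between-participant
intercept variability, then contrasts the pooled regression with the
random-intercept mixed model and its random-slope extension.
"""

import numpy as np
import pandas as pd

from mnpool import (SyntheticCohortSpec, compare_mixed, classify_r2,
                    fit_linear, fit_mixed, hierarchical_cohort)

spec = SyntheticCohortSpec(n_subjects=10, beta1_ms_per_hz=-15.0,
                           intercept_sd_ms=72.0, residual_sd_ms=36.0, seed=2)
participants, truth = hierarchical_cohort(spec)

rates = np.concatenate([p.firing_rate_hz for p in participants])
durs = np.concatenate([p.inhibition_duration_ms for p in participants])
pooled = fit_linear(rates, durs)
print(f"pooled: R^2 = {pooled.r_squared:.2f} ({classify_r2(pooled.r_squared)})")

per = [fit_linear(p.firing_rate_hz, p.inhibition_duration_ms).r_squared
       for p in participants if p.n_units >= 3]
print(f"median per-participant R^2 = {np.median(per):.2f}")

df = pd.DataFrame({"duration": durs, "rate": rates,
                   "subject": np.concatenate(
                       [[p.participant_id] * p.n_units
                        for p in participants])})
m1 = fit_mixed(df, "random-intercept")
m2 = fit_mixed(df, "random-intercept-slope")
cmp_ = compare_mixed(m1, m2)
print(f"model 1: beta1 = {m1.beta1:.1f} ms/Hz "
      f"(CI {m1.beta1_ci[0]:.1f}..{m1.beta1_ci[1]:.1f}), "
      f"ICC_subject = {m1.icc_subject:.2f}")
print(f"LRT p = {cmp_.p_value:.3f} -> keep {cmp_.selected}")

# Participant heterogeneity depresses the pooled R^2 while each participant
# individually shows a clean negative slope; the mixed model recovers the
# generating slope (-15 ms/Hz) and attributes ~80% of the variance to
# between-participant differences (ICC ~ 0.8).  With no true random slope,
# the likelihood-ratio test keeps the simpler model.
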