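"""Published per-subject summary statistics of the 17-subject silicone-seat cohort.

These are the reported summary values (not raw signals — the original
recordings were never deposited) for the validation cohort of 17 subjects
(13 female, 4 male, ages 24–70) recorded for 5 minutes each on the
silicone-electrode toilet seat alongside a chest reference.  They serve as
inputs for re-deriving the cohort-level aggregates: the morphology mean/sd
row and the HRV radar percentages.
"""

from __future__ import annotations

import numpy as np

from seatecg.hrv import HRVSummary

#: Per-subject mean Pearson correlation between matched REF/EXP mean
#: heartbeat waveforms (subjects 1–17).
PCC_PER_SUBJECT = np.array([
    0.88, 0.98, 0.81, 0.95, 0.97, 0.89, 0.86, 0.99, 0.88,
    0.97, 0.98, 0.83, 0.82, 0.99, 0.89, 0.88, 0.87,
])

#: Per-subject range-normalised RMSE (%) between the same waveforms.
NRMSE_PER_SUBJECT = np.array([
    29.26, 19.86, 30.34, 51.65, 49.89, 24.66, 17.45, 61.34, 34.21,
    29.78, 25.65, 12.45, 34.65, 21.45, 57.65, 26.16, 34.07,
])

#: Cohort HRV summaries for the radar comparison: chest reference channel
#: and the silicone thigh channel.  Values as reported (the absolute scale
#: of the NNI-derived entries reflects the original tool's internal units;
#: the radar percentages depend only on ratios).
HRV_REF = HRVSummary(
    mean_nni=28663.5,
    sd1=334.8,
    sdnn=17257.6,
    rmssd=761.1,
    sdsd=323.3,
    nn20=80,
    peak_freq=0.01,
    check_poincare=False,  # SD1 quoted independently in the report
)

HRV_EXP_SILICONE = HRVSummary(
    mean_nni=27050.8,
    sd1=127.89,
    sdnn=15679.9,
    rmssd=797.5,
    sdsd=222.3,
    nn20=72,
    peak_freq=0.01,
    check_poincare=False,
)
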