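"""Heart-rate-variability summaries and REF-vs-EXP radar percentages.

Time-domain statistics are computed on the NN-interval series (seconds
between successive R peaks, reported in ms): mean NNI, SDNN, RMSSD, SDSD,
the Poincaré minor-axis spread SD1 = SDSD/sqrt(2), and NN20 (count of
successive differences exceeding 20 ms).  The spectral peak frequency is
taken from a Welch periodogram of the evenly resampled NN series.  Sample
(n−1) standard deviations are used throughout.

The radar normalisation compares an experimental-channel summary to the
reference channel, expressing each parameter as a signed percentage
deviation with the reference at 100%.
"""

from __future__ import annotations

from dataclasses import InitVar, dataclass, fields

import numpy as np
from scipy import signal as sps

from seatecg.signals import BeatSeries

__all__ = ["HRVSummary", "hrv_summary", "radar_percent"]

#: Resampling rate for the spectral estimate (Hz).
RESAMPLE_FS = 4.0
#: Welch segment length (seconds).
WELCH_SEGMENT = 120.0


@dataclass
class HRVSummary:
    """Time-domain HRV parameters of one channel (ms unless noted).

    ``check_poincare`` enforces the identity SD1 = SDSD/sqrt(2), which holds
    for every summary this package computes; it can be disabled to carry
    externally reported parameter rows that quote SD1 independently.
    """

    mean_nni: float
    sdnn: float
    rmssd: float
    sdsd: float
    sd1: float
    nn20: int
    peak_freq: float
    check_poincare: InitVar[bool] = True

    def __post_init__(self, check_poincare: bool) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")
        if (
            check_poincare
            and self.sdsd > 0
            and abs(self.sd1 - self.sdsd / np.sqrt(2)) > 1e-9 * self.sdsd
        ):
            raise ValueError("sd1 must equal sdsd/sqrt(2)")


def _peak_frequency(beats: BeatSeries) -> float:
    """Dominant frequency of the evenly resampled NN tachogram."""
    nn = beats.nn_intervals
    if nn.size < 4:
        return 0.0
    t_beats = beats.times[1:]  # NN_i is defined at the time of its second peak
    t_even = np.arange(t_beats[0], t_beats[-1], 1.0 / RESAMPLE_FS)
    if t_even.size < 8:
        return 0.0
    tach = np.interp(t_even, t_beats, nn)
    nperseg = min(t_even.size, int(WELCH_SEGMENT * RESAMPLE_FS))
    f, p = sps.welch(tach - tach.mean(), fs=RESAMPLE_FS, nperseg=nperseg)
    return float(f[np.argmax(p)])


def hrv_summary(beats: BeatSeries) -> HRVSummary:
    """Time-domain HRV summary of a beat series (needs >= 3 R peaks)."""
    if len(beats) < 3:
        raise ValueError("HRV summary needs at least 3 R peaks")
    nn_ms = beats.nn_intervals * 1000.0
    d = np.diff(nn_ms)
    sdsd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return HRVSummary(
        mean_nni=float(np.mean(nn_ms)),
        sdnn=float(np.std(nn_ms, ddof=1)),
        rmssd=float(np.sqrt(np.mean(d**2))),
        sdsd=sdsd,
        sd1=sdsd / np.sqrt(2.0),
        nn20=int(np.sum(np.abs(d) > 20.0)),
        peak_freq=_peak_frequency(beats),
    )


def radar_percent(ref: HRVSummary, exp: HRVSummary) -> dict[str, float]:
    """Signed percentage deviation of each parameter, reference at 100%.

    For each parameter p: ``100 * (exp_p - ref_p) / ref_p``.  A parameter
    whose reference value is 0 is flagged NaN rather than raising.
    """
    out: dict[str, float] = {}
    for f in fields(HRVSummary):
        r = float(getattr(ref, f.name))
        e = float(getattr(exp, f.name))
        out[f.name] = 100.0 * (e - r) / r if r != 0 else float("nan")
    return out
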