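"""Per-session rhythm and signal-quality statistics.

For each session the experimental thigh channel is scored against the chest
reference: the fraction of REF QRS complexes the EXP channel reproduces,
the instantaneous heart-rate deviation between channels, the percentage of
session time excluded as saturated or beat-free (signal detection error,
SDE), the time to the first usable EXP beat (TB) and the total saturated
time (TS).  A two-sided Welch t-test compares the two instantaneous-HR
samples.  The module also provides the skin–electrode impedance utility
Z = R * VA / VB used when bench-testing dry-electrode materials.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

from seatecg.preprocess import detect_out_of_range, detect_r_peaks
from seatecg.signals import BeatSeries, SignalRecord

__all__ = [
    "QualityReport",
    "sde",
    "hr_deviation",
    "qrs_ratio",
    "impedance",
    "quality_report",
]

#: Beats in the two channels are considered the same heartbeat when their
#: R peaks fall within this window (seconds).
MATCH_WINDOW = 0.15


@dataclass
class QualityReport:
    """One session's quality row (per-subject summary).

    All percentages are on 0–100; ``tb`` and ``ts`` are in seconds.
    ``p_value`` is the two-sided Welch t-test comparing the EXP and REF
    instantaneous heart-rate samples (a high p-value means the thigh
    channel reproduces the reference rhythm).
    """

    subject_id: str
    qrs_ratio_pct: float
    hr_dev_mean: float
    hr_dev_sd: float
    sde_pct: float
    p_value: float
    tb: float
    ts: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.qrs_ratio_pct <= 100.0:
            raise ValueError("qrs_ratio_pct must lie in [0, 100]")
        if not 0.0 <= self.sde_pct <= 100.0:
            raise ValueError("sde_pct must lie in [0, 100]")
        if self.tb < 0 or self.ts < 0:
            raise ValueError("tb and ts must be >= 0")
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def sde(total_s: float, excluded_s: float) -> float:
    """Signal detection error: percentage of session time excluded.

    ``SDE(%) = (1 - (S - N)/S) * 100 = 100 * N/S`` where S is the total
    signal and N the out-of-range (excluded) signal, both in seconds.
    """
    if total_s <= 0:
        raise ValueError("total_s must be positive")
    if not 0.0 <= excluded_s <= total_s:
        raise ValueError("excluded_s must lie in [0, total_s]")
    return 100.0 * excluded_s / total_s


def _match_beats(
    ref: BeatSeries, exp: BeatSeries, window: float
) -> list[tuple[int, int]]:
    """Greedy one-to-one nearest matching of EXP beats to REF beats."""
    rt, et = ref.times, exp.times
    pairs: list[tuple[float, int, int]] = []
    for j, t in enumerate(et):
        i = int(np.searchsorted(rt, t))
        for k in (i - 1, i):
            if 0 <= k < rt.size and abs(rt[k] - t) <= window:
                pairs.append((abs(rt[k] - t), k, j))
    pairs.sort()
    used_r: set[int] = set()
    used_e: set[int] = set()
    out: list[tuple[int, int]] = []
    for _, k, j in pairs:
        if k in used_r or j in used_e:
            continue
        used_r.add(k)
        used_e.add(j)
        out.append((k, j))
    out.sort()
    return out


def qrs_ratio(ref: BeatSeries, exp: BeatSeries, window: float = MATCH_WINDOW) -> float:
    """Percentage of REF QRS complexes also detected on the EXP channel."""
    if len(ref) == 0:
        raise ValueError("reference series has no beats")
    if len(exp) == 0:
        return 0.0
    matches = _match_beats(ref, exp, window)
    return 100.0 * len(matches) / len(ref)


def _matched_hr_pairs(
    ref: BeatSeries, exp: BeatSeries, window: float
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous HR of both channels over beat pairs that are
    consecutive in both (the only pairs where 60/NN is a heart rate on
    each channel simultaneously)."""
    matches = _match_beats(ref, exp, window)
    hr_ref, hr_exp = [], []
    for (r0, e0), (r1, e1) in zip(matches, matches[1:]):
        if r1 == r0 + 1 and e1 == e0 + 1:
            hr_ref.append(60.0 / ((ref.r_peaks[r1] - ref.r_peaks[r0]) / ref.fs))
            hr_exp.append(60.0 / ((exp.r_peaks[e1] - exp.r_peaks[e0]) / exp.fs))
    return np.asarray(hr_ref), np.asarray(hr_exp)


def hr_deviation(
    ref: BeatSeries, exp: BeatSeries, window: float = MATCH_WINDOW
) -> tuple[float, float, np.ndarray]:
    """Instantaneous heart-rate deviation of EXP relative to REF.

    For every consecutive pair of matched beats present in both channels,
    the instantaneous rate is 60/NN; the deviation is |HR_exp − HR_ref|.
    Returns (mean BPM, sd BPM, per-pair deviations); empty result when
    either channel has fewer than two peaks.
    """
    if len(ref) < 2 or len(exp) < 2:
        return float("nan"), float("nan"), np.empty(0)
    hr_ref, hr_exp = _matched_hr_pairs(ref, exp, window)
    devs_arr = np.abs(hr_exp - hr_ref)
    if devs_arr.size == 0:
        return float("nan"), float("nan"), devs_arr
    sd = float(np.std(devs_arr, ddof=1)) if devs_arr.size > 1 else 0.0
    return float(np.mean(devs_arr)), sd, devs_arr


def matched_beats(
    ref: BeatSeries, exp: BeatSeries, window: float = MATCH_WINDOW
) -> BeatSeries:
    """The subset of EXP beats matched one-to-one to a REF beat.

    Useful for channel comparisons (e.g. HRV) that should be computed on
    genuine heartbeats only, excluding spurious detections on noisy
    stretches of the thigh channel.
    """
    matches = _match_beats(ref, exp, window)
    idx = np.asarray([j for _, j in matches], dtype=int)
    return BeatSeries(exp.r_peaks[np.sort(idx)], exp.fs)


def impedance(R: float, VA: float, VB: float) -> float:
    """Skin–electrode impedance magnitude from the divider bench circuit.

    With a series resistor R (kΩ) and oscilloscope amplitudes VA (across
    the electrode) and VB (across the resistor): Z(kΩ) = R * VA / VB.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    if VB <= 0:
        raise ValueError("VB must be positive")
    return R * VA / VB


def _beat_free_time(exp: BeatSeries, duration: float, window: float = 2.0) -> float:
    """Seconds of session covered by 2 s windows containing no EXP beat."""
    if len(exp) == 0:
        return duration
    edges = np.arange(0.0, duration, window)
    t = exp.times
    free = 0.0
    for lo in edges:
        hi = min(lo + window, duration)
        if not np.any((t >= lo) & (t < hi)):
            free += hi - lo
    return free


def quality_report(
    ref_rec: SignalRecord,
    exp_rec: SignalRecord,
    ref_beats: BeatSeries | None = None,
    exp_beats: BeatSeries | None = None,
) -> QualityReport:
    """Assemble the full per-session quality row from filtered channels.

    The excluded signal N for the SDE combines the out-of-range (saturated)
    runs of the raw EXP channel with beat-free stretches (2 s windows with
    no detectable beat), since noise corruption and saturation both make
    the channel unusable.
    """
    from seatecg.preprocess import bandpass_fir

    duration = exp_rec.duration
    clip = float(exp_rec.meta.get("clip_level", np.max(np.abs(exp_rec.samples))))
    runs = detect_out_of_range(exp_rec, -clip * 0.999, clip * 0.999, min_run=0.1)
    ts = float(sum(d for _, d in runs))

    if ref_beats is None:
        ref_beats = detect_r_peaks(bandpass_fir(ref_rec))
    if exp_beats is None:
        exp_beats = detect_r_peaks(bandpass_fir(exp_rec))

    ratio = qrs_ratio(ref_beats, exp_beats)
    mean_dev, sd_dev, _ = hr_deviation(ref_beats, exp_beats)

    excluded = min(duration, ts + _beat_free_time(exp_beats, duration))
    sde_pct = sde(duration, excluded)

    if len(ref_beats) >= 2 and len(exp_beats) >= 2:
        hr_ref, hr_exp = _matched_hr_pairs(ref_beats, exp_beats, MATCH_WINDOW)
        if hr_ref.size >= 2 and (np.std(hr_ref) > 0 or np.std(hr_exp) > 0):
            p = float(stats.ttest_ind(hr_exp, hr_ref, equal_var=False).pvalue)
        elif hr_ref.size >= 2:
            p = 1.0  # identical constant rates on both channels
        else:
            p = float("nan")
    else:
        p = float("nan")

    # TB: delay from the first reference beat to the first EXP beat matched
    # to a reference beat (0 when the thigh channel is usable from the start)
    matches = _match_beats(ref_beats, exp_beats, MATCH_WINDOW)
    if matches and len(ref_beats) > 0:
        tb = max(
            0.0,
            float(exp_beats.times[matches[0][1]] - ref_beats.times[0]),
        )
    else:
        tb = duration

    return QualityReport(
        subject_id=exp_rec.subject_id,
        qrs_ratio_pct=ratio,
        hr_dev_mean=mean_dev,
        hr_dev_sd=sd_dev,
        sde_pct=sde_pct,
        p_value=p,
        tb=tb,
        ts=ts,
    )
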