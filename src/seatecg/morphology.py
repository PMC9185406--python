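"""Heartbeat-template extraction and waveform-morphology scoring.

A template is a fixed window around an R peak (default 0.2 s before to
0.4 s after, covering P-QRS-T at normal rates).  Thigh-channel templates
are validated against the reference channel: EXP cycles anchored at
REF-matched beats are correlated with the mean REF cycle and rejected as
outliers below a correlation threshold.  Channel similarity is scored with
the Pearson correlation coefficient (PCC) and the range-normalised RMSE
between matched waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from seatecg.signals import BeatSeries, SignalRecord

__all__ = [
    "TemplateSet",
    "extract_templates",
    "reject_outliers",
    "pcc",
    "nrmse",
    "morphology_report",
]

#: Default template window around the R peak, seconds.
PRE_WINDOW = 0.2
POST_WINDOW = 0.4


@dataclass
class TemplateSet:
    """Fixed-length heartbeat waveforms for one subject/channel.

    ``templates`` has shape (n_beats, window_len) with the R sample at
    index ``round(pre * fs)``.  ``valid_mask`` marks templates that
    survived outlier rejection; ``r_peaks`` records the anchor index of
    each template in the originating signal.
    """

    templates: np.ndarray
    fs: float
    window: tuple[float, float] = (PRE_WINDOW, POST_WINDOW)
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    subject_id: str = ""
    channel_role: str = "REF"
    r_peaks: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.templates = np.atleast_2d(np.asarray(self.templates, dtype=float))
        expected = round((self.window[0] + self.window[1]) * self.fs) + 1
        if self.templates.size and self.templates.shape[1] != expected:
            raise ValueError(
                f"template length {self.templates.shape[1]} != window {expected}"
            )
        if self.valid_mask is None:
            self.valid_mask = np.ones(len(self), dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.r_peaks is None:
            self.r_peaks = np.full(len(self), -1, dtype=np.int64)

    def __len__(self) -> int:
        return 0 if self.templates.size == 0 else self.templates.shape[0]

    @property
    def valid(self) -> np.ndarray:
        """The valid templates only, shape (n_valid, window_len)."""
        return self.templates[self.valid_mask]

    def mean_waveform(self) -> np.ndarray:
        """Mean of the valid templates."""
        if not self.valid_mask.any():
            raise ValueError("no valid templates")
        return self.valid.mean(axis=0)


def extract_templates(
    rec: SignalRecord,
    beats: BeatSeries,
    pre: float = PRE_WINDOW,
    post: float = POST_WINDOW,
) -> TemplateSet:
    """Cut one fixed window per R peak whose window fits inside the record.

    Beats too close to either end of the record are skipped.  An empty set
    (no beat with a full window) is returned flagged rather than raised.
    """
    if len(beats) == 0:
        raise ValueError("beat series is empty")
    n_pre = round(pre * rec.fs)
    n_post = round(post * rec.fs)
    rows, anchors = [], []
    for p in beats.r_peaks:
        if p - n_pre >= 0 and p + n_post < rec.samples.size:
            rows.append(rec.samples[p - n_pre : p + n_post + 1])
            anchors.append(int(p))
    templates = np.asarray(rows) if rows else np.empty((0, n_pre + n_post + 1))
    return TemplateSet(
        templates=templates,
        fs=rec.fs,
        window=(pre, post),
        subject_id=rec.subject_id,
        channel_role=rec.channel_role,
        r_peaks=np.asarray(anchors, dtype=np.int64),
    )


def reject_outliers(
    exp: TemplateSet, ref: TemplateSet, min_corr: float = 0.8
) -> TemplateSet:
    """Invalidate EXP cycles poorly correlated with the mean REF cycle.

    The two sets must cover the same beats one-to-one (EXP cycles anchored
    at REF-matched R peaks).  Each EXP template whose Pearson correlation
    with the mean REF waveform falls below ``min_corr`` is marked invalid.
    """
    if len(exp) == 0 or len(ref) == 0:
        raise ValueError("no matched template pairs")
    if len(exp) != len(ref):
        raise ValueError("template sets must pair one-to-one")
    anchor = ref.mean_waveform()
    mask = np.array(
        [_safe_corr(row, anchor) >= min_corr for row in exp.templates], dtype=bool
    )
    return replace(exp, valid_mask=mask)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def select_best_templates(
    exp: TemplateSet, ref: TemplateSet, n: int
) -> TemplateSet:
    """Keep the ``n`` EXP cycles best correlated with the mean REF cycle.

    Like :func:`reject_outliers` but rank-based: useful when a fixed number
    of usable templates per subject is needed (e.g. for identification
    protocols) regardless of where a noisy session's correlation
    distribution sits relative to a hard threshold.  Temporal order is
    preserved; all returned templates are marked valid.
    """
    if len(exp) == 0 or len(ref) == 0:
        raise ValueError("no matched template pairs")
    if len(exp) != len(ref):
        raise ValueError("template sets must pair one-to-one")
    anchor = ref.mean_waveform()
    corr = np.array([_safe_corr(row, anchor) for row in exp.templates])
    keep = np.sort(np.argsort(corr)[::-1][: min(n, len(exp))])
    return replace(
        exp,
        templates=exp.templates[keep],
        valid_mask=np.ones(keep.size, dtype=bool),
        r_peaks=exp.r_peaks[keep],
    )


def pcc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson product-moment correlation between two waveforms."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("waveforms must have equal length >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for a constant waveform")
    return float(np.corrcoef(a, b)[0, 1])


def nrmse(ref: np.ndarray, exp: np.ndarray) -> float:
    """RMSE between waveforms, as a percentage of the reference range."""
    ref = np.asarray(ref, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if ref.shape != exp.shape:
        raise ValueError("waveforms must have equal length")
    rng = float(np.max(ref) - np.min(ref))
    if rng == 0:
        raise ValueError("reference waveform has zero range")
    return 100.0 * float(np.sqrt(np.mean((ref - exp) ** 2))) / rng


def morphology_report(
    per_subject: dict[str, np.ndarray | float] | list,
) -> tuple[float, float]:
    """Cohort mean and sd of a per-subject morphology metric.

    Accepts per-subject scalars or lists (a list is reduced to its mean
    first), then returns the arithmetic mean and sample sd across subjects.
    A single subject yields sd 0.
    """
    values = per_subject.values() if isinstance(per_subject, dict) else per_subject
    means = [float(np.mean(v)) for v in values]
    if not means:
        raise ValueError("need at least one subject")
    sd = float(np.std(means, ddof=1)) if len(means) > 1 else 0.0
    return float(np.mean(means)), sd
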