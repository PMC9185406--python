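"""Synthetic paired REF/EXP ECG sessions.

The generator renders each heartbeat as a sum of five Gaussian bumps (P, Q,
R, S, T), a standard simplification of the dynamical ECG model that is
adequate for morphology-correlation and template-classification work.  A
subject is a draw of per-wave amplitude/width/latency parameters around a
canonical beat, plus a mean heart rate and its variability; the thigh (EXP)
channel is the chest (REF) channel after amplitude attenuation, additive
broadband noise, baseline wander, powerline interference, recorder clipping
during saturation episodes, and an optional delayed onset during which the
channel sits at the recorder rail.

Both channels share the same underlying R-peak times, which are returned as
ground truth in the records' metadata — this is what makes every downstream
detector and quality metric testable without real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from seatecg.signals import SignalRecord

# Canonical beat: (amplitude [a.u.], latency from R [s], Gaussian width [s])
# Amplitudes are relative to an R wave of 1; timings follow normal adult
# intervals (PR ~ 0.16 s, QT ~ 0.36 s at 60 BPM).
CANONICAL_WAVES: dict[str, tuple[float, float, float]] = {
    "P": (0.15, -0.22, 0.025),
    "Q": (-0.10, -0.035, 0.010),
    "R": (1.00, 0.0, 0.012),
    "S": (-0.18, 0.035, 0.012),
    "T": (0.35, 0.28, 0.045),
}

# Per-subject sampling ranges: multiplicative jitter on amplitude and width,
# additive jitter on latency (s).  R latency stays 0 (it anchors the beat)
# and its amplitude varies mildly so it remains the unique global maximum.
_WAVE_JITTER: dict[str, tuple[float, float, float]] = {
    "P": (0.45, 0.30, 0.030),
    "Q": (0.50, 0.30, 0.010),
    "R": (0.15, 0.25, 0.000),
    "S": (0.50, 0.30, 0.010),
    "T": (0.40, 0.30, 0.040),
}

#: Recorder full-scale used for saturation clipping, arbitrary units.
DEFAULT_CLIP_LEVEL = 1.0


@dataclass
class SubjectProfile:
    """Per-subject cardiac parameters for the generator.

    ``morphology_params`` maps wave name -> (amplitude, latency s, width s).
    ``sex_hair_factor`` in [0, 1] scales thigh-channel degradation the way
    androgenic body hair degrades dry-electrode contact: it shrinks the
    effective attenuation gain and inflates the noise floor.
    """

    subject_id: str
    heart_rate_mean: float = 70.0
    heart_rate_sd: float = 3.0
    morphology_params: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(CANONICAL_WAVES)
    )
    sex_hair_factor: float = 0.0

    def __post_init__(self) -> None:
        if not 40.0 <= self.heart_rate_mean <= 180.0:
            raise ValueError("heart_rate_mean must lie in [40, 180] BPM")
        if self.heart_rate_sd < 0:
            raise ValueError("heart_rate_sd must be >= 0")
        if not 0.0 <= self.sex_hair_factor <= 1.0:
            raise ValueError("sex_hair_factor must lie in [0, 1]")


@dataclass
class DegradationSpec:
    """Thigh-channel degradation applied on top of the clean beat train.

    All times are in seconds relative to session start; saturation episodes
    must lie inside the session.  ``attenuation_gain`` is the EXP amplitude
    relative to REF (< 1 for a thigh lead, where ECG amplitudes drop to the
    microvolt range); ``clip_level`` is the symmetric recorder full scale.
    """

    attenuation_gain: float = 0.4
    noise_sd: float = 0.0
    baseline_wander_amp: float = 0.0
    baseline_wander_freq: float = 0.25
    saturation_episodes: list[tuple[float, float]] = field(default_factory=list)
    onset_delay: float = 0.0
    powerline_amp: float = 0.0
    powerline_freq: float = 50.0
    clip_level: float = DEFAULT_CLIP_LEVEL

    def __post_init__(self) -> None:
        if self.attenuation_gain <= 0:
            raise ValueError("attenuation_gain must be > 0")
        if self.onset_delay < 0:
            raise ValueError("onset_delay must be >= 0")
        for start, dur in self.saturation_episodes:
            if start < 0 or dur < 0:
                raise ValueError("saturation episode times must be >= 0")


def typical_degradation() -> DegradationSpec:
    """Degradation profile of a typical thigh session.

    Calibrated so that a 5-min session shows the quality levels reported
    for seat-acquired thigh ECG: roughly three-quarters to four-fifths of
    reference QRS complexes recovered, ~15% of session time excluded as
    saturated or beat-free, tens-to-hundreds of morphology-valid heartbeat
    cycles, and a delayed usable onset of a couple of seconds.
    """
    return DegradationSpec(
        attenuation_gain=0.4,
        noise_sd=0.06,
        baseline_wander_amp=0.1,
        baseline_wander_freq=0.25,
        saturation_episodes=[(60.0, 15.0), (200.0, 10.0)],
        onset_delay=2.0,
        powerline_amp=0.03,
    )


def clean_degradation() -> DegradationSpec:
    """All-zero degradation: EXP is exactly attenuation_gain x REF."""
    return DegradationSpec(attenuation_gain=0.4)


def render_template(
    profile: SubjectProfile,
    fs: float = 1000.0,
    pre: float = 0.3,
    post: float = 0.45,
) -> np.ndarray:
    """Render one noise-free beat of a subject on a [-pre, post] s window."""
    t = np.arange(-round(pre * fs), round(post * fs) + 1) / fs
    out = np.zeros_like(t)
    for amp, lat, width in profile.morphology_params.values():
        out += amp * np.exp(-0.5 * ((t - lat) / width) ** 2)
    return out


def _sample_profile(subject_id: str, rng: np.random.Generator) -> SubjectProfile:
    waves: dict[str, tuple[float, float, float]] = {}
    for name, (amp, lat, width) in CANONICAL_WAVES.items():
        da, dw, dl = _WAVE_JITTER[name]
        waves[name] = (
            amp * (1.0 + rng.uniform(-da, da)),
            lat + rng.uniform(-dl, dl),
            width * (1.0 + rng.uniform(-dw, dw)),
        )
    return SubjectProfile(
        subject_id=subject_id,
        heart_rate_mean=rng.uniform(55.0, 95.0),
        heart_rate_sd=rng.uniform(1.0, 5.0),
        morphology_params=waves,
        sex_hair_factor=float(rng.uniform(0.0, 0.3)),
    )


def make_population(n_subjects: int, seed: int) -> list[SubjectProfile]:
    """Draw ``n_subjects`` distinct subject profiles, deterministically.

    Profiles are redrawn (bounded retries) until all pairwise correlations
    of their clean rendered templates fall below 0.999, so no two subjects
    are morphological twins.  Identification needs at least two classes.
    """
    if n_subjects < 2:
        raise ValueError("identification needs at least 2 subjects")
    if n_subjects > 50:
        raise ValueError("n_subjects must be <= 50")
    rng = np.random.default_rng(seed)
    profiles: list[SubjectProfile] = []
    templates: list[np.ndarray] = []
    i = 0
    while len(profiles) < n_subjects:
        prof = _sample_profile(f"S{len(profiles) + 1:02d}", rng)
        tpl = render_template(prof)
        if all(np.corrcoef(tpl, other)[0, 1] < 0.999 for other in templates):
            profiles.append(prof)
            templates.append(tpl)
        i += 1
        if i > 100 * n_subjects:  # pragma: no cover - defensive
            raise RuntimeError("could not draw distinct profiles")
    return profiles


def _beat_times(
    profile: SubjectProfile, duration: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian RR interval train, floored at 0.3 s."""
    rr_mean = 60.0 / profile.heart_rate_mean
    # delta-method conversion of HR sd (BPM) to RR sd (s)
    rr_sd = 60.0 * profile.heart_rate_sd / profile.heart_rate_mean**2
    times = []
    t = rr_mean / 2.0
    while t < duration:
        times.append(t)
        t += max(0.3, rng.normal(rr_mean, rr_sd))
    return np.asarray(times)


def _render_beat_train(
    profile: SubjectProfile, beat_times: np.ndarray, n: int, fs: float
) -> np.ndarray:
    sig = np.zeros(n)
    for amp, lat, width in profile.morphology_params.values():
        # each wave contributes only within +-5 sigma of its centre
        half = int(np.ceil(5 * width * fs))
        for bt in beat_times:
            c = (bt + lat) * fs
            lo = max(0, int(np.floor(c)) - half)
            hi = min(n, int(np.ceil(c)) + half + 1)
            if lo >= hi:
                continue
            t = (np.arange(lo, hi) - c) / fs
            sig[lo:hi] += amp * np.exp(-0.5 * (t / width) ** 2)
    return sig


def synth_session(
    profile: SubjectProfile,
    degr: DegradationSpec,
    duration: float = 300.0,
    fs: float = 1000.0,
    seed: int = 0,
) -> tuple[SignalRecord, SignalRecord]:
    """Render one paired session: clean REF channel and degraded EXP channel.

    Returns ``(ref, exp)`` records sharing the same underlying R-peak train;
    ground-truth peak indices are stored in ``meta["r_peaks_true"]`` of both.
    The EXP channel is ``gain * REF + noise + wander + powerline``, pinned to
    the recorder rail inside saturation episodes and before ``onset_delay``.
    """
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    if duration <= 0:
        raise ValueError("duration must be positive")
    for start, dur in degr.saturation_episodes:
        if start + dur > duration:
            raise ValueError("saturation episode outside the session")
    if degr.onset_delay > duration:
        raise ValueError("onset_delay exceeds the session")

    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    beat_times = _beat_times(profile, duration, rng)
    ref = _render_beat_train(profile, beat_times, n, fs)
    r_true = np.round(beat_times * fs).astype(np.int64)
    r_true = r_true[r_true < n]

    # body hair degrades dry-electrode contact: it raises the noise floor
    # (the rendered amplitude itself is a subject morphology parameter)
    hair = profile.sex_hair_factor
    exp = degr.attenuation_gain * ref
    t = np.arange(n) / fs
    if degr.noise_sd > 0:
        exp = exp + rng.normal(0.0, degr.noise_sd * (1.0 + 2.0 * hair), n)
    if degr.baseline_wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        exp = exp + degr.baseline_wander_amp * np.sin(
            2 * np.pi * degr.baseline_wander_freq * t + phase
        )
    if degr.powerline_amp > 0:
        exp = exp + degr.powerline_amp * np.sin(2 * np.pi * degr.powerline_freq * t)

    clip = degr.clip_level
    exp = np.clip(exp, -clip, clip)
    for start, dur in degr.saturation_episodes:
        i0, i1 = int(round(start * fs)), int(round((start + dur) * fs))
        exp[i0:i1] = clip
    if degr.onset_delay > 0:
        exp[: int(round(degr.onset_delay * fs))] = clip

    meta = {"r_peaks_true": r_true, "clip_level": clip}
    ref_rec = SignalRecord(ref, fs, "REF", profile.subject_id, meta=dict(meta))
    exp_rec = SignalRecord(exp, fs, "EXP", profile.subject_id, meta=dict(meta))
    return ref_rec, exp_rec


def synth_sync_events(
    duration: float,
    n_events: int,
    seed: int = 0,
    offset: float = 0.0,
    jitter_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Optical synchronisation events: LED flash times and LUX arrival times.

    The seat's LED and the reference device's luminosity sensor record the
    same physical flashes on two unsynchronised clocks; LUX times equal LED
    times plus a constant inter-device offset (optionally jittered).  The
    offset is what :func:`seatecg.preprocess.align_sessions` recovers.
    """
    if n_events < 1:
        raise ValueError("need at least one sync event")
    rng = np.random.default_rng(seed)
    led = np.sort(rng.uniform(0.0, duration, n_events))
    lux = led + offset
    if jitter_sd > 0:
        lux = lux + rng.normal(0.0, jitter_sd, n_events)
    return led, lux


def degraded_for(profile: SubjectProfile, base: DegradationSpec | None = None,
                 seed: int = 0, duration: float = 300.0) -> DegradationSpec:
    """Per-subject variation of a base degradation (episode placement)."""
    base = base or typical_degradation()
    rng = np.random.default_rng(seed)
    episodes = []
    for _ in base.saturation_episodes:
        dur = float(rng.uniform(2.0, min(30.0, duration / 4)))
        start = float(rng.uniform(0.1 * duration, 0.9 * duration - dur))
        episodes.append((start, dur))
    return replace(base, saturation_episodes=episodes)
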