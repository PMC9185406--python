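"""Shared fixtures: synthetic populations, sessions and template sets.

Everything is generated at test time from fixed seeds; sessions used by
several tests are session-scoped so rendering and peak detection run once.
Identification fixtures run at 250 Hz to keep template sizes (151 samples)
and classifier training desk-scale.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from seatecg import (
    make_population,
    synth_session,
    bandpass_fir,
    detect_r_peaks,
    extract_templates,
)
from seatecg.morphology import select_best_templates
from seatecg.synth import clean_degradation, typical_degradation

FS = 250.0


def build_template_sets(n_subjects, seed, degr, fs=FS, duration=300.0, cap=90):
    """Render a population and return per-subject EXP template sets.

    EXP cycles are anchored at reference-detected R peaks and the ``cap``
    best-correlated cycles per subject are kept, mimicking the full
    analysis chain's valid-template selection.
    """
    sets = {}
    for i, prof in enumerate(make_population(n_subjects, seed)):
        ref, exp = synth_session(prof, degr, duration, fs, seed=seed * 100 + i)
        ref_f, exp_f = bandpass_fir(ref), bandpass_fir(exp)
        ref_beats = detect_r_peaks(ref_f)
        ref_t = extract_templates(ref_f, ref_beats)
        exp_t = extract_templates(exp_f, ref_beats)
        sets[prof.subject_id] = select_best_templates(exp_t, ref_t, cap)
    return sets


@pytest.fixture(scope="session")
def clean_session():
    """One zero-degradation 5-min paired session at 250 Hz."""
    prof = make_population(2, seed=11)[0]
    return synth_session(prof, clean_degradation(), 300.0, FS, seed=11)


@pytest.fixture(scope="session")
def clean_beats(clean_session):
    ref, exp = clean_session
    return (
        detect_r_peaks(bandpass_fir(ref)),
        detect_r_peaks(bandpass_fir(exp)),
    )


@pytest.fixture(scope="session")
def clean_sets4():
    """Template sets for a clean, morphologically distinct 4-subject cohort."""
    return build_template_sets(4, seed=5, degr=clean_degradation())


@pytest.fixture(scope="session")
def degraded_sets17():
    """Template sets for the full 17-subject cohort at typical degradation."""
    return build_template_sets(17, seed=7, degr=typical_degradation(), cap=90)
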