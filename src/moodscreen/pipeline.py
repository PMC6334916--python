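"""End-to-end glue: raw recordings → per-phase feature tables → results."""

from __future__ import annotations

import pandas as pd

from .features import extract_phase_features
from .kinematics import ImuRecording, process_recording
from .segmentation import PHASE_ORDER, segment_phases
from .synth import Cohort


def recording_features(
    recording: ImuRecording,
    startle_time_s: float,
    phases: tuple[str, ...] = PHASE_ORDER,
    **front_end_kwargs,
) -> dict[str, pd.Series]:
    """All 174 features for each requested phase of one recording."""
    channels = process_recording(recording, **front_end_kwargs)
    segments = segment_phases(channels, startle_time_s)
    return {ph: extract_phase_features(segments[ph]) for ph in phases}


def cohort_feature_tables(
    cohort: Cohort,
    phases: tuple[str, ...] = PHASE_ORDER,
    **front_end_kwargs,
) -> tuple[dict[str, pd.DataFrame], pd.Series]:
    """Feature table per phase for a synthetic cohort.

    Returns ``(tables, labels)`` where ``tables[phase]`` is a
    subjects × 174 DataFrame indexed by subject id.
    """
    rows: dict[str, dict[str, pd.Series]] = {ph: {} for ph in phases}
    for subject in cohort.subjects:
        feats = recording_features(
            subject.recording, subject.startle_time_s, phases=phases,
            **front_end_kwargs,
        )
        for ph in phases:
            rows[ph][subject.subject_id] = feats[ph]
    tables = {
        ph: pd.DataFrame.from_dict(rows[ph], orient="index") for ph in phases
    }
    return tables, cohort.labels


GAMMA_FAMILY_PREFIXES = ("gamma_", "omegav_")


def gamma_family_count(feature_names) -> int:
    """How many of the given features describe heading (yaw angle or
    vertical angular rate)."""
    return sum(
        any(name.startswith(p) for p in GAMMA_FAMILY_PREFIXES)
        for name in feature_names
    )
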