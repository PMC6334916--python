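"""Synthetic two-group cohorts for end-to-end pipeline testing.

Real recordings of children performing the task cannot be shared, so
this module generates cohorts with the task's qualitative structure:
21 cases and 41 controls by default, each a ~55 s, 100 Hz waist-IMU
recording with a startle event at 30 s.  The generator works in the
inverse direction — it prescribes the world-frame orientation
trajectory and synthesises the device-frame accelerometer/gyroscope
signals from it — so the ground-truth kinematics are exact and the
analysis pipeline can be checked against them.

The planted group difference mirrors the avoidance phenomenology: case
subjects execute a large smooth yaw turn (sigmoidal, final heading
~160° ± 30°, clipped to [90°, 350°]) beginning half-way through the
Potential Threat window, while controls wander mildly (final heading
~30° ± 20°, clipped below 58°).  Both groups share postural sway
(sinusoidal tilt), sensor noise, and an identical-in-distribution
startle jolt (0.3 s damped 8–15 Hz acceleration burst) — the jolt
carries no diagnostic signal on purpose.

All randomness flows from one master seed through per-subject
substreams, so cohorts are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .kinematics import ImuRecording
from .segmentation import PHASE_WINDOWS


class SynthError(ValueError):
    pass


@dataclass
class CohortSpec:
    """Generator configuration; defaults are the study conditions."""

    n_case: int = 21
    n_control: int = 41
    sample_rate_hz: float = 100.0
    duration_s: float = 55.0
    startle_time_s: float = 30.0
    # yaw-turn effect
    case_yaw_mean: float = 160.0
    case_yaw_sd: float = 30.0
    case_yaw_clip: tuple[float, float] = (90.0, 350.0)
    control_yaw_mean: float = 30.0
    control_yaw_sd: float = 20.0
    control_yaw_clip: tuple[float, float] = (0.0, 58.0)
    turn_onset_frac: float = 0.5  # fraction of the Potential Threat window
    turn_tau_s: float = 1.2
    # nuisance structure
    sway_amp_deg: float = 3.0
    sway_freq_hz: float = 0.25
    accel_noise_g: float = 0.02
    gyro_noise_dps: float = 1.0
    jolt_amp_g: float = 0.5
    jolt_decay_s: float = 0.08

    def validate(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise SynthError("group sizes must be >= 1")
        if not 0.0 <= self.turn_onset_frac <= 1.0:
            raise SynthError("turn_onset_frac must lie in [0, 1]")
        for name in ("accel_noise_g", "gyro_noise_dps", "sway_amp_deg",
                     "jolt_amp_g"):
            if getattr(self, name) < 0:
                raise SynthError(f"{name} must be >= 0")
        pt_start, pt_end = PHASE_WINDOWS["PotentialThreat"]
        if self.startle_time_s + pt_start < 0:
            raise SynthError("startle too early: Potential Threat not covered")
        if self.startle_time_s + PHASE_WINDOWS["ResponseModulation"][1] > self.duration_s:
            raise SynthError("recording too short for Response Modulation")

    @property
    def n_subjects(self) -> int:
        return self.n_case + self.n_control


def _yaw_trajectory(t: np.ndarray, spec: CohortSpec, group: str,
                    rng: np.random.Generator) -> np.ndarray:
    """Smooth signed heading trajectory (degrees)."""
    if group == "case":
        mean, sd = spec.case_yaw_mean, spec.case_yaw_sd
        lo, hi = spec.case_yaw_clip
    elif group == "control":
        mean, sd = spec.control_yaw_mean, spec.control_yaw_sd
        lo, hi = spec.control_yaw_clip
    else:
        raise SynthError(f"unknown group {group!r}")
    final = float(np.clip(rng.normal(mean, sd), lo, hi))
    sign = 1.0 if rng.random() < 0.5 else -1.0
    pt_start = spec.startle_time_s + PHASE_WINDOWS["PotentialThreat"][0]
    pt_len = np.diff(PHASE_WINDOWS["PotentialThreat"])[0]
    t0 = pt_start + spec.turn_onset_frac * pt_len
    return sign * final / (1.0 + np.exp(-(t - t0) / spec.turn_tau_s))


def simulate_subject(
    group: str, spec: CohortSpec, seed: int | np.random.Generator,
) -> tuple[ImuRecording, float]:
    """One synthetic subject: (recording, startle_time_s).

    The device-frame gyro is the exact body rate of the prescribed
    orientation trajectory; the accelerometer reads gravity in the
    device frame plus the startle jolt and white noise.
    """
    spec.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = spec.sample_rate_hz
    n = int(round(spec.duration_s * fs)) + 1
    t = np.arange(n) / fs

    psi = _yaw_trajectory(t, spec, group, rng)

    # postural sway: sinusoidal tilt about a random horizontal axis
    beta = rng.uniform(0, 2 * np.pi)
    phase0 = rng.uniform(0, 2 * np.pi)
    theta = np.radians(spec.sway_amp_deg) * np.sin(
        2 * np.pi * spec.sway_freq_hz * t + phase0
    )
    axis = np.array([np.cos(beta), np.sin(beta), 0.0])
    r_tilt = Rotation.from_rotvec(theta[:, None] * axis[None, :])
    r_yaw = Rotation.from_euler("z", psi[:, None], degrees=True)
    rot = r_yaw * r_tilt  # device -> world

    # exact body-frame angular rate from successive rotations
    rel = rot[:-1].inv() * rot[1:]
    gyro = np.vstack([rel.as_rotvec() * fs, np.zeros(3)])
    gyro[-1] = gyro[-2]
    gyro = np.degrees(gyro)

    # specific force: gravity resolved into the device frame (+1 g up)
    accel = rot.inv().apply(np.array([0.0, 0.0, 1.0]))

    # startle jolt: damped 8-15 Hz burst on a random device axis
    if spec.jolt_amp_g > 0:
        f_j = rng.uniform(8.0, 15.0)
        ax_j = rng.normal(size=3)
        ax_j /= np.linalg.norm(ax_j)
        tj = t - spec.startle_time_s
        burst = np.where(
            (tj >= 0) & (tj < 0.3),
            spec.jolt_amp_g * np.exp(-np.maximum(tj, 0) / spec.jolt_decay_s)
            * np.sin(2 * np.pi * f_j * tj),
            0.0,
        )
        accel = accel + burst[:, None] * ax_j[None, :]

    if spec.accel_noise_g > 0:
        accel = accel + rng.normal(0.0, spec.accel_noise_g, (n, 3))
    if spec.gyro_noise_dps > 0:
        gyro = gyro + rng.normal(0.0, spec.gyro_noise_dps, (n, 3))

    rec = ImuRecording(time=t, accel=accel, gyro=gyro,
                       sample_rate_hz=fs, accel_units="g")
    return rec, spec.startle_time_s


@dataclass
class Subject:
    subject_id: str
    group: str  # "case" | "control"
    recording: ImuRecording
    startle_time_s: float
    seed: int

    @property
    def label(self) -> int:
        return 1 if self.group == "case" else 0


@dataclass
class Cohort:
    spec: CohortSpec
    seed: int
    subjects: list[Subject]

    @property
    def labels(self) -> pd.Series:
        return pd.Series({s.subject_id: s.label for s in self.subjects})

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"subject_id": s.subject_id, "group": s.group, "seed": s.seed,
              "startle_time_s": s.startle_time_s} for s in self.subjects]
        )


def simulate_cohort(spec: CohortSpec, seed: int) -> Cohort:
    """Simulate all subjects (cases first, then controls) with
    independent substreams spawned from the master seed."""
    spec.validate()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(spec.n_subjects)
    subjects: list[Subject] = []
    groups = ["case"] * spec.n_case + ["control"] * spec.n_control
    for i, (group, child) in enumerate(zip(groups, children)):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        rec, startle = simulate_subject(group, spec, np.random.default_rng(child))
        subjects.append(Subject(
            subject_id=f"S{i + 1:03d}", group=group, recording=rec,
            startle_time_s=startle, seed=sub_seed,
        ))
    return Cohort(spec=spec, seed=seed, subjects=subjects)


# ---------------------------------------------------------------------------
# statistical shortcut: feature tables without signal synthesis
# ---------------------------------------------------------------------------

def simulate_feature_table(
    n_case: int,
    n_control: int,
    n_features: int,
    effects: dict[str, float] | None = None,
    seed: int | None = None,
    feature_prefix: str = "f",
) -> tuple[pd.DataFrame, pd.Series]:
    """Gaussian feature table with optionally planted group effects.

    All features are standard normal; ``effects`` maps feature names
    (``f000`` style) to a case-minus-control mean gap in SD units.
    Returns (X, y) with cases first (label 1).
    """
    rng = np.random.default_rng(seed)
    n = n_case + n_control
    names = [f"{feature_prefix}{i:03d}" for i in range(n_features)]
    X = pd.DataFrame(rng.standard_normal((n, n_features)), columns=names,
                     index=[f"S{i + 1:03d}" for i in range(n)])
    y = pd.Series([1] * n_case + [0] * n_control, index=X.index)
    for name, gap in (effects or {}).items():
        if name not in X.columns:
            raise SynthError(f"unknown feature {name!r} in effects")
        X.loc[y == 1, name] += gap
    return X, y


def simulate_cbcl(
    labels: pd.Series,
    case_mean: float = 62.0,
    case_sd: float = 8.0,
    control_mean: float = 50.0,
    control_sd: float = 8.0,
    seed: int | None = None,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Synthetic CBCL T scores (three scales) for labelled subjects.

    Scores are group-specific normals truncated to the plausible T-score
    range [20, 100]; scales are drawn independently.  ``missing_rate``
    knocks out entries at random (tracked downstream by listwise
    exclusion).
    """
    from .cbcl import SCALES

    rng = np.random.default_rng(seed)
    y = np.asarray(labels)
    n = len(y)
    data: dict[str, np.ndarray] = {}
    for scale in SCALES:
        mean = np.where(y == 1, case_mean, control_mean)
        sd = np.where(y == 1, case_sd, control_sd)
        vals = np.clip(rng.normal(mean, sd), 20.0, 100.0)
        if missing_rate > 0:
            vals = np.where(rng.random(n) < missing_rate, np.nan, vals)
        data[scale] = vals
    df = pd.DataFrame(data, index=labels.index)
    df["diagnosis"] = y
    return df
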