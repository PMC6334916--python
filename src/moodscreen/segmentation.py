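"""Segmentation of the task time series into its three conceptual phases.

The mood-induction task is anchored on the startle moment (the reveal of
the fake snake).  Relative to that event the phases are:

* Potential Threat   — [-23 s, -3 s): anticipation while approaching,
* Startle            — [-3 s, +3 s): the reveal itself,
* Response Modulation — [+3 s, +23 s): the regulation period after.

Windows are half-open on the right so boundary samples belong to the
later phase; at 100 Hz the segments hold exactly 2000 / 600 / 2000
samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import KinematicChannels

#: phase name -> (start, end) in seconds relative to the startle moment
PHASE_WINDOWS: dict[str, tuple[float, float]] = {
    "PotentialThreat": (-23.0, -3.0),
    "Startle": (-3.0, 3.0),
    "ResponseModulation": (3.0, 23.0),
}

PHASE_ORDER = tuple(PHASE_WINDOWS)


class SegmentationError(ValueError):
    """Raised when a recording does not cover a requested phase window."""


@dataclass
class PhaseSegment:
    phase: str
    channels: KinematicChannels
    window: tuple[float, float]  # seconds relative to the startle moment

    @property
    def n_samples(self) -> int:
        return self.channels.n_samples


def segment_phases(
    channels: KinematicChannels, startle_time: float
) -> dict[str, PhaseSegment]:
    """Cut the six-channel series into the three phases.

    ``startle_time`` is the annotated event time on the recording's own
    time axis.  Raises :class:`SegmentationError` naming the first phase
    whose window is not fully covered by the recording.
    """
    t = channels.time
    dt = 1.0 / channels.rate_hz
    eps = 1e-9
    segments: dict[str, PhaseSegment] = {}
    for phase, (rel_start, rel_end) in PHASE_WINDOWS.items():
        start = startle_time + rel_start
        end = startle_time + rel_end
        if start < t[0] - eps:
            raise SegmentationError(
                f"{phase} window begins at {start:.3f} s, before the recording"
                f" start ({t[0]:.3f} s)"
            )
        if end - dt > t[-1] + eps:
            raise SegmentationError(
                f"{phase} window ends at {end:.3f} s, after the recording"
                f" end ({t[-1]:.3f} s)"
            )
        i0 = int(np.searchsorted(t, start - eps, side="left"))
        i1 = int(np.searchsorted(t, end - eps, side="left"))
        segments[phase] = PhaseSegment(
            phase=phase,
            channels=channels.slice(i0, i1),
            window=(rel_start, rel_end),
        )
    return segments
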