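"""Per-channel time-series feature extraction (29 features per channel).

Each phase segment yields, for each of the six kinematic channels, a
fixed-order vector of 29 features:

* 9 amplitude statistics — mean, RMS, skew, kurtosis (non-excess),
  range, max, min, SD (n-1 divisor), peak-to-RMS ratio;
* 7 band powers from the one-sided periodogram of the mean-removed
  series — 0–0.5, 0.5–1.5, 1.5–5, 5–10, 10–15, 15–20 and >20 Hz;
* locations and heights of the first 6 periodogram peaks, ordered by
  ascending frequency, zero-padded when fewer exist (12 values);
* the autocorrelation height at zero lag (biased autocovariance, i.e.
  the mean squared deviation from the series mean).

Six channels × 29 features = 174 features per phase.  Names follow
``<channel>_<feature>``, e.g. ``gamma_rms``, ``av_peak6_loc``,
``gamma_band2_power``, ``gamma_autocorr0_height``; the order is fixed
and identical across runs.

Degenerate inputs map to finite values: skew/kurtosis of a
zero-variance series are 0, peak-to-RMS of an all-zero series is 0, and
a flat spectrum yields (0, 0) peak pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal, stats

from .kinematics import CHANNEL_ORDER
from .segmentation import PhaseSegment

#: band edges in Hz; the final band runs from 20 Hz to the Nyquist rate
BAND_EDGES = (0.0, 0.5, 1.5, 5.0, 10.0, 15.0, 20.0)
N_BANDS = 7
N_PEAKS = 6

_STAT_NAMES = (
    "mean", "rms", "skew", "kurtosis", "range", "max", "min", "std",
    "peak2rms",
)


class FeatureError(ValueError):
    pass


def channel_feature_names(channel: str) -> list[str]:
    """The 29 feature names for one channel, in extraction order."""
    names = [f"{channel}_{s}" for s in _STAT_NAMES]
    names += [f"{channel}_band{i}_power" for i in range(1, N_BANDS + 1)]
    for i in range(1, N_PEAKS + 1):
        names += [f"{channel}_peak{i}_loc", f"{channel}_peak{i}_height"]
    names.append(f"{channel}_autocorr0_height")
    return names


def phase_feature_names() -> list[str]:
    """All 174 feature names for one phase (channels in canonical order)."""
    out: list[str] = []
    for ch in CHANNEL_ORDER:
        out.extend(channel_feature_names(ch))
    return out


N_FEATURES_PER_CHANNEL = len(channel_feature_names("x"))  # 29
N_FEATURES_PER_PHASE = N_FEATURES_PER_CHANNEL * len(CHANNEL_ORDER)  # 174


# ---------------------------------------------------------------------------
# spectral helpers
# ---------------------------------------------------------------------------

def _periodogram(x: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram of the mean-removed series, rectangular
    window, scaled so the bin powers sum to the biased sample variance."""
    f, p = signal.periodogram(
        x, fs=rate, window="boxcar", detrend="constant", scaling="spectrum"
    )
    return f, p


def band_power(
    series: np.ndarray, rate: float, f_lo: float, f_hi: float
) -> float:
    """Total periodogram power in [f_lo, f_hi); the upper edge is
    included when it equals the Nyquist frequency."""
    nyq = rate / 2.0
    if not (0.0 <= f_lo < f_hi <= nyq + 1e-12):
        raise FeatureError(f"invalid band edges [{f_lo}, {f_hi}) for rate {rate}")
    f, p = _periodogram(np.asarray(series, dtype=float), rate)
    return float(p[_band_mask(f, f_lo, f_hi, nyq)].sum())


def _band_mask(f: np.ndarray, lo: float, hi: float, nyq: float) -> np.ndarray:
    if hi >= nyq - 1e-12:
        return (f >= lo) & (f <= nyq + 1e-12)
    return (f >= lo) & (f < hi)


def _band_powers(f: np.ndarray, p: np.ndarray, rate: float) -> np.ndarray:
    nyq = rate / 2.0
    edges = list(BAND_EDGES) + [nyq]
    out = np.empty(N_BANDS)
    for i in range(N_BANDS):
        out[i] = p[_band_mask(f, edges[i], edges[i + 1], nyq)].sum()
    return out


def _peak_indices(p: np.ndarray) -> np.ndarray:
    """Strict local maxima of the periodogram, excluding numerical-noise
    bins (heights below 1e-12 of the spectral maximum)."""
    idx, _ = signal.find_peaks(p)
    if idx.size == 0 or p.max() <= 0:
        return np.array([], dtype=int)
    return idx[p[idx] > 1e-12 * p.max()]


def spectral_peaks(
    series: np.ndarray, rate: float, k: int = N_PEAKS
) -> list[tuple[float, float]]:
    """(frequency, power) of the first ``k`` local maxima of the
    periodogram, in ascending frequency; padded with (0, 0)."""
    f, p = _periodogram(np.asarray(series, dtype=float), rate)
    idx = _peak_indices(p)
    pairs = [(float(f[i]), float(p[i])) for i in idx[:k]]
    pairs += [(0.0, 0.0)] * (k - len(pairs))
    return pairs


def autocorr_zero_height(series: np.ndarray) -> float:
    """Zero-lag height of the biased autocovariance: the mean squared
    deviation from the series mean (divisor N)."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise FeatureError("empty series")
    return float(np.mean((x - x.mean()) ** 2))


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def extract_channel_features(series: np.ndarray, rate: float) -> np.ndarray:
    """The 29-vector for one channel; see the module docstring for the
    composition and ordering."""
    x = np.asarray(series, dtype=float)
    if x.size < 2 * rate:
        raise FeatureError(
            f"series too short: {x.size} samples < 2 s at {rate} Hz"
        )
    if not np.all(np.isfinite(x)):
        raise FeatureError("series contains non-finite samples")

    rms = float(np.sqrt(np.mean(x**2)))
    sd = float(np.std(x, ddof=1))
    if sd > 0:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
    else:
        skew = 0.0
        kurt = 0.0
    stats_block = [
        float(np.mean(x)),
        rms,
        skew,
        kurt,
        float(np.ptp(x)),
        float(np.max(x)),
        float(np.min(x)),
        sd,
        float(np.max(np.abs(x)) / rms) if rms > 0 else 0.0,
    ]

    f, p = _periodogram(x, rate)
    bands = _band_powers(f, p, rate)

    idx = _peak_indices(p)
    peaks: list[float] = []
    for i in range(N_PEAKS):
        if i < idx.size:
            peaks += [float(f[idx[i]]), float(p[idx[i]])]
        else:
            peaks += [0.0, 0.0]

    ac0 = autocorr_zero_height(x)
    return np.array(stats_block + list(bands) + peaks + [ac0])


def extract_phase_features(segment: PhaseSegment) -> pd.Series:
    """All 174 named features for one phase segment (channels in the
    canonical order ah, av, omegah, omegav, alpha, gamma)."""
    rate = segment.channels.rate_hz
    values: list[np.ndarray] = []
    for ch in CHANNEL_ORDER:
        values.append(extract_channel_features(segment.channels.channel(ch), rate))
    return pd.Series(np.concatenate(values), index=phase_feature_names())
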