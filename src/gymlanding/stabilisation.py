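"""Contact detection and landing stabilisation indices from lower-back IMU data.

Two indices per channel and analysis window:

* **DSI** (dynamic stability index): root-mean-square deviation of the
  baseline-zeroed post-contact signal from zero.  Units of the channel.
* **TTS** (time to stabilisation): sequential-average method.  With the
  cumulative mean ``seq(k) = mean(x[1..k])`` from contact onward and the
  threshold ``T = 0.25 x SD`` of the quiet tail used for zeroing, TTS is the
  earliest time after which ``|seq(k)| <= T`` holds for every later sample.
  If that never happens TTS equals the window length (censored sentinel).

Both are computed over 3-s and 1-s post-contact windows after a 30-Hz
zero-phase low-pass and zeroing against the mean of the final 0.5 s
(3-s window) or 0.25 s (1-s window) of the window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InsufficientDataError, InvalidConfigError, NoFlightError, NoImpactError
from .io import ACC_CHANNELS, IMU_CHANNELS

logger = logging.getLogger(__name__)

IMU_RATE_HZ = 370.4
WINDOWS_S = (3.0, 1.0)
_BASELINE_TAIL_S = {3.0: 0.5, 1.0: 0.25}

# Contact-detection defaults: the rule (near-zero specific force = flight,
# supra-threshold vertical peak = impact) is fixed; these constants are free
# parameters of the detector.
FLIGHT_THRESHOLD_G = 0.3
FLIGHT_MIN_DURATION_S = 0.08
IMPACT_PEAK_THRESHOLD_G = 2.0
IMPACT_SEARCH_S = 0.2


@dataclass(frozen=True)
class ContactEvent:
    time_s: float
    index: int
    flight_intervals_found: int


@dataclass
class StabilisationIndices:
    window_s: float
    dsi: dict[str, float]           # per channel, >= 0
    tts_s: dict[str, float]         # per channel, in [0, window_s]
    tts_censored: dict[str, bool]   # True where the sentinel was returned


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[0::2], edges[1::2]))


def detect_contact(imu, rate_hz: float = IMU_RATE_HZ,
                   flight_threshold_g: float = FLIGHT_THRESHOLD_G,
                   flight_min_duration_s: float = FLIGHT_MIN_DURATION_S,
                   peak_threshold_g: float = IMPACT_PEAK_THRESHOLD_G,
                   search_s: float = IMPACT_SEARCH_S) -> ContactEvent:
    """Locate foot-floor contact: the first local maximum of vertical
    acceleration exceeding ``peak_threshold_g`` after the end of the *last*
    flight phase (maximal run of specific-force magnitude below
    ``flight_threshold_g`` lasting at least ``flight_min_duration_s``).
    """
    acc = np.column_stack([np.asarray(imu[ch], dtype=float) for ch in ACC_CHANNELS])
    acc_v = acc[:, 2]
    magnitude = np.sqrt((acc**2).sum(axis=1))
    min_run = int(round(flight_min_duration_s * rate_hz))
    flights = [(a, b) for a, b in _runs(magnitude < flight_threshold_g) if b - a >= min_run]
    if not flights:
        raise NoFlightError("no flight phase (near-zero specific force) found")
    last_end = flights[-1][1]
    horizon = min(len(acc_v), last_end + int(round(search_s * rate_hz)) + 1)
    seg = acc_v[last_end:horizon]
    # local maxima above threshold, endpoints included via edge comparison
    for i in range(len(seg)):
        left = seg[i - 1] if i > 0 else -np.inf
        right = seg[i + 1] if i + 1 < len(seg) else -np.inf
        if seg[i] > peak_threshold_g and seg[i] >= left and seg[i] > right:
            idx = last_end + i
            return ContactEvent(time_s=idx / rate_hz, index=idx,
                                flight_intervals_found=len(flights))
    raise NoImpactError(
        f"no vertical-acceleration peak above {peak_threshold_g} g within "
        f"{search_s * 1000:.0f} ms of the last flight phase"
    )


def lowpass_30(channel: np.ndarray, rate_hz: float = IMU_RATE_HZ) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass at 30 Hz."""
    x = np.asarray(channel, dtype=float)
    sos = sps.butter(4, 30.0, btype="lowpass", fs=rate_hz, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(x) <= padlen:
        raise InsufficientDataError(f"signal of {len(x)} samples too short for low-pass filtering")
    return sps.sosfiltfilt(sos, x)


def baseline_tail_s(window_s: float) -> float:
    try:
        return _BASELINE_TAIL_S[float(window_s)]
    except KeyError:
        # generalisation for non-standard windows: keep the same 1/6 ratio
        return window_s / 6.0


def baseline_subtract(segment: np.ndarray, window_s: float,
                      rate_hz: float = IMU_RATE_HZ) -> np.ndarray:
    """Zero the segment against the mean of its terminal quiet-stance tail
    (0.5 s for the 3-s window, 0.25 s for the 1-s window)."""
    x = np.asarray(segment, dtype=float)
    n_tail = int(round(baseline_tail_s(window_s) * rate_hz))
    if n_tail < 1 or n_tail > len(x):
        raise InsufficientDataError("segment shorter than its baseline tail")
    return x - x[-n_tail:].mean()


def dsi(segment_zeroed: np.ndarray) -> float:
    """Dynamic stability index: RMS deviation from the zero baseline."""
    x = np.asarray(segment_zeroed, dtype=float)
    if len(x) == 0:
        raise InsufficientDataError("empty segment")
    return float(np.sqrt(np.mean(x**2)))


def tts(segment_zeroed: np.ndarray, rate_hz: float = IMU_RATE_HZ,
        window_s: float = 3.0, variant: str = "sequential") -> tuple[float, bool]:
    """Time to stabilisation of a baseline-zeroed post-contact segment.

    Returns ``(tts_s, censored)``.  The fixed default (``'sequential'``) is
    the sequential (cumulative) average with a 0.25 x tail-SD threshold
    around zero and a "remains within" (suffix) condition.  Named variants:
    ``'series_mean'`` uses the whole-segment mean as reference and 0.25 x
    the whole-segment SD (the classic ground-reaction-force formulation);
    ``'unstable_last'`` reports the time just after the last threshold
    violation of seq(k).
    """
    x = np.asarray(segment_zeroed, dtype=float)
    if len(x) == 0:
        raise InsufficientDataError("empty segment")
    n_tail = int(round(baseline_tail_s(window_s) * rate_hz))
    if variant == "series_mean":
        # Colby's original reference: the overall series mean and 0.25 x the
        # SD of the whole segment (always attainable as seq -> series mean).
        threshold = 0.25 * float(np.std(x))
        seq = np.cumsum(x) / np.arange(1, len(x) + 1) - x.mean()
        variant = "sequential"
    else:
        threshold = 0.25 * float(np.std(x[-n_tail:]))
        seq = np.cumsum(x) / np.arange(1, len(x) + 1)
    if threshold == 0.0:
        if np.any(np.abs(seq) > 0.0):
            logger.warning("TTS threshold is zero with nonzero signal; returning window length")
            return float(window_s), True
        return 0.0, False
    within = np.abs(seq) <= threshold
    if variant == "sequential":
        # earliest index from which the condition holds for every later sample
        stays = np.flip(np.logical_and.accumulate(np.flip(within)))
        hits = np.flatnonzero(stays)
    elif variant == "unstable_last":
        violations = np.flatnonzero(~within)
        hits = (np.array([violations[-1] + 1]) if len(violations) and violations[-1] + 1 < len(x)
                else (np.array([0]) if not len(violations) else np.array([], dtype=int)))
    else:
        raise InvalidConfigError(f"unknown TTS variant {variant!r}")
    if len(hits) == 0:
        return float(window_s), True
    return float(hits[0] / rate_hz), False


def compute_indices(imu, contact: ContactEvent, rate_hz: float = IMU_RATE_HZ,
                    windows_s: tuple[float, ...] = WINDOWS_S,
                    tts_variant: str = "sequential") -> list[StabilisationIndices]:
    """Full per-trial index pipeline: low-pass the whole record, window it
    after contact, zero the baseline, then DSI and TTS for all 6 channels."""
    results = []
    max_window = max(windows_s)
    n_needed = contact.index + int(round(max_window * rate_hz))
    n_have = len(np.asarray(imu[IMU_CHANNELS[0]]))
    if n_have < n_needed:
        raise InsufficientDataError(
            f"only {(n_have - contact.index) / rate_hz:.2f} s of post-contact signal; "
            f"{max_window:.1f} s needed"
        )
    filtered = {ch: lowpass_30(np.asarray(imu[ch], dtype=float), rate_hz) for ch in IMU_CHANNELS}
    for window in windows_s:
        n_win = int(round(window * rate_hz))
        dsi_vals: dict[str, float] = {}
        tts_vals: dict[str, float] = {}
        censored: dict[str, bool] = {}
        for ch in IMU_CHANNELS:
            seg = filtered[ch][contact.index:contact.index + n_win]
            zeroed = baseline_subtract(seg, window, rate_hz)
            dsi_vals[ch] = dsi(zeroed)
            tts_vals[ch], censored[ch] = tts(zeroed, rate_hz, window, variant=tts_variant)
        results.append(StabilisationIndices(window_s=window, dsi=dsi_vals,
                                            tts_s=tts_vals, tts_censored=censored))
    return results
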