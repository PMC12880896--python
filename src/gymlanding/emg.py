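"""Surface-EMG processing: from raw mV traces to 30-node activity patterns.

Fixed order of operations: resample to 1000 Hz -> 30-350 Hz zero-phase
band-pass -> full-wave rectification -> (quality control on the *raw* mV
amplitude, since 3 mV is an electrode-level physical bound) -> per-participant
normalisation to the AS maximum -> integration in 20-ms windows over the
-300...+300 ms window around contact.  Node 16 starts exactly at contact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .errors import InsufficientDataError, InvalidConfigError, NormalisationError

TARGET_RATE_HZ = 1000.0
NATIVE_RATES = (1926.0, 1111.0)
PATTERN_WINDOW_S = 0.3   # half-width of the analysis window around contact
NODE_WIDTH_S = 0.020
N_NODES = 30
AMPLITUDE_LIMIT_MV = 3.0
_SATURATION_RUN = 50      # samples within 0.1% of the global extremum
_FLATLINE_RUN = 200       # identical consecutive samples


@dataclass(frozen=True)
class QCVerdict:
    keep: bool
    reason: str  # ok | amplitude_over_3mV | artifact_saturation | artifact_flatline


@dataclass
class EMGPattern:
    """Integrated normalised activity in 30 consecutive 20-ms windows.

    Nodes 1-15 cover -300...0 ms before contact, nodes 16-30 cover
    0...+300 ms after it; values are non-negative (units: normalised * s).
    """

    muscle: str
    nodes: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.shape != (N_NODES,):
            raise ValueError(f"pattern must have exactly {N_NODES} nodes")
        if not np.all(np.isfinite(self.nodes)) or np.any(self.nodes < 0):
            raise ValueError("pattern nodes must be finite and non-negative")


def resample_to_1000hz(signal: np.ndarray, native_rate_hz: float) -> np.ndarray:
    """Polyphase resampling onto a uniform 1000 Hz grid.

    1111 -> 1000 is a non-integer ratio, so polyphase interpolation (not
    decimation) is used; envelope features keep their timing to within one
    output sample.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("expected a 1-D signal")
    if len(signal) < 10:
        raise InsufficientDataError("signal shorter than 10 samples")
    if native_rate_hz <= 0:
        raise InvalidConfigError("native rate must be positive")
    if float(native_rate_hz) not in NATIVE_RATES:
        warnings.warn(
            f"native rate {native_rate_hz} Hz is not one of {NATIVE_RATES}; resampling anyway",
            stacklevel=2,
        )
    ratio = Fraction(TARGET_RATE_HZ / native_rate_hz).limit_denominator(10000)
    # Kaiser beta 12: ~ -120 dB stopband so passband ripple stays ~1e-7,
    # keeping constants and low-frequency envelopes numerically intact
    return sps.resample_poly(signal, ratio.numerator, ratio.denominator,
                             window=("kaiser", 12.0), padtype="line")


def bandpass_30_350(signal: np.ndarray, rate_hz: float = TARGET_RATE_HZ) -> np.ndarray:
    """Zero-phase (forward-backward) 4th-order Butterworth band-pass, 30-350 Hz."""
    signal = np.asarray(signal, dtype=float)
    sos = sps.butter(4, [30.0, 350.0], btype="bandpass", fs=rate_hz, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(signal) <= 3 * padlen:
        raise InsufficientDataError(
            f"signal of {len(signal)} samples too short for stable zero-phase filtering"
        )
    return sps.sosfiltfilt(sos, signal)


def rectify(signal: np.ndarray) -> np.ndarray:
    """Full-wave rectification (pointwise absolute value)."""
    return np.abs(np.asarray(signal, dtype=float))


def _max_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return int(np.max(edges[1::2] - edges[0::2]))


def qc_check(raw_signal_mv: np.ndarray) -> QCVerdict:
    """Screen one raw (pre-filtering) EMG trace in mV.

    Excluded when the amplitude exceeds 3 mV, when >= 50 consecutive samples
    sit within 0.1% of the global extremum (saturation), or when >= 200
    consecutive samples are identical (flatline).
    """
    x = np.asarray(raw_signal_mv, dtype=float)
    if np.max(np.abs(x)) > AMPLITUDE_LIMIT_MV:
        return QCVerdict(False, "amplitude_over_3mV")
    extremum = np.max(np.abs(x))
    if extremum > 0:
        near = np.abs(np.abs(x) - extremum) <= 1e-3 * extremum
        if _max_run(near) >= _SATURATION_RUN:
            return QCVerdict(False, "artifact_saturation")
    if len(x) >= 2:
        same = np.diff(x) == 0.0
        if _max_run(same) + 1 >= _FLATLINE_RUN:
            return QCVerdict(False, "artifact_flatline")
    return QCVerdict(True, "ok")


def process_raw(signal_mv: np.ndarray, native_rate_hz: float) -> np.ndarray:
    """resample -> band-pass -> rectify; returns the processed trace at 1000 Hz."""
    return rectify(bandpass_30_350(resample_to_1000hz(signal_mv, native_rate_hz)))


def _analysis_slice(n: int, contact_time_s: float) -> slice:
    c = int(round(contact_time_s * TARGET_RATE_HZ))
    half = int(round(PATTERN_WINDOW_S * TARGET_RATE_HZ))
    if c - half < 0 or c + half > n:
        raise InsufficientDataError(
            f"signal does not cover contact +/- {PATTERN_WINDOW_S*1000:.0f} ms "
            f"(need samples {c - half}..{c + half}, have 0..{n})"
        )
    return slice(c - half, c + half)


def as_max_divisor(processed_as: dict[str, np.ndarray],
                   contact_times: dict[str, float],
                   participant: str, muscle: str,
                   window: str = "analysis") -> float:
    """Normalisation divisor: maximum processed amplitude over a participant's
    kept AS trials for one muscle, pooling both gaze conditions.

    ``window='analysis'`` (default) restricts the maximum to the
    -300...+300 ms window around contact; ``window='trial'`` uses the whole
    record instead (the alternative reading of "maximum observed during AS").
    """
    if not processed_as:
        raise NormalisationError(
            f"no kept AS trial for participant {participant}, muscle {muscle}"
        )
    peak = 0.0
    for trial_id, x in processed_as.items():
        if window == "analysis":
            seg = x[_analysis_slice(len(x), contact_times[trial_id])]
        elif window == "trial":
            seg = x
        else:
            raise InvalidConfigError(f"unknown normalisation window {window!r}")
        peak = max(peak, float(np.max(seg)))
    if peak <= 0:
        raise NormalisationError(
            f"AS maximum is zero for participant {participant}, muscle {muscle}"
        )
    return peak


def extract_pattern(normalised_signal: np.ndarray, contact_time_s: float,
                    muscle: str = "") -> EMGPattern:
    """Integrate the normalised 1000-Hz trace in 30 non-overlapping 20-ms
    windows spanning -300...+300 ms; window 16 starts exactly at contact.

    Node value = sum of samples x 0.001 s (rectangular rule at fixed rate).
    """
    x = np.asarray(normalised_signal, dtype=float)
    sl = _analysis_slice(len(x), contact_time_s)
    seg = x[sl]
    per_node = int(round(NODE_WIDTH_S * TARGET_RATE_HZ))
    nodes = seg.reshape(N_NODES, per_node).sum(axis=1) / TARGET_RATE_HZ
    return EMGPattern(muscle=muscle, nodes=nodes)
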