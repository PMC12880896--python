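"""Synthetic EMG + IMU landing trials with known ground truth.

The generator emulates the study design of a gymnastics landing experiment:
18 subjects x 4 motor tasks (DL drop landing, SB/SF backward/forward tucked
somersault, AS backward acrobatic series) x 2 gaze instructions (down,
ahead) x 2-3 repetitions.  Each IMU record is piecewise:

* quiet stance (vertical specific force ~ 1 g + noise; SF gets run-up bumps),
* for AS optionally a first flight + intermediate hand/foot contact,
* a final flight phase (specific-force magnitude ~ 0 g),
* a half-sine impact transient on the vertical axis, peaking at the defined
  contact instant, riding on a smooth 0 -> 1 g stance ramp,
* a damped post-impact oscillation A e^(-t/tau) sin(2 pi f t + phi) per
  channel, starting where the transient ends and decaying into stance noise.

EMG channels are band-limited Gaussian carriers (30-350 Hz at the native
rate, so the downstream band-pass is approximately transparent) multiplied
by burst envelopes that rise a task-dependent preactivation time before
contact, peak at contact, and decay exponentially after it.

All spectral content of the deterministic IMU components is kept well below
the 30 Hz analysis low-pass (oscillation at a few Hz, transient >= 60 ms),
so closed-form signal energies remain valid references after filtering.

Randomness is drawn from per-stream generators keyed by
``SeedSequence([master_seed, subject_index, task_index, gaze_index,
repetition, stream_index])`` so adding trials never perturbs existing ones.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import DatasetIntegrityError, InvalidConfigError
from .io import (
    EMG_CHANNELS,
    GAZES,
    IMU_CHANNELS,
    MANIFEST_COLUMNS,
    TASKS,
    RawTrial,
    TrialMeta,
    write_manifest,
    write_trial,
)

_STREAMS = {"subject": 0, "imu": 1, "emg": 2}

# Fixed per-channel oscillation phases (rad); arbitrary but deterministic.
_OSC_PHASE = {
    "acc_ml": 0.9,
    "acc_ap": 1.7,
    "acc_v": 0.0,
    "gyro_sagittal": 0.5,
    "gyro_frontal": 2.1,
    "gyro_transverse": 1.3,
}


def _default_flight_durations() -> dict[str, float]:
    # DL: 30 cm box drop (~0.25 s free fall); somersaults/series fly longer.
    return {"DL": 0.25, "SB": 0.45, "SF": 0.50, "AS": 0.55}


def _default_impact_amplitudes() -> dict[str, float]:
    # Peak lower-back vertical specific force in g, scaled with landing height;
    # sprung gymnastics floors keep trunk-level peaks moderate.
    return {"DL": 3.0, "SB": 3.5, "SF": 4.0, "AS": 4.5}


def _default_osc_amp() -> dict[str, float]:
    # Post-impact oscillation amplitudes: accelerations in g, gyro in deg/s.
    return {
        "acc_ml": 0.35,
        "acc_ap": 0.50,
        "acc_v": 1.20,
        "gyro_sagittal": 60.0,
        "gyro_frontal": 40.0,
        "gyro_transverse": 30.0,
    }


def _default_noise_sd() -> dict[str, float]:
    return {"acc": 0.01, "gyro": 1.0, "emg": 0.01}


def _default_preactivation() -> dict[str, float]:
    # Pre-contact EMG onset lead (s): earliest for forward somersaults where
    # anticipatory demand is highest, shortest for the simple drop landing.
    return {"DL": 0.08, "SB": 0.12, "SF": 0.15, "AS": 0.12}


def _default_task_amp_scale() -> dict[str, float]:
    # AS largest so the AS-max normalisation divisor bounds the other tasks.
    return {"DL": 0.7, "SB": 1.0, "SF": 1.2, "AS": 1.4}


def _default_muscle_amp_scale() -> dict[str, float]:
    return {
        "rectus_femoris": 0.9,
        "vastus_medialis": 1.0,
        "biceps_femoris": 0.7,
        "tibialis_anterior": 0.8,
        "peroneus_longus": 0.85,
        "gastrocnemius_medialis": 1.0,
    }


def _default_muscle_pre_scale() -> dict[str, float]:
    return {m: 1.0 for m in EMG_CHANNELS}


def _default_task_effect() -> dict[str, float]:
    # Additive shift of the IMU oscillation-amplitude multiplier per task;
    # DSI is linear in amplitude, so this injects a task main effect on the
    # stabilisation outcomes (strong task effects are the regime under study).
    return {"DL": 0.0, "SB": 0.25, "SF": 0.40, "AS": 0.50}


@dataclass
class SimConfig:
    """Study-design and signal-model parameters for the synthetic cohort."""

    n_subjects: int = 18
    tasks: tuple[str, ...] = TASKS
    gaze_levels: tuple[str, ...] = GAZES
    reps_per_cell: int = 3
    seed: int = 0
    emg_rate_hz: float = 1926.0
    imu_rate_hz: float = 370.4

    stance_duration_s: float = 1.5
    post_contact_s: float = 4.0
    flight_duration_s: dict[str, float] = field(default_factory=_default_flight_durations)
    as_include_handspring: bool = True
    as_first_flight_s: float = 0.30
    as_ground_s: float = 0.25
    intermediate_impact_g: float = 3.0

    impact_amplitude_g: dict[str, float] = field(default_factory=_default_impact_amplitudes)
    impact_duration_s: float = 0.10  # soft sprung-floor transient
    osc_amp: dict[str, float] = field(default_factory=_default_osc_amp)
    osc_freq_hz: float = 4.0
    osc_tau_s: float = 0.50
    noise_sd: dict[str, float] = field(default_factory=_default_noise_sd)

    emg_preactivation_s: dict[str, float] = field(default_factory=_default_preactivation)
    muscle_preactivation_scale: dict[str, float] = field(default_factory=_default_muscle_pre_scale)
    emg_burst_amp_mv: float = 0.20
    task_amp_scale: dict[str, float] = field(default_factory=_default_task_amp_scale)
    muscle_amp_scale: dict[str, float] = field(default_factory=_default_muscle_amp_scale)
    emg_decay_s: float = 0.15

    task_effect: dict[str, float] = field(default_factory=_default_task_effect)
    gaze_effect: float = 0.0  # 0 reproduces the null-gaze regime
    subject_sd: float = 0.10  # between-subject amplitude variability

    def validate(self) -> None:
        if self.n_subjects < 1 or self.reps_per_cell < 1:
            raise InvalidConfigError("n_subjects and reps_per_cell must be positive")
        for t in self.tasks:
            if t not in TASKS:
                raise InvalidConfigError(f"unknown task {t!r}")
        for g in self.gaze_levels:
            if g not in GAZES:
                raise InvalidConfigError(f"unknown gaze level {g!r}")
        for name in ("emg_rate_hz", "imu_rate_hz", "stance_duration_s", "post_contact_s",
                     "impact_duration_s", "osc_freq_hz", "osc_tau_s", "emg_decay_s"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be strictly positive")
        dt = 1.0 / self.imu_rate_hz
        for t in self.tasks:
            if self.flight_duration_s[t] < 3 * dt:
                raise InvalidConfigError(
                    f"flight_duration_s[{t}]={self.flight_duration_s[t]} shorter than 3 IMU samples"
                )
        if self.post_contact_s < 3.0:
            raise InvalidConfigError("post_contact_s must cover the 3-s analysis window")


@dataclass
class GroundTruth:
    """Known truth of one simulated trial (noise-free analytic quantities)."""

    trial_id: str
    contact_time_s: float
    flight_intervals: list[tuple[float, float]]
    channel_rms: dict[str, float]  # analytic RMS over the 3-s window, noise-free
    emg_onset_s: dict[str, float]  # true envelope onset per muscle


def stream_rng(master_seed: int, meta: TrialMeta, stream: str,
               tasks: tuple[str, ...] = TASKS) -> np.random.Generator:
    """Per-(trial, stream) generator; stable under dataset growth."""
    key = [
        int(master_seed),
        abs(hash_subject(meta.subject_id)),
        TASKS.index(meta.task),
        GAZES.index(meta.gaze),
        int(meta.repetition),
        _STREAMS[stream],
    ]
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(key)))


def hash_subject(subject_id: str) -> int:
    digest = hashlib.sha256(subject_id.encode()).digest()
    return int.from_bytes(digest[:4], "little")


def _subject_multiplier(config: SimConfig, master_seed: int, subject_id: str) -> float:
    ss = np.random.SeedSequence([int(master_seed), hash_subject(subject_id), _STREAMS["subject"]])
    rng = np.random.Generator(np.random.PCG64(ss))
    return float(max(0.2, 1.0 + config.subject_sd * rng.standard_normal()))


def damped_sine_energy(amp: float, tau_s: float, freq_hz: float, phase: float, T: float) -> float:
    """Closed-form integral of ``(A e^(-t/tau) sin(2 pi f t + phi))^2`` over [0, T]."""
    a = 2.0 / tau_s
    b = 2.0 * (2.0 * np.pi * freq_hz)
    psi = 2.0 * phase
    i1 = (1.0 - np.exp(-a * T)) / a

    def antider(t: float) -> float:
        return np.exp(-a * t) * (-a * np.cos(b * t + psi) + b * np.sin(b * t + psi)) / (a * a + b * b)

    i2 = antider(T) - antider(0.0)
    return float(amp * amp / 2.0 * (i1 - i2))


def _impact_window_energy(amp_g: float, d: float) -> float:
    """Integral of the squared zeroed vertical signal over the post-contact
    half of the impact transient.

    The stance-weight ramp completes exactly at the transient apex (the
    contact instant), so after zeroing against the 1 g tail baseline only the
    decaying spike half ``A sin(pi u / d), u in [d/2, d]`` remains:
    integral = A^2 d / 4.
    """
    return amp_g * amp_g * d / 4.0


@dataclass(frozen=True)
class _Timeline:
    """Event times (s from record start) of one simulated trial."""

    flight_intervals: tuple[tuple[float, float], ...]  # free-fall spans
    impact_start_s: float  # end of last free fall = transient start
    contact_time_s: float  # transient peak (= impact_start + d/2)
    total_s: float
    intermediate_contact_s: float | None  # AS handspring contact, if any


def _timeline(config: SimConfig, task: str) -> _Timeline:
    d = config.impact_duration_s
    t = config.stance_duration_s
    flights: list[tuple[float, float]] = []
    intermediate = None
    if task == "AS" and config.as_include_handspring:
        flights.append((t, t + config.as_first_flight_s))
        t += config.as_first_flight_s
        intermediate = t
        t += config.as_ground_s
    fd = config.flight_duration_s[task]
    impact_start = t + fd
    # contact (transient apex) is defined on the IMU sample grid
    contact = round((impact_start + d / 2.0) * config.imu_rate_hz) / config.imu_rate_hz
    impact_start = contact - d / 2.0
    flights.append((t, impact_start))
    total = contact + config.post_contact_s
    return _Timeline(tuple(flights), impact_start, contact, total, intermediate)


def _amp_multiplier(config: SimConfig, meta: TrialMeta, master_seed: int) -> float:
    mult = _subject_multiplier(config, master_seed, meta.subject_id)
    mult *= 1.0 + config.task_effect.get(meta.task, 0.0)
    if meta.gaze == "ahead":
        mult *= 1.0 + config.gaze_effect
    return mult


def _half_sine(t: np.ndarray, start: float, duration: float, amp: float) -> np.ndarray:
    u = t - start
    mask = (u >= 0) & (u <= duration)
    out = np.zeros_like(t)
    out[mask] = amp * np.sin(np.pi * u[mask] / duration)
    return out


def generate_imu_trial(config: SimConfig, meta: TrialMeta,
                       master_seed: int) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the 6-channel IMU record of one trial plus its ground truth."""
    config.validate()
    if meta.task not in config.tasks:
        raise InvalidConfigError(f"task {meta.task!r} not in configured tasks {config.tasks}")
    fs = config.imu_rate_hz
    dt = 1.0 / fs
    tl = _timeline(config, meta.task)
    n = int(round(tl.total_s * fs)) + 1
    t = np.arange(n) * dt
    rng = stream_rng(master_seed, meta, "imu")
    mult = _amp_multiplier(config, meta, master_seed)
    d = config.impact_duration_s
    a_imp = config.impact_amplitude_g[meta.task]
    t_osc = tl.impact_start_s + d  # oscillation starts where the transient ends

    # Vertical stance/ground weight: 1 g whenever the body is supported.
    w = np.ones(n)
    for fs_s, fe_s in tl.flight_intervals:
        w[(t >= fs_s) & (t < fe_s)] = 0.0
    # smooth 0 -> 1 g ramp completing exactly at the transient apex, so the
    # recorded vertical maximum falls on the defined contact instant
    ramp_mask = (t >= tl.impact_start_s) & (t < tl.contact_time_s)
    w[ramp_mask] = (1.0 - np.cos(2.0 * np.pi * (t[ramp_mask] - tl.impact_start_s) / d)) / 2.0

    channels: dict[str, np.ndarray] = {}
    for ch in IMU_CHANNELS:
        kind = "acc" if ch.startswith("acc") else "gyro"
        x = np.zeros(n)
        if ch == "acc_v":
            x += w
            x += _half_sine(t, tl.impact_start_s, d, a_imp)
            if tl.intermediate_contact_s is not None:
                x += _half_sine(t, tl.intermediate_contact_s, 0.05,
                                config.intermediate_impact_g)
            if meta.task == "SF":
                # run-up steps before take-off
                for step in (0.5, 0.3):
                    x += _half_sine(t, config.stance_duration_s - step, 0.08, 0.8)
        osc_mask = t >= t_osc
        u = t[osc_mask] - t_osc
        amp = config.osc_amp[ch] * mult
        x[osc_mask] += amp * np.exp(-u / config.osc_tau_s) * np.sin(
            2.0 * np.pi * config.osc_freq_hz * u + _OSC_PHASE[ch]
        )
        x += config.noise_sd[kind] * rng.standard_normal(n)
        channels[ch] = x

    rms: dict[str, float] = {}
    T3 = 3.0
    for ch in IMU_CHANNELS:
        amp = config.osc_amp[ch] * mult
        energy = damped_sine_energy(amp, config.osc_tau_s, config.osc_freq_hz,
                                    _OSC_PHASE[ch], T3 - d / 2.0)
        if ch == "acc_v":
            energy += _impact_window_energy(a_imp, d)
        rms[ch] = float(np.sqrt(energy / T3))

    onsets = {
        m: tl.contact_time_s
        - config.emg_preactivation_s[meta.task] * config.muscle_preactivation_scale[m]
        for m in EMG_CHANNELS
    }
    truth = GroundTruth(
        trial_id=meta.trial_id,
        contact_time_s=tl.contact_time_s,
        flight_intervals=[(float(a), float(b)) for a, b in tl.flight_intervals],
        channel_rms=rms,
        emg_onset_s=onsets,
    )
    imu = pd.DataFrame({"time_s": t, **channels})
    return imu, truth


def emg_envelope(config: SimConfig, meta: TrialMeta, muscle: str,
                 t: np.ndarray, contact_time_s: float, master_seed: int) -> np.ndarray:
    """Noise-free burst envelope (mV) for one muscle: smoothstep rise starting
    ``preactivation`` before contact, peak at contact, exponential decay after."""
    pre = config.emg_preactivation_s[meta.task] * config.muscle_preactivation_scale[muscle]
    amp = (config.emg_burst_amp_mv * config.task_amp_scale[meta.task]
           * config.muscle_amp_scale[muscle]
           * _subject_multiplier(config, master_seed, meta.subject_id))
    floor = config.noise_sd["emg"]
    shape = np.zeros_like(t)
    rise = (t >= contact_time_s - pre) & (t < contact_time_s)
    u = (t[rise] - (contact_time_s - pre)) / pre
    shape[rise] = 3.0 * u**2 - 2.0 * u**3
    after = t >= contact_time_s
    shape[after] = np.exp(-(t[after] - contact_time_s) / config.emg_decay_s)
    return floor + amp * shape


def generate_emg_trial(config: SimConfig, meta: TrialMeta, contact_time_s: float,
                       master_seed: int) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Generate the 6-channel EMG record; returns (EMG block, noise-free envelopes)."""
    config.validate()
    if config.emg_rate_hz not in (1926.0, 1111.0):
        raise InvalidConfigError(
            f"native EMG rate {config.emg_rate_hz} Hz not supported (expected 1926 or 1111)"
        )
    fs = config.emg_rate_hz
    tl = _timeline(config, meta.task)
    if not (0.0 < contact_time_s < tl.total_s):
        raise InvalidConfigError("contact_time_s outside the trial span")
    n = int(round(tl.total_s * fs)) + 1
    t = np.arange(n) / fs
    rng = stream_rng(master_seed, meta, "emg")
    sos = sps.butter(4, [30.0, 350.0], btype="bandpass", fs=fs, output="sos")

    channels: dict[str, np.ndarray] = {}
    envelopes: dict[str, np.ndarray] = {}
    for muscle in EMG_CHANNELS:
        carrier = sps.sosfiltfilt(sos, rng.standard_normal(n))
        sd = carrier.std()
        if sd > 0:
            carrier = carrier / sd
        env = emg_envelope(config, meta, muscle, t, contact_time_s, master_seed)
        channels[muscle] = carrier * env
        envelopes[muscle] = env
    emg = pd.DataFrame({"time_s": t, **channels})
    return emg, envelopes


def generate_trial(config: SimConfig, meta: TrialMeta,
                   master_seed: int) -> tuple[RawTrial, GroundTruth, dict[str, np.ndarray]]:
    imu, truth = generate_imu_trial(config, meta, master_seed)
    emg, envelopes = generate_emg_trial(config, meta, truth.contact_time_s, master_seed)
    return RawTrial(meta=meta, emg=emg, imu=imu), truth, envelopes


def _iter_cells(config: SimConfig):
    for s in range(config.n_subjects):
        subject_id = f"S{s + 1:02d}"
        for task in config.tasks:
            for gaze in config.gaze_levels:
                for rep in range(1, config.reps_per_cell + 1):
                    yield TrialMeta(
                        subject_id=subject_id,
                        task=task,
                        gaze=gaze,
                        repetition=rep,
                        emg_rate_hz=config.emg_rate_hz,
                        imu_rate_hz=config.imu_rate_hz,
                    )


def generate_dataset(config: SimConfig, out_dir: str, master_seed: int | None = None,
                     overwrite: bool = False) -> str:
    """Write a full synthetic dataset (trial CSVs, manifest, ground truth).

    Returns the manifest path.  Trial count is
    ``n_subjects * len(tasks) * len(gaze_levels) * reps_per_cell``.
    """
    config.validate()
    if master_seed is None:
        master_seed = config.seed
    manifest_path = os.path.join(out_dir, "manifest.csv")
    if os.path.exists(manifest_path) and not overwrite:
        raise DatasetIntegrityError(
            f"manifest already exists at {manifest_path}; pass overwrite=True to replace"
        )
    os.makedirs(out_dir, exist_ok=True)

    rows = []
    truth_rows = []
    for meta in _iter_cells(config):
        trial, truth, _ = generate_trial(config, meta, master_seed)
        emg_name = f"{meta.trial_id}_emg.csv"
        imu_name = f"{meta.trial_id}_imu.csv"
        write_trial(trial, os.path.join(out_dir, emg_name), os.path.join(out_dir, imu_name))
        rows.append({
            "trial_id": meta.trial_id,
            "subject_id": meta.subject_id,
            "task": meta.task,
            "gaze": meta.gaze,
            "repetition": meta.repetition,
            "emg_path": emg_name,
            "imu_path": imu_name,
            "emg_rate_hz": config.emg_rate_hz,
            "imu_rate_hz": config.imu_rate_hz,
        })
        truth_rows.append({
            "trial_id": meta.trial_id,
            "contact_time_s": truth.contact_time_s,
            "n_flights": len(truth.flight_intervals),
            "flight_intervals": ";".join(f"{a:.9f}:{b:.9f}" for a, b in truth.flight_intervals),
            **{f"rms_{ch}": truth.channel_rms[ch] for ch in IMU_CHANNELS},
            **{f"onset_{m}": truth.emg_onset_s[m] for m in EMG_CHANNELS},
        })

    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    write_manifest(manifest, manifest_path)
    pd.DataFrame(truth_rows).to_csv(
        os.path.join(out_dir, "ground_truth.csv"), index=False, float_format="%.12g"
    )
    with open(os.path.join(out_dir, "sim_config.json"), "w") as fh:
        json.dump({"master_seed": master_seed, **asdict(config)}, fh, indent=2, default=list)
    return manifest_path


def load_ground_truth(path: str) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"trial_id": str})
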