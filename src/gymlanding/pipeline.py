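"""End-to-end orchestration: simulate -> process -> indices -> statistics.

Outputs of a run (all under the run's output directory):

* ``data/`` — the simulated dataset (when no existing dataset is given)
* ``contact_log.csv`` — trial_id, contact_time_s, n_flight_phases
* ``qc_log.csv`` — per trial x muscle QC verdicts
* ``indices.csv`` — tidy trial_id, window_s, channel, dsi, tts_s, tts_censored
* ``patterns.csv`` — tidy trial_id, muscle, node, value
* ``scalar_stats.json`` / ``anova_table.csv`` — ANOVA, post hocs, normality
* ``spm.json`` — waveform ANOVA results per muscle
* ``run_manifest.json`` — run id (config hash), seed, counts, warnings

Reruns with the same config and seed are bit-identical for every
deterministic stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import anova as anova_mod
from . import emg as emg_mod
from . import spm as spm_mod
from . import stabilisation as stab_mod
from .errors import GymlandingError, InvalidConfigError, NormalisationError
from .io import EMG_CHANNELS, IMU_CHANNELS, DatasetEntry, discover_dataset, read_trial
from .synthetic import SimConfig, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str
    dataset: str | None = None          # manifest path of an existing dataset
    sim: SimConfig | None = None        # or a simulation config
    windows_s: tuple[float, ...] = (3.0, 1.0)
    alpha: float = 0.05
    n_perm: int = 1000
    seed: int = 0
    qc_enabled: bool = True
    normalisation_window: str = "analysis"  # or "trial"
    tts_variant: str = "sequential"
    gg_correction: bool = False

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise InvalidConfigError("alpha must lie strictly between 0 and 1")
        if any(w <= 0 for w in self.windows_s):
            raise InvalidConfigError("analysis windows must be positive")
        if self.n_perm < 100:
            raise InvalidConfigError("n_perm must be at least 100")
        if self.dataset is None and self.sim is None:
            raise InvalidConfigError("either a dataset manifest or a simulation config is required")
        if self.normalisation_window not in ("analysis", "trial"):
            raise InvalidConfigError("normalisation_window must be 'analysis' or 'trial'")


def _coerce(text: str):
    text = text.strip()
    if text.lower() in ("true", "false"):
        return text.lower() == "true"
    if "," in text:
        return tuple(_coerce(part) for part in text.split(","))
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


def parse_config(path: str) -> RunConfig:
    """Read a flat ``key = value`` config file (dotted keys address nested
    simulation parameters, e.g. ``sim.flight_duration_s.DL = 0.25``)."""
    flat: dict[str, object] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise InvalidConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, value = line.split("=", 1)
            flat[key.strip()] = _coerce(value)
    return config_from_flat(flat)


def config_from_flat(flat: dict[str, object]) -> RunConfig:
    run_kwargs: dict[str, object] = {}
    sim_kwargs: dict[str, object] = {}
    sim_requested = False
    run_fields = {f.name for f in dataclasses.fields(RunConfig)}
    sim_fields = {f.name: f for f in dataclasses.fields(SimConfig)}
    for key, value in flat.items():
        if key.startswith("sim."):
            sim_requested = True
            parts = key[4:].split(".")
            if parts[0] not in sim_fields:
                raise InvalidConfigError(f"unknown simulation key {key!r}")
            if len(parts) == 1:
                if parts[0] in ("tasks", "gaze_levels") and isinstance(value, str):
                    value = (value,)
                sim_kwargs[parts[0]] = value
            elif len(parts) == 2:
                base = sim_kwargs.setdefault(parts[0], dict(getattr(SimConfig(), parts[0])))
                base[parts[1]] = value  # type: ignore[index]
            else:
                raise InvalidConfigError(f"key {key!r} nests too deep")
        elif key in run_fields:
            if key == "windows_s" and not isinstance(value, tuple):
                value = (value,)
            run_kwargs[key] = value
        else:
            raise InvalidConfigError(f"unknown config key {key!r}")
    if sim_requested:
        run_kwargs["sim"] = SimConfig(**sim_kwargs)  # type: ignore[arg-type]
    if "out_dir" not in run_kwargs:
        run_kwargs["out_dir"] = "gymlanding_run"
    return RunConfig(**run_kwargs)  # type: ignore[arg-type]


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _process_trials(entries: list[DatasetEntry], config: RunConfig):
    """Per-trial stage: contact detection, stabilisation indices, EMG QC and
    processing.  Returns (contact_df, indices_df, qc_df, processed EMG store,
    warnings)."""
    contact_rows, index_rows, qc_rows, warnings = [], [], [], []
    processed: dict[str, dict] = {}  # trial_id -> {muscle: trace, contact, meta}
    for entry in entries:
        trial = read_trial(entry.emg_path, entry.imu_path, entry.meta)
        rate = entry.meta.imu_rate_hz
        try:
            contact = stab_mod.detect_contact(trial.imu, rate_hz=rate)
        except GymlandingError as exc:
            raise GymlandingError(f"contact detection failed for {entry.trial_id}: {exc}") from exc
        contact_rows.append({
            "trial_id": entry.trial_id,
            "contact_time_s": contact.time_s,
            "n_flight_phases": contact.flight_intervals_found,
        })
        indices = stab_mod.compute_indices(trial.imu, contact, rate_hz=rate,
                                           windows_s=config.windows_s,
                                           tts_variant=config.tts_variant)
        for rec in indices:
            for ch in IMU_CHANNELS:
                index_rows.append({
                    "trial_id": entry.trial_id,
                    "subject_id": entry.meta.subject_id,
                    "task": entry.meta.task,
                    "gaze": entry.meta.gaze,
                    "repetition": entry.meta.repetition,
                    "window_s": rec.window_s,
                    "channel": ch,
                    "dsi": rec.dsi[ch],
                    "tts_s": rec.tts_s[ch],
                    "tts_censored": rec.tts_censored[ch],
                })
                if rec.tts_censored[ch]:
                    warnings.append(f"{entry.trial_id}: censored TTS for {ch} @ {rec.window_s} s")

        kept: dict[str, np.ndarray] = {}
        for muscle in EMG_CHANNELS:
            raw = trial.emg[muscle].to_numpy()
            verdict = (emg_mod.qc_check(raw) if config.qc_enabled
                       else emg_mod.QCVerdict(True, "ok"))
            qc_rows.append({"trial_id": entry.trial_id, "muscle": muscle,
                            "keep": verdict.keep, "reason": verdict.reason})
            if verdict.keep:
                kept[muscle] = emg_mod.process_raw(raw, entry.meta.emg_rate_hz)
            else:
                warnings.append(f"{entry.trial_id}: {muscle} excluded ({verdict.reason})")
        processed[entry.trial_id] = {
            "meta": entry.meta, "contact_time_s": contact.time_s, "muscles": kept,
        }
    contact_df = pd.DataFrame(contact_rows)
    indices_df = pd.DataFrame(index_rows)
    qc_df = pd.DataFrame(qc_rows)
    return contact_df, indices_df, qc_df, processed, warnings


def _extract_patterns(processed: dict[str, dict], config: RunConfig):
    """Normalise per participant/muscle to the AS maximum and integrate the
    30-node patterns.  Participants with no kept AS trial for a muscle are
    dropped from that muscle with a warning."""
    pattern_rows, warnings = [], []
    by_subject: dict[str, list[str]] = {}
    for trial_id, rec in processed.items():
        by_subject.setdefault(rec["meta"].subject_id, []).append(trial_id)

    for subject, trial_ids in sorted(by_subject.items()):
        for muscle in EMG_CHANNELS:
            as_traces = {
                tid: processed[tid]["muscles"][muscle]
                for tid in trial_ids
                if processed[tid]["meta"].task == "AS" and muscle in processed[tid]["muscles"]
            }
            contacts = {tid: processed[tid]["contact_time_s"] for tid in trial_ids}
            try:
                divisor = emg_mod.as_max_divisor(as_traces, contacts, subject, muscle,
                                                 window=config.normalisation_window)
            except NormalisationError as exc:
                warnings.append(str(exc))
                continue
            for tid in trial_ids:
                if muscle not in processed[tid]["muscles"]:
                    continue
                pattern = emg_mod.extract_pattern(
                    processed[tid]["muscles"][muscle] / divisor,
                    contacts[tid], muscle=muscle,
                )
                meta = processed[tid]["meta"]
                for node, value in enumerate(pattern.nodes, start=1):
                    pattern_rows.append({
                        "trial_id": tid, "subject_id": subject, "task": meta.task,
                        "gaze": meta.gaze, "repetition": meta.repetition,
                        "muscle": muscle, "node": node, "value": value,
                    })
    return pd.DataFrame(pattern_rows), warnings


def scalar_statistics(indices_df: pd.DataFrame, config: RunConfig) -> dict:
    """Scalar layer: per outcome (index x channel x window), RM-ANOVA with
    Bonferroni post hocs for significant effects and the KS normality screen."""
    report: dict[str, dict] = {}
    for window in sorted(indices_df["window_s"].unique(), reverse=True):
        sub = indices_df[indices_df["window_s"] == window]
        wide = sub.pivot_table(
            index=["subject_id", "task", "gaze", "repetition"],
            columns="channel", values=["dsi", "tts_s"],
        )
        wide.columns = [f"{a}_{b}" for a, b in wide.columns]
        wide = wide.reset_index()
        table = anova_mod.aggregate_reps(wide)
        for outcome in sorted(table["outcome"].unique()):
            result = anova_mod.rm_anova_2way(table, outcome, gg_correction=config.gg_correction)
            values = table.loc[table["outcome"] == outcome, "value"].to_numpy()
            try:
                ks_stat, ks_p = anova_mod.ks_normality(values, seed=config.seed)
                normality: dict = {"ks_statistic": ks_stat, "p": ks_p}
            except anova_mod.DegenerateSampleError:
                # e.g. a TTS outcome censored at the window length everywhere
                normality = {"ks_statistic": None, "p": None, "degenerate": True}
            entry: dict = {
                "window_s": window,
                "normality": normality,
                "effects": {},
            }
            for name, eff in result.effects.items():
                entry["effects"][name] = {
                    "F": eff.F, "df": [eff.df_num, eff.df_den], "p": eff.p,
                }
                if eff.p < config.alpha:
                    posthoc = anova_mod.bonferroni_posthoc(table, outcome, name)
                    entry["effects"][name]["posthoc"] = [
                        {"pair": list(r.pair), "mean_difference": r.mean_difference,
                         "t": r.t, "p_raw": r.p_raw, "p_adjusted": r.p_adjusted}
                        for r in posthoc
                    ]
            report[f"{outcome}_{window:g}s"] = entry
    return report


def build_pattern_stacks(patterns_df: pd.DataFrame,
                         drop_incomplete: bool = True) -> tuple[dict[str, spm_mod.PatternStack], list[str]]:
    """Cell-mean (subject, task, gaze, node) stacks per muscle from the tidy
    pattern table; subjects with incomplete cells are dropped with a warning."""
    warnings = []
    stacks: dict[str, spm_mod.PatternStack] = {}
    n_nodes = int(patterns_df["node"].max())
    for muscle in EMG_CHANNELS:
        sub = patterns_df[patterns_df["muscle"] == muscle]
        if sub.empty:
            warnings.append(f"no patterns at all for {muscle}")
            continue
        cells = sub.groupby(["subject_id", "task", "gaze", "node"])["value"].mean()
        subjects = sorted(sub["subject_id"].unique())
        tasks = [t for t in ("DL", "SB", "SF", "AS") if t in set(sub["task"])]
        gazes = [g for g in ("down", "ahead") if g in set(sub["gaze"])]
        data = np.full((len(subjects), len(tasks), len(gazes), n_nodes), np.nan)
        for (s, t, g, node), v in cells.items():
            data[subjects.index(s), tasks.index(t), gazes.index(g), int(node) - 1] = v
        complete = ~np.isnan(data).any(axis=(1, 2, 3))
        if not complete.all():
            dropped = [s for s, ok in zip(subjects, complete) if not ok]
            if drop_incomplete:
                warnings.append(f"{muscle}: dropped incomplete subjects {dropped}")
                data = data[complete]
                subjects = [s for s, ok in zip(subjects, complete) if ok]
            else:
                raise anova_mod.ImbalanceError(f"{muscle}: incomplete subjects {dropped}")
        stacks[muscle] = spm_mod.PatternStack(muscle=muscle, data=data,
                                              subjects=subjects, tasks=tasks, gazes=gazes)
    return stacks, warnings


def waveform_statistics(patterns_df: pd.DataFrame, config: RunConfig) -> tuple[dict, list[str]]:
    stacks, warnings = build_pattern_stacks(patterns_df)
    report = {}
    for muscle, stack in stacks.items():
        results = spm_mod.spm_infer(stack, n_perm=config.n_perm, seed=config.seed,
                                    alpha=config.alpha)
        report[muscle] = spm_mod.result_to_dict(results)
        report[muscle]["n_subjects"] = len(stack.subjects)
    return report, warnings


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the run manifest dictionary."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    run_id = _config_hash(config)

    if config.dataset is not None:
        manifest_path = config.dataset
    else:
        data_dir = os.path.join(config.out_dir, "data")
        manifest_path = generate_dataset(config.sim, data_dir,
                                         master_seed=config.seed, overwrite=True)
    entries = discover_dataset(manifest_path)

    contact_df, indices_df, qc_df, processed, warnings = _process_trials(entries, config)
    patterns_df, w2 = _extract_patterns(processed, config)
    warnings += w2

    fmt = "%.12g"
    contact_df.to_csv(os.path.join(config.out_dir, "contact_log.csv"),
                      index=False, float_format=fmt)
    qc_df.to_csv(os.path.join(config.out_dir, "qc_log.csv"), index=False)
    indices_df.to_csv(os.path.join(config.out_dir, "indices.csv"),
                      index=False, float_format=fmt)
    patterns_df.to_csv(os.path.join(config.out_dir, "patterns.csv"),
                       index=False, float_format=fmt)

    scalar_report = scalar_statistics(indices_df, config)
    spm_report, w3 = waveform_statistics(patterns_df, config)
    warnings += w3

    with open(os.path.join(config.out_dir, "scalar_stats.json"), "w") as fh:
        json.dump({"run_id": run_id, "results": scalar_report}, fh, indent=2, sort_keys=True)
    with open(os.path.join(config.out_dir, "spm.json"), "w") as fh:
        json.dump({"run_id": run_id, "results": spm_report}, fh, indent=2, sort_keys=True)

    flat_rows = []
    for outcome, entry in scalar_report.items():
        for effect, eff in entry["effects"].items():
            flat_rows.append({"outcome": outcome, "effect": effect,
                              "F": eff["F"], "p": eff["p"]})
    pd.DataFrame(flat_rows).to_csv(os.path.join(config.out_dir, "anova_table.csv"),
                                   index=False, float_format=fmt)

    manifest = {
        "run_id": run_id,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "n_trials": len(entries),
        "n_qc_excluded": int((~qc_df["keep"]).sum()) if len(qc_df) else 0,
        "warnings": warnings,
    }
    with open(os.path.join(config.out_dir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
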