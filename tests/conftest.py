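import numpy as np
import pandas as pd
import pytest

from gymlanding.synthetic import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Miniature study: 3 subjects x 4 tasks x 2 gaze x 2 reps."""
    return SimConfig(n_subjects=3, reps_per_cell=2)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory, small_config):
    out = tmp_path_factory.mktemp("dataset")
    manifest = generate_dataset(small_config, str(out), master_seed=11)
    return {"dir": out, "manifest": manifest, "config": small_config, "seed": 11}


def make_balanced_table(rng: np.random.Generator, n_subjects: int = 8,
                        task_shift: dict[str, float] | None = None,
                        gaze_shift: float = 0.0) -> pd.DataFrame:
    """Random balanced subject x task x gaze study table with optional
    additive effects (within-cell noise SD = 1)."""
    rows = []
    for s in range(n_subjects):
        subject_effect = rng.normal(0, 0.5)
        for task in ("DL", "SB", "SF", "AS"):
            for gaze in ("down", "ahead"):
                value = rng.normal() + subject_effect
                if task_shift:
                    value += task_shift.get(task, 0.0)
                if gaze == "ahead":
                    value += gaze_shift
                rows.append({"subject_id": f"S{s:02d}", "task": task, "gaze": gaze,
                             "outcome": "y", "value": value})
    return pd.DataFrame(rows)
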