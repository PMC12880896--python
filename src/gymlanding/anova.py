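"""Fully within-subject two-way (task x gaze) ANOVA for scalar outcomes.

The design is a x b x subject with one value per cell (repetitions averaged
beforehand).  Each effect is tested against its own effect-by-subject
interaction mean square:

    F_task = MS_task / MS_task:subj          df = (a-1), (a-1)(s-1)
    F_gaze = MS_gaze / MS_gaze:subj          df = (b-1), (b-1)(s-1)
    F_int  = MS_task:gaze / MS_task:gaze:subj  df = (a-1)(b-1), (a-1)(b-1)(s-1)

No sphericity correction is applied by default; Greenhouse-Geisser is
available behind a flag.  The sums-of-squares core is vectorised over
arbitrary trailing axes so the waveform (node-wise) layer can reuse it.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .errors import DegenerateSampleError, ImbalanceError, InvalidConfigError
from .io import GAZES, TASKS

STUDY_COLUMNS = ("subject_id", "task", "gaze", "outcome", "value")


@dataclass
class EffectResult:
    F: float
    df_num: int
    df_den: int
    p: float
    ss_effect: float
    ss_error: float
    ges: float | None = None  # Greenhouse-Geisser epsilon when requested


@dataclass
class AnovaResult:
    outcome: str
    effects: dict[str, EffectResult]  # keys: task, gaze, interaction


@dataclass
class PosthocResult:
    pair: tuple[str, str]
    mean_difference: float
    t: float
    p_raw: float
    p_adjusted: float
    n_comparisons: int


def aggregate_reps(trials: pd.DataFrame, value_cols: list[str] | None = None) -> pd.DataFrame:
    """Collapse trial-level outcomes to one value per subject x task x gaze
    cell (arithmetic mean over available repetitions).

    ``trials`` is wide: columns subject_id, task, gaze, repetition plus one
    column per outcome.  Returns the long-format study table and raises on
    empty cells (no imputation).
    """
    key = ["subject_id", "task", "gaze"]
    if value_cols is None:
        value_cols = [c for c in trials.columns if c not in (*key, "repetition", "trial_id")]
    cells = trials.groupby(key, sort=True)[value_cols].mean().reset_index()

    subjects = sorted(trials["subject_id"].unique())
    tasks = [t for t in TASKS if t in set(trials["task"])]
    gazes = [g for g in GAZES if g in set(trials["gaze"])]
    expected = {(s, t, g) for s in subjects for t in tasks for g in gazes}
    present = set(map(tuple, cells[key].itertuples(index=False)))
    missing = sorted(expected - present)
    if missing:
        raise ImbalanceError(f"missing subject x task x gaze cells: {missing}")

    long = cells.melt(id_vars=key, value_vars=value_cols,
                      var_name="outcome", value_name="value")
    return long[list(STUDY_COLUMNS)]


def table_to_cells(table: pd.DataFrame, outcome: str) -> tuple[np.ndarray, list[str], list[str], list[str]]:
    """Pivot a long study table into an (S, A, B) cell array for one outcome."""
    sub = table[table["outcome"] == outcome]
    if sub.empty:
        raise InvalidConfigError(f"outcome {outcome!r} not present in table")
    subjects = sorted(sub["subject_id"].unique())
    tasks = [t for t in TASKS if t in set(sub["task"])]
    gazes = [g for g in GAZES if g in set(sub["gaze"])]
    pivot = sub.set_index(["subject_id", "task", "gaze"])["value"]
    if pivot.index.duplicated().any():
        raise ImbalanceError("more than one row per subject x task x gaze cell")
    x = np.full((len(subjects), len(tasks), len(gazes)), np.nan)
    for (s, t, g), v in pivot.items():
        x[subjects.index(s), tasks.index(t), gazes.index(g)] = v
    if np.isnan(x).any():
        idx = np.argwhere(np.isnan(x))
        missing = [(subjects[i], tasks[j], gazes[k]) for i, j, k in idx]
        raise ImbalanceError(f"unbalanced table; missing cells: {missing}")
    return x, subjects, tasks, gazes


def rm_anova_cells(x: np.ndarray) -> dict[str, dict[str, np.ndarray]]:
    """Within-subject two-way ANOVA decomposition on an (S, A, B, ...) array.

    Trailing axes are carried through (nodes, permutations, replicates...).
    Returns per effect: F, p, ss_effect, ss_error, df_num, df_den.
    Zero-variance effects are reported as F = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim < 3:
        raise InvalidConfigError("expected an array of shape (subjects, a, b, ...)")
    S, A, B = x.shape[:3]
    if S < 3:
        raise InvalidConfigError("at least 3 subjects required")
    if A < 2 or B < 2:
        raise InvalidConfigError("both factors need at least 2 levels")

    m = x.mean(axis=(0, 1, 2))
    ms_ = x.mean(axis=(1, 2))           # (S, ...)
    ma = x.mean(axis=(0, 2))            # (A, ...)
    mb = x.mean(axis=(0, 1))            # (B, ...)
    mab = x.mean(axis=0)                # (A, B, ...)
    mas = x.mean(axis=2)                # (S, A, ...)
    mbs = x.mean(axis=1)                # (S, B, ...)

    ss_a = B * S * ((ma - m) ** 2).sum(axis=0)
    ss_b = A * S * ((mb - m) ** 2).sum(axis=0)
    ss_ab = S * ((mab - ma[:, None] - mb[None, :] + m) ** 2).sum(axis=(0, 1))
    ss_as = B * ((mas - ma[None, :] - ms_[:, None] + m) ** 2).sum(axis=(0, 1))
    ss_bs = A * ((mbs - mb[None, :] - ms_[:, None] + m) ** 2).sum(axis=(0, 1))
    resid = (x - mab[None] - mas[:, :, None] - mbs[:, None, :]
             + ma[None, :, None] + mb[None, None, :] + ms_[:, None, None] - m)
    ss_abs = (resid ** 2).sum(axis=(0, 1, 2))

    out: dict[str, dict[str, np.ndarray]] = {}
    for name, ss_eff, ss_err, dfn, dfd in (
        ("task", ss_a, ss_as, A - 1, (A - 1) * (S - 1)),
        ("gaze", ss_b, ss_bs, B - 1, (B - 1) * (S - 1)),
        ("interaction", ss_ab, ss_abs, (A - 1) * (B - 1), (A - 1) * (B - 1) * (S - 1)),
    ):
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss_eff / dfn) / (ss_err / dfd)
        F = np.where(ss_eff == 0, 0.0, F)
        F = np.where((ss_err == 0) & (ss_eff > 0), np.inf, F)
        p = np.where(np.isinf(F), 0.0, spstats.f.sf(np.where(np.isfinite(F), F, 0.0), dfn, dfd))
        p = np.where(np.asarray(F) == 0, 1.0, p)
        out[name] = {"F": F, "p": p, "ss_effect": ss_eff, "ss_error": ss_err,
                     "df_num": dfn, "df_den": dfd}
    out["_ss"] = {  # exposed for the sums-of-squares conservation check
        "total": ((x - m) ** 2).sum(axis=(0, 1, 2)),
        "subject": A * B * ((ms_ - m) ** 2).sum(axis=0),
        "task": ss_a, "gaze": ss_b, "interaction": ss_ab,
        "task_subj": ss_as, "gaze_subj": ss_bs, "interaction_subj": ss_abs,
    }
    return out


def _gg_epsilon(y: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the covariance of within-subject scores."""
    cov = np.cov(y.T)
    k = cov.shape[0]
    mean_diag = np.trace(cov) / k
    grand = cov.mean()
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * ((cov**2).sum() - 2 * k * (cov.mean(axis=1) ** 2).sum() + k * k * grand**2)
    return float(num / den) if den > 0 else 1.0


def rm_anova_2way(table: pd.DataFrame, outcome: str,
                  gg_correction: bool = False) -> AnovaResult:
    """Two-way repeated-measures ANOVA for one outcome of a balanced study table."""
    x, subjects, tasks, gazes = table_to_cells(table, outcome)
    core = rm_anova_cells(x)
    effects: dict[str, EffectResult] = {}
    for name in ("task", "gaze", "interaction"):
        e = core[name]
        F = float(e["F"])
        dfn, dfd = e["df_num"], e["df_den"]
        p = float(e["p"])
        eps = None
        if gg_correction and dfn > 1 and np.isfinite(F) and F > 0:
            if name == "task":
                scores = x.mean(axis=2)
            elif name == "gaze":
                scores = x.mean(axis=1)
            else:
                scores = x.reshape(x.shape[0], -1)
            eps = _gg_epsilon(scores)
            p = float(spstats.f.sf(F, dfn * eps, dfd * eps))
        effects[name] = EffectResult(F=F, df_num=dfn, df_den=dfd, p=p,
                                     ss_effect=float(e["ss_effect"]),
                                     ss_error=float(e["ss_error"]), ges=eps)
    return AnovaResult(outcome=outcome, effects=effects)


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Paired t-test returning (mean difference, t, raw p).

    Identical paired samples (zero difference variance and zero mean
    difference) are reported as difference 0 with p = 1 by convention.
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    n = len(d)
    if n < 3:
        raise DegenerateSampleError("fewer than 3 paired observations")
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if md == 0.0:
            return 0.0, 0.0, 1.0
        return md, np.inf, 0.0
    t = md / (sd / np.sqrt(n))
    p = 2.0 * spstats.t.sf(abs(t), n - 1)
    return md, float(t), float(p)


def bonferroni_posthoc(table: pd.DataFrame, outcome: str, effect: str,
                       interaction_style: str = "cells") -> list[PosthocResult]:
    """Bonferroni-adjusted paired t-tests on subject-level condition means.

    ``effect`` is 'task' (6 pairs), 'gaze' (1 pair) or 'interaction'.  For the
    interaction, ``interaction_style='cells'`` compares all 28 pairs of the 8
    task x gaze cells; ``'simple'`` runs simple-effects slices (task pairs
    within each gaze plus the gaze pair within each task, 16 tests), the
    layout used for per-task descriptive figures.  The Bonferroni multiplier
    is the number of tests actually performed; adjusted p = min(1, m * p).
    """
    x, subjects, tasks, gazes = table_to_cells(table, outcome)
    comparisons: list[tuple[tuple[str, str], np.ndarray, np.ndarray]] = []
    if effect == "task":
        marg = x.mean(axis=2)
        for i, j in combinations(range(len(tasks)), 2):
            comparisons.append(((tasks[i], tasks[j]), marg[:, i], marg[:, j]))
    elif effect == "gaze":
        marg = x.mean(axis=1)
        for i, j in combinations(range(len(gazes)), 2):
            comparisons.append(((gazes[i], gazes[j]), marg[:, i], marg[:, j]))
    elif effect == "interaction":
        labels = [(t, g) for t in tasks for g in gazes]
        flat = x.reshape(x.shape[0], -1)
        if interaction_style == "cells":
            for i, j in combinations(range(len(labels)), 2):
                pair = ("/".join(labels[i]), "/".join(labels[j]))
                comparisons.append((pair, flat[:, i], flat[:, j]))
        elif interaction_style == "simple":
            for gi, g in enumerate(gazes):
                for i, j in combinations(range(len(tasks)), 2):
                    pair = (f"{tasks[i]}/{g}", f"{tasks[j]}/{g}")
                    comparisons.append((pair, x[:, i, gi], x[:, j, gi]))
            for ti, t in enumerate(tasks):
                for i, j in combinations(range(len(gazes)), 2):
                    pair = (f"{t}/{gazes[i]}", f"{t}/{gazes[j]}")
                    comparisons.append((pair, x[:, ti, i], x[:, ti, j]))
        else:
            raise InvalidConfigError(f"unknown interaction_style {interaction_style!r}")
    else:
        raise InvalidConfigError(f"unknown effect {effect!r}")

    m = len(comparisons)
    results = []
    for pair, a, b in comparisons:
        md, t, p = _paired_t(a, b)
        results.append(PosthocResult(pair=pair, mean_difference=md, t=t, p_raw=p,
                                     p_adjusted=min(1.0, m * p), n_comparisons=m))
    return results


@lru_cache(maxsize=64)
def _lilliefors_null(n: int, n_mc: int, seed: int) -> tuple[float, ...]:
    """Monte-Carlo null distribution of the KS statistic with estimated
    mean/SD (Lilliefors correction); cached per sample size."""
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, n, n_mc])))
    draws = rng.standard_normal((n_mc, n))
    z = (draws - draws.mean(axis=1, keepdims=True)) / draws.std(axis=1, ddof=1, keepdims=True)
    z.sort(axis=1)
    cdf = spstats.norm.cdf(z)
    k = np.arange(1, n + 1)
    d_plus = (k / n - cdf).max(axis=1)
    d_minus = (cdf - (k - 1) / n).max(axis=1)
    return tuple(np.sort(np.maximum(d_plus, d_minus)))


def ks_normality(values: np.ndarray, n_mc: int = 10_000, seed: int = 0) -> tuple[float, float]:
    """One-sample KS test against a normal with the sample's mean and SD.

    Because the parameters are estimated from the data, the p-value comes
    from a seeded Monte-Carlo null (Lilliefors correction), not the standard
    KS distribution.  Returns (statistic, p).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 5:
        raise DegenerateSampleError("need at least 5 values for the normality screen")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateSampleError("zero variance sample")
    stat = float(spstats.kstest(x, "norm", args=(x.mean(), sd)).statistic)
    null = np.asarray(_lilliefors_null(n, n_mc, seed))
    p = float((1 + np.sum(null >= stat)) / (len(null) + 1))
    return stat, p
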