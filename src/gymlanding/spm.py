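"""One-dimensional two-way repeated-measures ANOVA over 30-node EMG patterns.

At every node the same within-subject decomposition as the scalar layer is
applied, giving an F-curve per effect (task, gaze, interaction).  Family-wise
inference across the 30 nodes uses a within-subject permutation scheme with
the max-statistic: the critical value F* is the (1 - alpha) quantile of the
null distribution of the curve maximum, so any node exceeding F* is
significant at family-wise level alpha.  Supra-threshold clusters are
maximal runs of F > F*; each cluster's p is the proportion of null maxima at
or above the cluster's peak F.

Permutation schemes (all within subject, preserving exchangeability under
the respective null):

* gaze: independent gaze-label flips per (subject, task) pair;
* task: independent task-label permutations per (subject, gaze) slice;
* interaction: full-cell permutations within subject after subtracting the
  estimated main effects (restricted/approximate permutation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations as iter_permutations
from math import factorial

import numpy as np

from .anova import rm_anova_cells
from .errors import ImbalanceError, InvalidConfigError

EFFECTS = ("task", "gaze", "interaction")
_PERM_BATCH = 250  # permutations per vectorised batch (memory bound)


@dataclass
class PatternStack:
    """Cell-mean patterns for one muscle: array (subjects, tasks, gazes, nodes)."""

    muscle: str
    data: np.ndarray
    subjects: list[str]
    tasks: list[str]
    gazes: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ImbalanceError("pattern stack must be (subjects, tasks, gazes, nodes)")
        if not np.all(np.isfinite(self.data)):
            raise ImbalanceError(f"pattern stack for {self.muscle} contains missing cells")


@dataclass
class SpmEffectResult:
    effect: str
    F: np.ndarray                 # (nodes,)
    critical_F: float
    clusters: list[tuple[int, int]] = field(default_factory=list)  # [start, end) node runs
    cluster_p: list[float] = field(default_factory=list)
    df: tuple[int, int] = (0, 0)


def pointwise_f(stack: PatternStack) -> dict[str, np.ndarray]:
    """Node-wise F-curves for task, gaze and interaction."""
    core = rm_anova_cells(stack.data)
    return {e: np.asarray(core[e]["F"], dtype=float) for e in EFFECTS}


def _n_distinct(effect: str, S: int, A: int, B: int) -> float:
    if effect == "gaze":
        return float(B) ** (S * A) if B == 2 else float(factorial(B)) ** (S * A)
    if effect == "task":
        return float(factorial(A)) ** (S * B)
    return float(factorial(A * B)) ** S


def _permuted(x: np.ndarray, effect: str, rng: np.random.Generator,
              n_perm: int) -> np.ndarray:
    """Stack of permuted data, shape (n_perm, S, A, B, N)."""
    S, A, B, N = x.shape
    if effect == "gaze":
        if B != 2:
            raise InvalidConfigError("gaze permutation assumes 2 gaze levels")
        flips = rng.integers(0, 2, size=(n_perm, S, A), dtype=np.int8)
        out = np.broadcast_to(x, (n_perm, S, A, B, N)).copy()
        out[flips.astype(bool)] = out[flips.astype(bool)][:, ::-1]
        return out
    if effect == "task":
        perms = np.empty((n_perm, S, B, A), dtype=np.intp)
        for p in range(n_perm):
            for s in range(S):
                for b in range(B):
                    perms[p, s, b] = rng.permutation(A)
        # out[p, s, a, b] = x[s, perms[p, s, b, a], b]
        out = x[np.arange(S)[None, :, None, None],
                np.transpose(perms, (0, 1, 3, 2)),
                np.arange(B)[None, None, None, :]]
        return out
    if effect == "interaction":
        ma = x.mean(axis=(0, 2), keepdims=True)
        mb = x.mean(axis=(0, 1), keepdims=True)
        m = x.mean(axis=(0, 1, 2), keepdims=True)
        r = x - ma - mb + m  # residualise estimated main effects
        flat = r.reshape(S, A * B, N)
        out = np.empty((n_perm, S, A * B, N))
        for p in range(n_perm):
            for s in range(S):
                out[p, s] = flat[s, rng.permutation(A * B)]
        return out.reshape(n_perm, S, A, B, N)
    raise InvalidConfigError(f"unknown effect {effect!r}")


def _exact_gaze_max_f(x: np.ndarray) -> np.ndarray:
    """Null max-F over *all* 2^(S*A) gaze-label flip patterns, in batches."""
    S, A, B, N = x.shape
    n_units = S * A
    total = 2 ** n_units
    chunks = []
    for start in range(0, total, 1024):
        idx = np.arange(start, min(start + 1024, total))
        bits = ((idx[:, None] >> np.arange(n_units)[None, :]) & 1).astype(bool)
        flips = bits.reshape(len(idx), S, A)
        out = np.broadcast_to(x, (len(idx), S, A, B, N)).copy()
        out[flips] = out[flips][:, ::-1]
        chunks.append(_max_f(out, "gaze"))
    return np.concatenate(chunks)


def _max_f(xp: np.ndarray, effect: str) -> np.ndarray:
    """Curve maxima of the effect F for a (P, S, A, B, N) permutation stack."""
    # move the permutation axis to the back so the ANOVA core vectorises over it
    arr = np.moveaxis(xp, 0, -1)  # (S, A, B, N, P)
    F = rm_anova_cells(arr)[effect]["F"]  # (N, P)
    return np.asarray(F).max(axis=0)


def permutation_threshold(stack: PatternStack, effect: str, n_perm: int = 1000,
                          seed: int = 0, alpha: float = 0.05,
                          exact: bool = False) -> tuple[float, np.ndarray]:
    """Critical value F* and the null max-F sample for one effect.

    ``exact=True`` enumerates all gaze-label flips (only feasible for the
    gaze effect at small S*A); otherwise ``n_perm`` Monte-Carlo permutations
    are drawn from the scheme for ``effect``.
    """
    if effect not in EFFECTS:
        raise InvalidConfigError(f"unknown effect {effect!r}")
    if not 0 < alpha <= 1:
        raise InvalidConfigError("alpha must be in (0, 1]")
    x = stack.data
    S, A, B, _ = x.shape
    if _n_distinct(effect, S, A, B) < 1.0 / alpha:
        raise InvalidConfigError(
            f"only {_n_distinct(effect, S, A, B):.0f} distinct permutations exist for "
            f"{effect}; fewer than 1/alpha — use exact enumeration at a larger alpha"
        )
    if exact:
        if effect != "gaze":
            raise InvalidConfigError("exact enumeration is implemented for the gaze effect only")
        if S * A > 14:
            raise InvalidConfigError("exact enumeration infeasible beyond 2^14 flip patterns")
        max_f = _exact_gaze_max_f(x)
    else:
        if n_perm < 100:
            raise InvalidConfigError("n_perm must be at least 100")
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed])))
        chunks = []
        remaining = n_perm
        while remaining > 0:
            batch = min(_PERM_BATCH, remaining)
            chunks.append(_max_f(_permuted(x, effect, rng, batch), effect))
            remaining -= batch
        max_f = np.concatenate(chunks)
    if alpha == 1.0:
        return -np.inf, max_f  # every node significant at family-wise level 1
    critical = float(np.quantile(max_f, 1.0 - alpha, method="higher"))
    return critical, max_f


def _clusters(F: np.ndarray, critical: float) -> list[tuple[int, int]]:
    above = F > critical
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[0::2], edges[1::2]))


def spm_infer(stack: PatternStack, n_perm: int = 1000, seed: int = 0,
              alpha: float = 0.05,
              effects: tuple[str, ...] = EFFECTS) -> dict[str, SpmEffectResult]:
    """Full waveform inference: F-curves, permutation thresholds, clusters."""
    curves = pointwise_f(stack)
    core = rm_anova_cells(stack.data)
    out: dict[str, SpmEffectResult] = {}
    for effect in effects:
        F = curves[effect]
        critical, null_max = permutation_threshold(stack, effect, n_perm=n_perm,
                                                   seed=seed, alpha=alpha)
        clusters = _clusters(F, critical)
        cluster_p = [float(np.mean(null_max >= F[a:b].max())) for a, b in clusters]
        out[effect] = SpmEffectResult(
            effect=effect, F=F, critical_F=critical, clusters=clusters,
            cluster_p=cluster_p,
            df=(core[effect]["df_num"], core[effect]["df_den"]),
        )
    return out


def result_to_dict(results: dict[str, SpmEffectResult]) -> dict:
    """JSON-serialisable form of an SPM result set."""
    return {
        effect: {
            "F": [float(v) for v in r.F],
            "critical_F": r.critical_F,
            "clusters": [[int(a), int(b)] for a, b in r.clusters],
            "cluster_p": r.cluster_p,
            "df": list(r.df),
        }
        for effect, r in results.items()
    }


def plot_f_curves(results: dict[str, SpmEffectResult], muscle: str = "", ax=None):
    """F-curves with the critical-value line and the contact marker at the
    15|16 node boundary."""
    import matplotlib.pyplot as plt  # deferred: plotting is optional

    if ax is None:
        _, ax = plt.subplots()
    nodes = np.arange(1, len(next(iter(results.values())).F) + 1)
    for effect, r in results.items():
        line, = ax.plot(nodes, r.F, label=effect)
        ax.axhline(r.critical_F, color=line.get_color(), linestyle="--", alpha=0.5)
    ax.axvline(15.5, color="purple", linestyle=":", label="contact")
    ax.set_xlabel("pattern node (20 ms windows)")
    ax.set_ylabel("F")
    ax.set_title(muscle)
    ax.legend()
    return ax
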