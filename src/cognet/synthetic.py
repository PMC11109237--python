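"""Synthetic two-group cohorts with a prescribed inter-task correlation structure.

A Gaussian single-factor copula generates participant-level behavioral
summaries (accuracy %, mean RT ms) for a battery of cognitive tasks.  Per
participant a task-level latent vector is drawn from a zero-mean multivariate
normal with the requested task x task correlation matrix; accuracy and
(negated) reaction time each load on the shared task factor, so the composite
z-score downstream carries the latent correlation attenuated by the loading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The ten tasks of the cognitive battery, grouped by domain for reporting.
DEFAULT_TASKS = (
    "semantics",
    "syntax",
    "phonology",
    "prosody",
    "memory",
    "inhibition",
    "working_memory",
    "switching",
    "attention",
    "theory_of_mind",
)

DOMAIN_LABELS = {
    "semantics": "language",
    "syntax": "language",
    "phonology": "language",
    "prosody": "language",
    "memory": "memory",
    "inhibition": "executive",
    "working_memory": "executive",
    "switching": "executive",
    "attention": "executive",
    "theory_of_mind": "theory_of_mind",
}

# Per-task emission parameters: accuracy mean/sd (%), RT mean/sd (ms).
# Values emulate a young-adult sample on a language/executive battery
# (high accuracies, task-specific RT scales from ~350 to ~2350 ms).
DEFAULT_EMISSIONS = {
    "semantics": (95.88, 4.63, 662.94, 100.84),
    "syntax": (89.06, 5.38, 1255.18, 181.18),
    "phonology": (89.02, 10.39, 1567.29, 262.39),
    "prosody": (90.24, 6.66, 346.65, 101.29),
    "memory": (91.89, 4.66, 1647.68, 128.90),
    "inhibition": (96.76, 3.38, 546.71, 90.83),
    "working_memory": (87.24, 7.12, 702.46, 244.41),
    "switching": (94.79, 7.15, 1300.37, 278.61),
    "attention": (91.69, 8.21, 427.51, 77.78),
    "theory_of_mind": (92.96, 6.13, 2347.90, 920.91),
}


def default_latent_corr(
    task_names: tuple[str, ...] = DEFAULT_TASKS,
    within: float = 0.55,
    between: float = 0.30,
) -> np.ndarray:
    """Block-structured task correlation: stronger within a cognitive domain.

    With the default factor loading (0.7) the observed composite Spearman
    correlations land around 0.24 (between domains) to 0.45 (within), the
    range typical of inter-task correlations in healthy adult cohorts.
    """
    n = len(task_names)
    domains = [DOMAIN_LABELS.get(t, t) for t in task_names]
    corr = np.full((n, n), between)
    for i in range(n):
        for j in range(n):
            if domains[i] == domains[j]:
                corr[i, j] = within
    np.fill_diagonal(corr, 1.0)
    return nearest_valid_corr(corr)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic group of participants.

    Parameters
    ----------
    task_names : ordered task identifiers (nodes of the eventual network).
    n_per_group : participants to generate for this group.
    latent_corr : task x task target correlation of the shared latent factors
        (symmetric, unit diagonal, positive semi-definite).
    accuracy_mean_pct, accuracy_sd_pct : per-task accuracy emission scale (%).
    rt_mean_ms, rt_sd_ms : per-task reaction-time emission scale (ms).
    loading : fraction of each observed measure's variance explained by the
        shared latent task factor, in (0, 1]; both accuracy and RT co-load so
        the accuracy/RT composite carries the latent correlation.
    seed : RNG seed; identical spec (including seed) -> identical cohort.
    group : label attached to every generated record.
    """

    task_names: tuple[str, ...] = DEFAULT_TASKS
    n_per_group: int = 75
    latent_corr: np.ndarray | None = None
    accuracy_mean_pct: tuple[float, ...] | None = None
    accuracy_sd_pct: tuple[float, ...] | None = None
    rt_mean_ms: tuple[float, ...] | None = None
    rt_sd_ms: tuple[float, ...] | None = None
    loading: float = 0.7
    seed: int = 0
    group: str = "A"

    def __post_init__(self) -> None:
        object.__setattr__(self, "task_names", tuple(self.task_names))
        defaults = [DEFAULT_EMISSIONS.get(t, (90.0, 6.0, 1000.0, 200.0)) for t in self.task_names]
        for i, name in enumerate(("accuracy_mean_pct", "accuracy_sd_pct", "rt_mean_ms", "rt_sd_ms")):
            val = getattr(self, name)
            if val is None:
                val = tuple(d[i] for d in defaults)
            object.__setattr__(self, name, tuple(float(v) for v in val))
        corr = self.latent_corr
        if corr is None:
            corr = default_latent_corr(self.task_names)
        corr = np.asarray(corr, dtype=float)
        object.__setattr__(self, "latent_corr", corr)
        self.validate()

    def validate(self) -> None:
        n = len(self.task_names)
        if len(set(self.task_names)) != n:
            raise ValueError("task_names must be unique")
        if self.n_per_group < 5:
            raise ValueError(f"n_per_group must be >= 5, got {self.n_per_group}")
        if not (0.0 < self.loading <= 1.0):
            raise ValueError(f"loading must be in (0, 1], got {self.loading}")
        corr = self.latent_corr
        if corr.shape != (n, n):
            raise ValueError(f"latent_corr must be {n}x{n}, got {corr.shape}")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError("latent_corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ValueError("latent_corr must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-8:
            raise ValueError(
                "latent_corr is not positive semi-definite; "
                "repair it with nearest_valid_corr() first"
            )
        for name in ("accuracy_sd_pct", "rt_sd_ms"):
            if any(s <= 0 for s in getattr(self, name)):
                raise ValueError(f"all {name} entries must be > 0")

    def with_(self, **kwargs) -> "CohortSpec":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def nearest_valid_corr(
    matrix: np.ndarray, tol: float = 1e-10, max_iter: int = 1000
) -> np.ndarray:
    """Project a symmetric unit-diagonal matrix onto the valid correlation set.

    Alternating projections between the positive semi-definite cone
    (eigenvalue clipping) and the unit-diagonal affine set, iterated to
    convergence.  A matrix that is already a valid correlation matrix is
    returned unchanged (up to symmetrization).

    Raises
    ------
    ValueError : non-square or non-symmetric input.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix must be square, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-8):
        raise ValueError("matrix must have unit diagonal")
    x = (m + m.T) / 2.0
    if np.linalg.eigvalsh(x).min() >= -tol:
        np.fill_diagonal(x, 1.0)
        return x
    for _ in range(max_iter):
        vals, vecs = np.linalg.eigh(x)
        x_psd = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
        x_new = x_psd.copy()
        np.fill_diagonal(x_new, 1.0)
        np.clip(x_new, -1.0, 1.0, out=x_new)
        if np.max(np.abs(x_new - x)) < tol:
            x = x_new
            break
        x = x_new
    # final exact-PSD step: clip eigenvalues, renormalize to unit diagonal
    x = (x + x.T) / 2.0
    vals, vecs = np.linalg.eigh(x)
    x = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    d = np.sqrt(np.clip(np.diag(x), 1e-300, None))
    x = x / np.outer(d, d)
    x = (x + x.T) / 2.0
    np.fill_diagonal(x, 1.0)
    return x


def plant_group_difference(
    base_corr: np.ndarray, edge_deltas: dict[tuple[int, int] | tuple[str, str], float],
    task_names: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Additively modify selected pairwise correlations, then repair to PSD.

    ``edge_deltas`` maps task pairs (indices, or names when ``task_names`` is
    given) to additive changes of the latent correlation.  Raises if a delta
    would push any |rho| to 1 or beyond.
    """
    corr = np.asarray(base_corr, dtype=float).copy()
    for pair, delta in edge_deltas.items():
        i, j = pair
        if task_names is not None and isinstance(i, str):
            i, j = task_names.index(i), task_names.index(j)
        if i == j:
            raise ValueError("edge_deltas must reference off-diagonal pairs")
        new = corr[i, j] + delta
        if abs(new) >= 1.0:
            raise ValueError(
                f"delta {delta:+.3f} on pair ({pair[0]}, {pair[1]}) pushes "
                f"|rho| to {abs(new):.3f} >= 1"
            )
        corr[i, j] = corr[j, i] = new
    return nearest_valid_corr(corr)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one synthetic cohort as a long-form score table.

    Returns a DataFrame with columns ``participant_id, group, task,
    accuracy_pct, mean_rt_ms`` — one row per participant x task.  Per
    participant, task latents ``z ~ MVN(0, latent_corr)``; accuracy and
    negated RT emissions are ``sqrt(loading) * z + sqrt(1 - loading) * eps``
    with independent standard-normal ``eps``, rescaled to each task's
    emission mean/sd.  Larger latent -> higher accuracy and faster RT.
    Accuracy is clipped to [0, 100]; RT is floored at 1 ms (both rare at
    the default emission scales, and logged when they occur).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_per_group, len(spec.task_names)
    # eigen factor (not Cholesky): tolerates singular correlation targets
    vals, vecs = np.linalg.eigh(spec.latent_corr)
    factor = vecs * np.sqrt(np.clip(vals, 0.0, None))
    latent = rng.standard_normal((n, k)) @ factor.T
    a = np.sqrt(spec.loading)
    b = np.sqrt(1.0 - spec.loading)
    acc_z = a * latent + b * rng.standard_normal((n, k))
    rt_fast_z = a * latent + b * rng.standard_normal((n, k))

    acc = np.asarray(spec.accuracy_mean_pct) + np.asarray(spec.accuracy_sd_pct) * acc_z
    # larger latent -> faster (smaller) RT
    rt = np.asarray(spec.rt_mean_ms) - np.asarray(spec.rt_sd_ms) * rt_fast_z

    n_clip_acc = int(np.sum((acc < 0) | (acc > 100)))
    if n_clip_acc:
        logger.info("clipped %d accuracy values to [0, 100]", n_clip_acc)
    acc = np.clip(acc, 0.0, 100.0)
    n_clip_rt = int(np.sum(rt < 1.0))
    if n_clip_rt:
        logger.info("floored %d reaction times at 1 ms", n_clip_rt)
    rt = np.maximum(rt, 1.0)

    pid = [f"{spec.group}{i + 1:03d}" for i in range(n)]
    return pd.DataFrame(
        {
            "participant_id": np.repeat(pid, k),
            "group": spec.group,
            "task": np.tile(spec.task_names, n),
            "accuracy_pct": acc.ravel(),
            "mean_rt_ms": rt.ravel(),
        }
    )


def generate_two_group_cohort(
    spec_a: CohortSpec, spec_b: CohortSpec
) -> pd.DataFrame:
    """Concatenate two group cohorts into one score table.

    The two specs must share the task battery and carry distinct group
    labels; distinct seeds give independent groups, identical specs give
    byte-identical duplicated data (useful as an exact null).
    """
    if spec_a.task_names != spec_b.task_names:
        raise ValueError("both groups must share the same task battery")
    if spec_a.group == spec_b.group:
        raise ValueError("groups must carry distinct labels")
    return pd.concat(
        [generate_cohort(spec_a), generate_cohort(spec_b)], ignore_index=True
    )


def generate_matched_cohorts(
    base_spec: CohortSpec,
    edge_deltas: dict | None = None,
    uniform_delta: float = 0.0,
    group_a: str = "A",
    group_b: str = "B",
) -> pd.DataFrame:
    """Two matched groups differing only in their latent correlation.

    Emulates a participant-matched design with common random numbers: both
    groups reuse the seed (hence the underlying standard-normal draws) of
    ``base_spec``; group A's latent correlation is ``base_spec.latent_corr``
    with ``edge_deltas`` and/or a ``uniform_delta`` added to every pair
    (repaired to PSD), group B keeps the base matrix.  With all deltas zero
    the two groups are byte-identical copies of one cohort — the exact-null
    configuration.
    """
    k = len(base_spec.task_names)
    deltas = dict(edge_deltas or {})
    if uniform_delta:
        for i in range(k):
            for j in range(i + 1, k):
                deltas[(i, j)] = deltas.get((i, j), 0.0) + uniform_delta
    corr_a = (
        plant_group_difference(base_spec.latent_corr, deltas, base_spec.task_names)
        if deltas
        else base_spec.latent_corr
    )
    spec_a = base_spec.with_(latent_corr=corr_a, group=group_a)
    spec_b = base_spec.with_(group=group_b)
    return generate_two_group_cohort(spec_a, spec_b)
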