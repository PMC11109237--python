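"""Case-wise bootstrap of the correlation -> TMFG -> metrics chain.

Participants (rows of the composite matrix) are resampled with replacement
to the original sample size; each replicate re-ranks the resampled data,
rebuilds the Spearman matrix, refilters the TMFG and recomputes every node
and global metric.  The B replicate values per metric form a reference
distribution used two ways:

- stability: the empirical (unresampled) metric is called stable when it
  lies inside the 2.5-97.5 percentile interval (CI95) of its distribution;
- group comparison: the two groups' distributions are compared metric-wise
  with Welch t-tests, Bonferroni-corrected within declared families.

The comparison treats the B resamples as independent observations (degrees
of freedom ~ 2B - 2), the convention of the bootstrap-comparison literature
this mirrors.  That convention is anti-conservative for inference about the
underlying populations — bootstrap spread reflects sampling noise of a
*single* cohort, so two independently sampled cohorts from one population
will typically differ "significantly" under it.  It is reproduced
deliberately and flagged; see docs/methods.md.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import GLOBAL_METRIC_NAMES, metric_vector
from .preprocess import compare_performance, compute_composites
from .network import TMFGNetwork
from .tmfg import tmfg_adjacency

logger = logging.getLogger(__name__)


@dataclass
class BootstrapDistribution:
    """Resampled values of one metric for one group, with its CI95.

    With fewer than 40 replicates the percentile CI is too coarse to be
    meaningful; ``ci95`` and ``stable`` are then ``None``.
    """

    metric_name: str
    group: str
    values: np.ndarray
    empirical_value: float
    ci95: tuple[float, float] | None = field(init=False)
    stable: bool | None = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size >= 40:
            self.ci95 = ci95(self.values)
            self.stable = bool(
                self.ci95[0] <= self.empirical_value <= self.ci95[1]
            )
        else:
            self.ci95 = None
            self.stable = None


def ci95(values: np.ndarray) -> tuple[float, float]:
    """2.5th and 97.5th percentiles (linear interpolation)."""
    values = np.asarray(values, dtype=float)
    if values.size < 40:
        raise ValueError(
            f"need at least 40 bootstrap values for a CI95, got {values.size}"
        )
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


def _spearman_abs(X: np.ndarray) -> np.ndarray:
    """|Spearman rho| with zero diagonal, fast path for complete data."""
    ranks = stats.rankdata(X, axis=0)
    rho = np.corrcoef(ranks, rowvar=False)
    w = np.abs(rho)
    np.fill_diagonal(w, 0.0)
    return w


class CasewiseBootstrap:
    """Bootstrap estimator over a participants x tasks composite matrix.

    Parameters
    ----------
    B : number of bootstrap replicates.
    seed : master seed; replicate b draws from the deterministic substream
        ``SeedSequence(seed, spawn_key=(b,))``, so increasing B extends the
        replicate set without reshuffling earlier replicates.
    n_restarts : Louvain restarts inside each replicate (the empirical
        network always uses ``empirical_restarts``).
    empirical_restarts : Louvain restarts for the empirical network.
    max_redraw_factor : a replicate with a degenerate (zero-variance) task
        column is redrawn; more than ``max_redraw_factor * B`` total redraws
        raises a degenerate-data error.

    Attributes (after ``fit``)
    --------------------------
    distributions_ : dict metric name -> :class:`BootstrapDistribution`.
    empirical_ : dict metric name -> empirical value.
    n_redraws_ : degenerate replicates redrawn.
    """

    def __init__(
        self,
        B: int = 1000,
        seed: int = 0,
        n_restarts: int = 10,
        empirical_restarts: int = 100,
        max_redraw_factor: int = 100,
    ):
        self.B = B
        self.seed = seed
        self.n_restarts = n_restarts
        self.empirical_restarts = empirical_restarts
        self.max_redraw_factor = max_redraw_factor

    def get_params(self, deep: bool = True) -> dict:
        return {
            "B": self.B,
            "seed": self.seed,
            "n_restarts": self.n_restarts,
            "empirical_restarts": self.empirical_restarts,
            "max_redraw_factor": self.max_redraw_factor,
        }

    def set_params(self, **params) -> "CasewiseBootstrap":
        known = self.get_params()
        for key, value in params.items():
            if key not in known:
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X: pd.DataFrame, y=None, group: str = "all") -> "CasewiseBootstrap":
        X = pd.DataFrame(X)
        if X.shape[0] < 10:
            raise ValueError(f"need at least 10 participants, got {X.shape[0]}")
        if self.B < 2:
            raise ValueError("B must be >= 2")
        names = tuple(map(str, X.columns))
        arr = X.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError(
                "composite matrix contains missing cells; bootstrap requires "
                "complete rows (drop or restrict participants first)"
            )
        if (arr == arr[0]).all(axis=0).any():
            raise ValueError("a task column is constant; data are degenerate")

        n = arr.shape[0]
        w_emp = tmfg_adjacency(_spearman_abs(arr))
        self.empirical_ = metric_vector(
            w_emp, names, n_restarts=self.empirical_restarts, seed=self.seed
        )

        n_redraws = 0
        max_redraws = self.max_redraw_factor * self.B
        samples: dict[str, list[float]] = {k: [] for k in self.empirical_}
        for b in range(self.B):
            rng = np.random.default_rng(
                np.random.SeedSequence(self.seed, spawn_key=(b,))
            )
            while True:
                idx = rng.integers(0, n, size=n)
                Xb = arr[idx]
                if not (Xb == Xb[0]).all(axis=0).any():
                    break
                n_redraws += 1
                if n_redraws > max_redraws:
                    raise ValueError(
                        "persistent degenerate resamples: a task column keeps "
                        "collapsing to a constant"
                    )
            wb = tmfg_adjacency(_spearman_abs(Xb))
            mv = metric_vector(wb, names, n_restarts=self.n_restarts, seed=b)
            for k, v in mv.items():
                samples[k].append(v)
        if n_redraws:
            logger.info("redrew %d degenerate bootstrap replicates", n_redraws)
        self.n_redraws_ = n_redraws
        self.distributions_ = {
            k: BootstrapDistribution(
                metric_name=k,
                group=group,
                values=np.asarray(v),
                empirical_value=self.empirical_[k],
            )
            for k, v in samples.items()
        }
        return self


def casewise_bootstrap(
    composites: pd.DataFrame, B: int = 1000, seed: int = 0, **kwargs
) -> dict[str, BootstrapDistribution]:
    """Functional wrapper over :class:`CasewiseBootstrap`."""
    group = kwargs.pop("group", "all")
    est = CasewiseBootstrap(B=B, seed=seed, **kwargs)
    return est.fit(composites, group=group).distributions_


def _metric_family(name: str) -> str:
    return "global" if name in GLOBAL_METRIC_NAMES else name.split("[", 1)[0]


def compare_groups(
    dist_a: dict[str, BootstrapDistribution],
    dist_b: dict[str, BootstrapDistribution],
    families: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Welch t-tests between two groups' bootstrap distributions.

    Sign convention: positive t means group_b larger.  Bonferroni families
    default to the metrics present: the 4 global metrics form one family and
    each node-metric type (strength, clustering, local efficiency — one value
    per node) forms its own.  ``families`` may override family sizes by name.
    """
    shared = [k for k in dist_a if k in dist_b]
    skipped = set(dist_a) ^ set(dist_b)
    for k in skipped:
        logger.warning("metric %s present in only one group; skipped", k)
    fam_counts: dict[str, int] = {}
    for k in shared:
        fam = _metric_family(k)
        fam_counts[fam] = fam_counts.get(fam, 0) + 1
    if families:
        fam_counts.update(families)

    rows = []
    for k in shared:
        a, b = dist_a[k], dist_b[k]
        if np.ptp(a.values) == 0 and np.ptp(b.values) == 0:
            t, df = 0.0, float(len(a.values) + len(b.values) - 2)
            p = 1.0 if np.allclose(a.values.mean(), b.values.mean()) else 0.0
        else:
            res = stats.ttest_ind(b.values, a.values, equal_var=False)
            t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
        m = fam_counts[_metric_family(k)]
        rows.append(
            dict(
                metric=k,
                family=_metric_family(k),
                t_stat=t,
                degrees_of_freedom=df,
                p_raw=p,
                p_bonferroni=min(1.0, p * m),
                direction=(b.group if t > 0 else a.group) if t != 0 else "none",
            )
        )
    return pd.DataFrame(rows)


def run_full_study(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    threshold_pct: float = 50.0,
    n_restarts: int = 10,
    empirical_restarts: int = 100,
) -> dict:
    """The full analysis: pooled sample plus both groups, end to end.

    Steps: accuracy filtering and pooled-sample composite scoring; raw
    performance comparison (Wilcoxon, Bonferroni); then for each of the
    pooled sample, group A and group B: Spearman/Holm association, TMFG,
    node and global metrics, case-wise bootstrap with CI95 stability; and
    finally the between-group Welch comparison of bootstrap distributions.

    Returns a report dict holding the estimators, distributions and tables;
    see :mod:`cognet.io` for serialization.
    """
    composites = compute_composites(
        table, scaling_label="pooled", threshold_pct=threshold_pct
    )
    performance = compare_performance(
        table, group_a, group_b, threshold_pct=threshold_pct
    )

    analyses = {}
    frames = {
        "all": composites.composite,
        group_a: composites.subset(group_a),
        group_b: composites.subset(group_b),
    }
    for i, (label, frame) in enumerate(frames.items()):
        net_est = TMFGNetwork(alpha=alpha, n_restarts=empirical_restarts,
                              seed=seed).fit(frame)
        complete = frame.dropna(axis=0)
        if len(complete) < len(frame):
            logger.info(
                "%s: dropped %d incomplete participants for the bootstrap",
                label, len(frame) - len(complete),
            )
        boot = CasewiseBootstrap(
            B=B,
            seed=(seed + 7919 * (i + 1)) % (2**31),
            n_restarts=n_restarts,
            empirical_restarts=empirical_restarts,
        ).fit(complete, group=label)
        analyses[label] = {"network": net_est, "bootstrap": boot}

    comparison = compare_groups(
        analyses[group_a]["bootstrap"].distributions_,
        analyses[group_b]["bootstrap"].distributions_,
    )
    return {
        "composites": composites,
        "performance": performance,
        "analyses": analyses,
        "comparison": comparison,
        "params": dict(
            group_a=group_a, group_b=group_b, B=B, seed=seed, alpha=alpha,
            threshold_pct=threshold_pct, n_restarts=n_restarts,
            empirical_restarts=empirical_restarts,
        ),
    }
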