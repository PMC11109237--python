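"""From raw accuracy/RT scores to composite z-scores, plus group comparison.

Each task yields two measures per participant: accuracy (% correct) and mean
reaction time (ms).  Scores with accuracy below a threshold (default 50%,
chance level on two-alternative tasks) are removed record-wise.  Both
measures are z-standardized per task over a scaling population — RT after
negation, so that higher always means better — and averaged into a single
composite z-score per participant x task.  Raw group differences are
screened with two-sample Wilcoxon rank-sum tests, Bonferroni-corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SCORE_COLUMNS = ("participant_id", "group", "task", "accuracy_pct", "mean_rt_ms")

#: Sample-sd convention used for every z-standardization in the package.
DDOF = 1


@dataclass
class CompositeMatrix:
    """Participants x tasks composite z-scores with companion z-matrices.

    ``composite`` is the entrywise mean of ``accuracy_z`` and ``rt_z``
    (the z-score of negated mean RT).  Cells excluded upstream are NaN.
    ``groups`` maps participant_id -> group label;  ``scaling_population``
    names the sample over which the standardization was computed.
    """

    composite: pd.DataFrame
    accuracy_z: pd.DataFrame
    rt_z: pd.DataFrame
    groups: pd.Series
    scaling_population: str = "all"

    @property
    def tasks(self) -> list[str]:
        return list(self.composite.columns)

    def subset(self, group: str) -> pd.DataFrame:
        """Composite rows of one group (scaling unchanged)."""
        return self.composite.loc[self.groups[self.groups == group].index]


def filter_low_accuracy(
    table: pd.DataFrame, threshold_pct: float = 50.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop records whose accuracy falls below ``threshold_pct``.

    Removal is per (participant, task) record — a participant failing one
    task keeps their other scores.  Returns the filtered table and an
    exclusion log with one row per removed record.
    """
    table = _validate_scores(table)
    below = table["accuracy_pct"] < threshold_pct
    log = table.loc[below, ["participant_id", "task", "accuracy_pct"]].reset_index(
        drop=True
    )
    kept = table.loc[~below].reset_index(drop=True)
    if below.any():
        logger.info(
            "excluded %d of %d records below %.1f%% accuracy",
            int(below.sum()), len(table), threshold_pct,
        )
    if kept.empty:
        logger.warning("all records excluded at threshold %.1f%%", threshold_pct)
    return kept, log


def compute_composites(
    table: pd.DataFrame,
    scaling_population: list[str] | None = None,
    scaling_label: str | None = None,
    threshold_pct: float | None = 50.0,
) -> CompositeMatrix:
    """Z-standardize accuracy and negated RT per task and average them.

    ``scaling_population`` restricts the participants over which each task's
    mean and sd are estimated (sample sd, ddof=1); all participants are then
    transformed with those constants.  Defaults to the full sample.  A task
    whose accuracy or RT has zero variance over the scaling population is a
    degenerate column and raises.
    """
    scorer = CompositeScorer(threshold_pct=threshold_pct)
    scorer.fit(table, scaling_population=scaling_population)
    return scorer.transform(table, scaling_label=scaling_label)


class CompositeScorer:
    """Transformer from long-form score tables to composite z-score matrices.

    Follows the scikit-learn estimator protocol: :meth:`fit` learns per-task
    means and standard deviations of accuracy and negated RT over the scaling
    population, :meth:`transform` applies them to any table on the same task
    battery.  Fitting and transforming on the same table reproduces the
    classical pooled-sample z-scoring.

    Parameters
    ----------
    threshold_pct : accuracy exclusion threshold applied before fitting and
        before every transform (set to ``None`` to disable).
    ddof : delta degrees of freedom of the sd estimate (1 = sample sd).

    Attributes
    ----------
    stats_ : DataFrame indexed by task with columns
        ``acc_mean, acc_sd, rt_mean, rt_sd`` (RT stats on the raw scale).
    scaling_population_ : the participant ids used for fitting.
    """

    def __init__(self, threshold_pct: float | None = 50.0, ddof: int = DDOF):
        self.threshold_pct = threshold_pct
        self.ddof = ddof

    # -- sklearn plumbing ------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"threshold_pct": self.threshold_pct, "ddof": self.ddof}

    def set_params(self, **params) -> "CompositeScorer":
        for key, value in params.items():
            if key not in ("threshold_pct", "ddof"):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # --------------------------------------------------------------------
    def fit(
        self, table: pd.DataFrame, scaling_population: list[str] | None = None
    ) -> "CompositeScorer":
        table = _validate_scores(table)
        if self.threshold_pct is not None:
            table, _ = filter_low_accuracy(table, self.threshold_pct)
        if scaling_population is not None:
            table = table[table["participant_id"].isin(scaling_population)]
        counts = table.groupby("task")["participant_id"].nunique()
        if (counts < 3).any():
            bad = counts[counts < 3].index.tolist()
            raise ValueError(f"fewer than 3 scaling participants for tasks {bad}")
        grouped = table.groupby("task")
        st = pd.DataFrame(
            {
                "acc_mean": grouped["accuracy_pct"].mean(),
                "acc_sd": grouped["accuracy_pct"].std(ddof=self.ddof),
                "rt_mean": grouped["mean_rt_ms"].mean(),
                "rt_sd": grouped["mean_rt_ms"].std(ddof=self.ddof),
            }
        )
        degenerate = st.index[(st["acc_sd"] == 0) | (st["rt_sd"] == 0)].tolist()
        if degenerate:
            raise ValueError(
                f"zero variance in accuracy or RT for tasks {degenerate}; "
                "cannot z-standardize a degenerate column"
            )
        self.stats_ = st
        self.scaling_population_ = sorted(table["participant_id"].unique())
        return self

    def transform(
        self, table: pd.DataFrame, scaling_label: str | None = None
    ) -> CompositeMatrix:
        if not hasattr(self, "stats_"):
            raise AttributeError("CompositeScorer is not fitted; call fit() first")
        table = _validate_scores(table)
        if self.threshold_pct is not None:
            table, _ = filter_low_accuracy(table, self.threshold_pct)
        task_order = [t for t in table["task"].unique() if t in self.stats_.index]
        missing = set(table["task"]) - set(self.stats_.index)
        if missing:
            raise ValueError(f"tasks not seen during fit: {sorted(missing)}")

        acc = table.pivot(index="participant_id", columns="task", values="accuracy_pct")
        rt = table.pivot(index="participant_id", columns="task", values="mean_rt_ms")
        acc, rt = acc[task_order], rt[task_order]
        st = self.stats_.loc[task_order]
        acc_z = (acc - st["acc_mean"]) / st["acc_sd"]
        # negate RT before standardizing: faster -> larger z
        rt_z = (-rt - (-st["rt_mean"])) / st["rt_sd"]
        composite = (acc_z + rt_z) / 2.0

        groups = (
            table.drop_duplicates("participant_id")
            .set_index("participant_id")["group"]
            .reindex(composite.index)
        )
        return CompositeMatrix(
            composite=composite,
            accuracy_z=acc_z,
            rt_z=rt_z,
            groups=groups,
            scaling_population=scaling_label or "fitted sample",
        )

    def fit_transform(
        self,
        table: pd.DataFrame,
        scaling_population: list[str] | None = None,
        scaling_label: str | None = None,
    ) -> CompositeMatrix:
        return self.fit(table, scaling_population).transform(
            table, scaling_label=scaling_label
        )


def wilcoxon_rank_sum(
    a: np.ndarray, b: np.ndarray, exact_below: int = 20
) -> tuple[float, float]:
    """Two-sided two-sample Wilcoxon (Mann-Whitney) test.

    Exact null enumeration when both groups have fewer than ``exact_below``
    observations and there are no ties; otherwise the normal approximation
    with continuity correction.  Returns (U statistic of the first sample,
    two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) < exact_below and len(b) < exact_below and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_performance(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    threshold_pct: float | None = 50.0,
) -> pd.DataFrame:
    """Wilcoxon rank-sum screening of raw group differences.

    For every task x measure (accuracy, RT, composite z) the two groups are
    compared with a two-sided rank-sum test; p-values are Bonferroni-adjusted
    over all comparisons performed in the call.  Composites are scaled over
    the pooled two-group sample.  A task missing entirely in one group is
    reported with NaN statistics and the run continues.
    """
    table = _validate_scores(table)
    present = set(table["group"])
    for g in (group_a, group_b):
        if g not in present:
            raise ValueError(f"group {g!r} not present in the table")
    sub = table[table["group"].isin([group_a, group_b])]
    if threshold_pct is not None:
        sub, _ = filter_low_accuracy(sub, threshold_pct)
    cm = compute_composites(sub, scaling_label="pooled")

    rows = []
    for task in sub["task"].unique():
        task_tab = sub[sub["task"] == task]
        comp_col = cm.composite[task]
        for measure, series in (
            ("accuracy_pct", task_tab.set_index("participant_id")["accuracy_pct"]),
            ("mean_rt_ms", task_tab.set_index("participant_id")["mean_rt_ms"]),
            ("composite_z", comp_col.dropna()),
        ):
            grp = cm.groups.reindex(series.index)
            if measure != "composite_z":
                grp = task_tab.set_index("participant_id")["group"].reindex(series.index)
            va = series[grp == group_a].to_numpy()
            vb = series[grp == group_b].to_numpy()
            if len(va) == 0 or len(vb) == 0:
                rows.append(
                    dict(task=task, measure=measure,
                         mean_a=np.nan, sd_a=np.nan, mean_b=np.nan, sd_b=np.nan,
                         statistic=np.nan, p_raw=np.nan)
                )
                logger.warning("no %s data for task %s in one group", measure, task)
                continue
            u, p = wilcoxon_rank_sum(va, vb)
            rows.append(
                dict(
                    task=task, measure=measure,
                    mean_a=va.mean(), sd_a=va.std(ddof=DDOF),
                    mean_b=vb.mean(), sd_b=vb.std(ddof=DDOF),
                    statistic=u, p_raw=p,
                )
            )
    out = pd.DataFrame(rows)
    m = int(out["p_raw"].notna().sum())
    out["p_bonferroni"] = np.minimum(out["p_raw"] * m, 1.0)
    out.attrs["group_a"], out.attrs["group_b"] = group_a, group_b
    out.attrs["n_comparisons"] = m
    return out


def _validate_scores(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SCORE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"score table missing columns {missing}")
    if table.duplicated(["participant_id", "task"]).any():
        dups = table[table.duplicated(["participant_id", "task"], keep=False)]
        pair = dups.iloc[0]
        raise ValueError(
            f"duplicate (participant, task) record: "
            f"({pair['participant_id']}, {pair['task']})"
        )
    acc = pd.to_numeric(table["accuracy_pct"], errors="raise")
    rt = pd.to_numeric(table["mean_rt_ms"], errors="raise")
    bad = table.index[(acc < 0) | (acc > 100)]
    if len(bad):
        raise ValueError(f"accuracy_pct outside [0, 100] at row {bad[0]}")
    bad = table.index[rt <= 0]
    if len(bad):
        raise ValueError(f"mean_rt_ms must be positive; bad value at row {bad[0]}")
    return table
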