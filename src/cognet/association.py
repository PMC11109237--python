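"""Task x task Spearman association matrices with Holm-adjusted significance.

The inter-task network is built from zero-order Spearman rank correlations
of the composite z-scores.  Two-sided p-values use the t approximation on
n - 2 degrees of freedom; multiplicity over the k(k-1)/2 unordered task
pairs is controlled with the Holm step-down procedure.  Missing cells
(records excluded upstream) are handled pairwise-complete.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class AssociationMatrix:
    """Spearman rho with raw and Holm-adjusted p-values per task pair."""

    rho: pd.DataFrame
    p_raw: pd.DataFrame
    p_holm: pd.DataFrame
    n_pairs: pd.DataFrame

    @property
    def tasks(self) -> list[str]:
        return list(self.rho.columns)

    def abs_weights(self) -> np.ndarray:
        """|rho| with zero diagonal — the weight matrix the network filter consumes."""
        w = np.abs(self.rho.to_numpy(dtype=float))
        np.fill_diagonal(w, 0.0)
        return np.nan_to_num(w, nan=0.0)


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson formula on midranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return np.nan
    return float((rx * ry).sum() / denom)


def _spearman_p(rho: float, n: int) -> float:
    """Two-sided p via the t approximation on n - 2 df."""
    if n < 4 or not np.isfinite(rho):
        return np.nan
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment, returned in the input order.

    Sort ascending; the i-th smallest p becomes
    ``max_{j <= i} min(1, (m - j + 1) * p_(j))`` — monotone in the rank
    order of the raw p-values and never exceeding 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = np.full(p.shape, np.nan)
    idx = np.where(finite)[0]
    m = len(idx)
    if m == 0:
        return adjusted
    order = idx[np.argsort(p[idx], kind="stable")]
    running = 0.0
    for j, i in enumerate(order):
        running = max(running, min(1.0, (m - j) * p[i]))
        adjusted[i] = running
    return adjusted


def spearman_matrix(
    composites: pd.DataFrame, min_pairs: int = 4
) -> AssociationMatrix:
    """Pairwise-complete Spearman correlation of a participants x tasks matrix.

    Holm adjustment is applied over all off-diagonal unordered pairs with at
    least ``min_pairs`` complete observations; pairs below that are reported
    as missing with a warning.
    """
    tasks = list(composites.columns)
    k = len(tasks)
    X = composites.to_numpy(dtype=float)
    rho = np.eye(k)
    p_raw = np.full((k, k), np.nan)
    n_pairs = np.zeros((k, k), dtype=int)
    np.fill_diagonal(n_pairs, np.sum(np.isfinite(X), axis=0))

    complete = np.isfinite(X)
    if complete.all():
        # fast path: no missing cells, one rank transform for the whole matrix
        ranks = stats.rankdata(X, axis=0)
        rho = np.corrcoef(ranks, rowvar=False)
        np.fill_diagonal(rho, 1.0)
        n = X.shape[0]
        n_pairs[:] = n
        for i in range(k):
            for j in range(i + 1, k):
                p_raw[i, j] = p_raw[j, i] = _spearman_p(rho[i, j], n)
    else:
        for i in range(k):
            for j in range(i + 1, k):
                mask = complete[:, i] & complete[:, j]
                n = int(mask.sum())
                n_pairs[i, j] = n_pairs[j, i] = n
                if n < min_pairs:
                    rho[i, j] = rho[j, i] = np.nan
                    logger.warning(
                        "pair (%s, %s) has only %d complete observations; "
                        "reported missing", tasks[i], tasks[j], n,
                    )
                    continue
                r = spearman_rho(X[mask, i], X[mask, j])
                rho[i, j] = rho[j, i] = r
                p_raw[i, j] = p_raw[j, i] = _spearman_p(r, n)

    iu = np.triu_indices(k, 1)
    p_holm_flat = holm_adjust(p_raw[iu])
    p_holm = np.full((k, k), np.nan)
    p_holm[iu] = p_holm_flat
    p_holm.T[iu] = p_holm_flat

    as_df = lambda a: pd.DataFrame(a, index=tasks, columns=tasks)
    return AssociationMatrix(
        rho=as_df(rho), p_raw=as_df(p_raw), p_holm=as_df(p_holm), n_pairs=as_df(n_pairs)
    )


def significant_edges(
    assoc: AssociationMatrix, alpha: float = 0.05
) -> pd.DataFrame:
    """Task pairs with Holm-adjusted p below alpha, by descending |rho|."""
    tasks = assoc.tasks
    rows = []
    for i in range(len(tasks)):
        for j in range(i + 1, len(tasks)):
            p = assoc.p_holm.iat[i, j]
            if np.isfinite(p) and p < alpha:
                rows.append(
                    dict(task_a=tasks[i], task_b=tasks[j],
                         rho=assoc.rho.iat[i, j], p_holm=p)
                )
    out = pd.DataFrame(rows, columns=["task_a", "task_b", "rho", "p_holm"])
    return out.reindex(out["rho"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )
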