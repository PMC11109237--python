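"""Estimator tying association, planar filtering and metrics together.

`TMFGNetwork` plays the role covariance-structure estimators play in
scikit-learn (fit a participants x tasks matrix, read fitted structure off
trailing-underscore attributes): fitting computes the Spearman association
matrix, filters it to a triangulated maximally filtered graph on |rho|, and
derives the node and global metrics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import AssociationMatrix, significant_edges, spearman_matrix
from .metrics import GlobalMetrics, summarize
from .tmfg import WeightedNetwork, tmfg


class TMFGNetwork:
    """Spearman + TMFG + graph-metric pipeline as a single estimator.

    Parameters
    ----------
    alpha : significance level for the Holm-adjusted edge report (the report
        is descriptive; significance never gates which edges the filter keeps).
    n_restarts : Louvain restarts for the modularity estimate.
    seed : RNG seed for community detection.
    domain_labels : optional node -> cognitive-domain map for exports.

    Attributes (after ``fit``)
    --------------------------
    association_ : :class:`AssociationMatrix` — rho, raw and Holm p-values.
    network_ : :class:`WeightedNetwork` — the TMFG on edge weights |rho|.
    node_metrics_ : DataFrame of strength / clustering / local efficiency.
    global_metrics_ : :class:`GlobalMetrics` bundle.
    significant_edges_ : DataFrame of Holm-significant task pairs.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        n_restarts: int = 100,
        seed: int = 0,
        domain_labels: dict[str, str] | None = None,
    ):
        self.alpha = alpha
        self.n_restarts = n_restarts
        self.seed = seed
        self.domain_labels = domain_labels

    def get_params(self, deep: bool = True) -> dict:
        return {
            "alpha": self.alpha,
            "n_restarts": self.n_restarts,
            "seed": self.seed,
            "domain_labels": self.domain_labels,
        }

    def set_params(self, **params) -> "TMFGNetwork":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X: pd.DataFrame, y=None) -> "TMFGNetwork":
        """Fit on a participants x tasks composite matrix (NaN = excluded)."""
        X = pd.DataFrame(X)
        if X.shape[1] < 4:
            raise ValueError("need at least 4 tasks to build a planar filter")
        self.association_ = spearman_matrix(X)
        self.network_ = tmfg(
            self.association_.abs_weights(),
            nodes=tuple(map(str, X.columns)),
            domain_labels=self.domain_labels,
        )
        self.node_metrics_, self.global_metrics_ = summarize(
            self.network_, n_restarts=self.n_restarts, seed=self.seed
        )
        self.significant_edges_ = significant_edges(self.association_, self.alpha)
        return self

    def fit_metrics(self, X: pd.DataFrame) -> dict[str, float]:
        """Fit and return the four global metrics as a flat dict."""
        return self.fit(X).global_metrics_.as_dict()


def build_network(
    composites: pd.DataFrame, **kwargs
) -> tuple[AssociationMatrix, WeightedNetwork, pd.DataFrame, GlobalMetrics]:
    """Functional wrapper over :class:`TMFGNetwork`."""
    est = TMFGNetwork(**kwargs).fit(composites)
    return est.association_, est.network_, est.node_metrics_, est.global_metrics_
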