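"""Readers, writers and run configuration.

Canonical input is a long (tidy) CSV of per-participant, per-task scores:
``participant_id, group, task, accuracy_pct, mean_rt_ms``.  Networks are
exported as GraphML, GEXF (Gephi-compatible) or plain edge-list CSV with
node attributes task / domain / strength and edge attribute weight.  A
YAML run configuration captures every analysis switch and round-trips
exactly; report writers emit the JSON/CSV artifact set of a full run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .association import AssociationMatrix
from .preprocess import SCORE_COLUMNS, _validate_scores
from .tmfg import WeightedNetwork

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Every switch of a full pipeline run, serializable to YAML."""

    input: str = ""
    group_col: str = "group"
    groups: tuple[str, ...] = ("A", "B")
    tasks: tuple[str, ...] | None = None
    B: int = 1000
    seed: int = 0
    alpha: float = 0.05
    threshold_pct: float = 50.0
    bonferroni_global: int = 4
    distance_transform: str = "inverse"      # edge length = 1/weight
    clustering_variant: str = "onnela"
    louvain_restarts: int = 100
    bootstrap_restarts: int = 10
    out_dir: str = "cognet_out"

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["groups"] = list(self.groups)
        if self.tasks is not None:
            data["tasks"] = list(self.tasks)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "groups" in data:
            data["groups"] = tuple(data["groups"])
        if data.get("tasks") is not None:
            data["tasks"] = tuple(data["tasks"])
        return cls(**data)

    def digest(self) -> str:
        """Short stable hash for provenance stamps."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-form score CSV.

    Required columns per :data:`~cognet.preprocess.SCORE_COLUMNS`; unknown
    columns are preserved but ignored downstream.  Duplicate (participant,
    task) records, non-numeric scores, accuracies outside [0, 100] and
    non-positive RTs raise schema errors naming the offending row.
    """
    table = pd.read_csv(path)
    missing = [c for c in SCORE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("accuracy_pct", "mean_rt_ms"):
        try:
            table[col] = pd.to_numeric(table[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: non-numeric values in {col}: {exc}") from exc
    try:
        return _validate_scores(table)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_scores(table: pd.DataFrame, path: str | Path) -> None:
    table[list(SCORE_COLUMNS)].to_csv(path, index=False)


def write_network(
    net: WeightedNetwork,
    path: str | Path,
    fmt: str | None = None,
    node_metrics: pd.DataFrame | None = None,
) -> None:
    """Export a network as ``graphml``, ``gexf`` or ``edgelist`` (CSV).

    Node attributes task, domain and strength (plus any supplied node
    metrics) ride along in the XML formats so layout tools can size and
    color nodes directly.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".graphml": "graphml", ".gexf": "gexf", ".csv": "edgelist"}.get(
            path.suffix, "graphml"
        )
    g = net.to_networkx()
    strengths = net.weights.sum(axis=0)
    for i, v in enumerate(net.nodes):
        g.nodes[v]["strength"] = float(strengths[i])
        if node_metrics is not None and v in node_metrics.index:
            for col in node_metrics.columns:
                g.nodes[v][col] = float(node_metrics.loc[v, col])
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "gexf":
        nx.write_gexf(g, path)
    elif fmt == "edgelist":
        pd.DataFrame(net.edges(), columns=["source", "target", "weight"]).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path: str | Path) -> WeightedNetwork:
    """Read a network written by :func:`write_network` (graphml/gexf)."""
    path = Path(path)
    if path.suffix == ".gexf":
        g = nx.read_gexf(path)
    else:
        g = nx.read_graphml(path)
    return WeightedNetwork.from_networkx(g)


def write_association(assoc: AssociationMatrix, out_dir: str | Path, prefix: str) -> None:
    out = Path(out_dir)
    assoc.rho.to_csv(out / f"{prefix}_rho.csv")
    assoc.p_raw.to_csv(out / f"{prefix}_p_raw.csv")
    assoc.p_holm.to_csv(out / f"{prefix}_p_holm.csv")


def write_report(report: dict, out_dir: str | Path, config: RunConfig | None = None) -> None:
    """Write the artifact set of :func:`cognet.bootstrap.run_full_study`.

    Per analysis (pooled + both groups): association CSV trio, GraphML and
    GEXF networks, node-metric CSV; plus the performance-comparison CSV,
    the group-comparison CSV, and one JSON summary holding empirical
    metrics, CI95 bounds, stability flags and provenance (seed, config hash).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report["performance"].to_csv(out / "performance_comparison.csv", index=False)
    report["comparison"].to_csv(out / "group_comparison.csv", index=False)

    summary: dict = {"params": report["params"], "groups": {}}
    if config is not None:
        summary["config_hash"] = config.digest()
    for label, parts in report["analyses"].items():
        net_est, boot = parts["network"], parts["bootstrap"]
        safe = str(label).replace(" ", "_")
        write_association(net_est.association_, out, f"association_{safe}")
        write_network(net_est.network_, out / f"network_{safe}.graphml",
                      node_metrics=net_est.node_metrics_)
        write_network(net_est.network_, out / f"network_{safe}.gexf",
                      node_metrics=net_est.node_metrics_)
        net_est.node_metrics_.to_csv(out / f"node_metrics_{safe}.csv")
        summary["groups"][str(label)] = {
            "global_metrics": net_est.global_metrics_.as_dict(),
            "partition": net_est.global_metrics_.partition,
            "significant_edges": net_est.significant_edges_.to_dict("records"),
            "bootstrap": {
                name: {
                    "empirical": d.empirical_value,
                    "ci95": list(d.ci95) if d.ci95 is not None else None,
                    "stable": d.stable,
                    "mean": float(np.mean(d.values)),
                    "sd": float(np.std(d.values, ddof=1)),
                }
                for name, d in boot.distributions_.items()
            },
            "n_redraws": boot.n_redraws_,
        }
    (out / "report.json").write_text(json.dumps(summary, indent=2))
    logger.info("wrote report to %s", out)
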