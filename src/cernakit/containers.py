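"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

GROUP_CASE = "case"
GROUP_CONTROL = "control"

#: ordered confidence classes for interaction tables (ascending trust)
CONFIDENCE_CLASSES = ("low", "medium", "high", "very high")

INTERACTION_COLUMNS = ("source", "target", "edge_type", "confidence")


@dataclass
class ExpressionMatrix:
    """A feature x sample matrix of log2 intensities with sample labels.

    values
        DataFrame indexed by feature id, one column per sample id.
    groups
        Series mapping sample id -> ``"case"`` / ``"control"``.
    batches
        Optional Series mapping sample id -> batch label.
    """

    values: pd.DataFrame
    groups: pd.Series
    batches: pd.Series | None = None

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.groups[self.groups.isna()].index)
            raise ValueError(f"samples without group label: {missing}")
        if not self.values.index.is_unique:
            raise ValueError("duplicate feature ids")
        if not self.values.columns.is_unique:
            raise ValueError("duplicate sample ids")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        bad = set(self.groups.unique()) - {GROUP_CASE, GROUP_CONTROL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for g in (GROUP_CASE, GROUP_CONTROL):
            if (self.groups == g).sum() == 0:
                raise ValueError(f"group {g!r} is empty")
        if self.batches is not None:
            self.batches = self.batches.reindex(self.values.columns)
            if self.batches.isna().any():
                raise ValueError("samples without batch label")

    @property
    def case_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == GROUP_CASE])

    @property
    def control_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == GROUP_CONTROL])

    def copy_with(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=values,
            groups=self.groups.copy(),
            batches=None if self.batches is None else self.batches.copy(),
        )


def validate_interaction_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the (source, target, edge_type, confidence) table invariants."""
    for col in INTERACTION_COLUMNS[:3]:
        if col not in table.columns:
            raise ValueError(f"interaction table missing column {col!r}")
    if (table["source"] == table["target"]).any():
        raise ValueError("interaction table contains self-loops")
    if table.duplicated(subset=["source", "target", "edge_type"]).any():
        raise ValueError("duplicate (source, target, edge_type) rows")
    return table


class CeRNANetwork:
    """Tripartite circRNA-miRNA-gene network with direction attributes.

    Wraps an undirected :class:`networkx.Graph` whose nodes carry a
    ``role`` attribute (``circ`` / ``mir`` / ``gene``) and, for circRNA and
    gene nodes, a ``direction`` attribute (``up`` / ``down``).  Edges carry
    an ``edge_type`` attribute (``circ-mir`` / ``mir-gene``).
    """

    def __init__(self, graph: nx.Graph):
        self.graph = graph
        self.validate()

    def validate(self) -> None:
        g = self.graph
        for node, data in g.nodes(data=True):
            if data.get("role") not in {"circ", "mir", "gene"}:
                raise ValueError(f"node {node!r} has no valid role")
            if data["role"] in {"circ", "gene"} and data.get("direction") not in {"up", "down"}:
                raise ValueError(f"node {node!r} has no valid direction")
        for u, v, data in g.edges(data=True):
            roles = {g.nodes[u]["role"], g.nodes[v]["role"]}
            if roles == {"circ", "mir"}:
                expected = "circ-mir"
            elif roles == {"mir", "gene"}:
                expected = "mir-gene"
            else:
                raise ValueError(f"edge ({u!r}, {v!r}) violates tripartite structure")
            if data.get("edge_type") != expected:
                raise ValueError(f"edge ({u!r}, {v!r}) mistyped: {data.get('edge_type')!r}")
        # every miRNA bridges at least one circRNA and one gene
        for node in self.mirnas:
            neigh_roles = {g.nodes[n]["role"] for n in g.neighbors(node)}
            if not {"circ", "gene"} <= neigh_roles:
                raise ValueError(f"miRNA {node!r} lacks a circRNA or gene partner")
        # direction consistency along every circ-mir-gene path
        for mir in self.mirnas:
            circs = [n for n in g.neighbors(mir) if g.nodes[n]["role"] == "circ"]
            genes = [n for n in g.neighbors(mir) if g.nodes[n]["role"] == "gene"]
            for c in circs:
                for gene in genes:
                    if g.nodes[c]["direction"] != g.nodes[gene]["direction"]:
                        raise ValueError(
                            f"inconsistent directions on path {c!r}-{mir!r}-{gene!r}"
                        )

    def _nodes_with_role(self, role: str) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["role"] == role)

    @property
    def circrnas(self) -> list[str]:
        return self._nodes_with_role("circ")

    @property
    def mirnas(self) -> list[str]:
        return self._nodes_with_role("mir")

    @property
    def genes(self) -> list[str]:
        return self._nodes_with_role("gene")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def composition(self) -> dict[str, int]:
        return {
            "n_circ": len(self.circrnas),
            "n_mir": len(self.mirnas),
            "n_gene": len(self.genes),
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
        }

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for u, v, data in self.graph.edges(data=True):
            # orient circ->mir and mir->gene for readability
            if self.graph.nodes[v]["role"] == "circ" or (
                self.graph.nodes[v]["role"] == "mir"
                and self.graph.nodes[u]["role"] == "gene"
            ):
                u, v = v, u
            rows.append({"source": u, "target": v, "edge_type": data["edge_type"]})
        return (
            pd.DataFrame(rows, columns=["source", "target", "edge_type"])
            .sort_values(["edge_type", "source", "target"])
            .reset_index(drop=True)
        )

    def node_table(self) -> pd.DataFrame:
        rows = [
            {"id": n, "role": d["role"], "direction": d.get("direction", "")}
            for n, d in self.graph.nodes(data=True)
        ]
        return (
            pd.DataFrame(rows, columns=["id", "role", "direction"])
            .sort_values(["role", "id"])
            .reset_index(drop=True)
        )


@dataclass
class ModelComparison:
    """Discrimination and reclassification summary of base vs augmented model."""

    model_name: str
    auc_base: float
    auc_base_ci: tuple[float, float]
    auc_augmented: float
    auc_augmented_ci: tuple[float, float]
    delong_p: float
    idi: float
    idi_ci: tuple[float, float]
    idi_p: float
    nri: float
    nri_ci: tuple[float, float]
    nri_p: float
    n: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.converged:
            for a in (self.auc_base, self.auc_augmented):
                if not 0.0 <= a <= 1.0:
                    raise ValueError("AUC outside [0, 1]")
            if not -2.0 <= self.nri <= 2.0:
                raise ValueError("NRI outside [-2, 2]")
            if not -1.0 <= self.idi <= 1.0:
                raise ValueError("IDI outside [-1, 1]")

    def as_row(self) -> dict:
        return {
            "model": self.model_name,
            "auc": self.auc_augmented,
            "auc_ci_low": self.auc_augmented_ci[0],
            "auc_ci_high": self.auc_augmented_ci[1],
            "delong_p_vs_base": self.delong_p,
            "idi": self.idi,
            "idi_ci_low": self.idi_ci[0],
            "idi_ci_high": self.idi_ci[1],
            "idi_p": self.idi_p,
            "nri": self.nri,
            "nri_ci_low": self.nri_ci[0],
            "nri_ci_high": self.nri_ci[1],
            "nri_p": self.nri_p,
            "converged": self.converged,
        }
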