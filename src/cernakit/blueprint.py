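"""Study blueprint: the design constants of the simulated ceRNA study.

A :class:`StudyBlueprint` pins down everything the synthetic-data
generator needs — array and cohort sizes, planted differential features,
the intended tripartite network, PPI wiring, covariate prevalences and
marker odds ratios — so that every downstream stage can be checked
against known ground truth.  :func:`paper_scale_blueprint` builds the
canonical study: a 5-vs-5 circRNA array with 22 planted differential
circRNAs, two expression batches of 49+50 and 110+112 samples with 439
planted differential genes (46 tagged immune-related), a 53-node/56-edge
tripartite truth network, a 12-node/23-edge PPI graph with four designed
hub genes, and a 100-vs-100 cohort matched 1:1 on sex and age.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence

import numpy as np

Edge = tuple[str, str]


@dataclass(frozen=True)
class NetworkTruth:
    """Intended tripartite wiring with node directions."""

    circ_mir_edges: tuple[Edge, ...]
    mir_gene_edges: tuple[Edge, ...]
    circ_direction: Mapping[str, str]
    gene_direction: Mapping[str, str]

    def __post_init__(self) -> None:
        circ_mirs = {m for _, m in self.circ_mir_edges}
        gene_mirs = {m for m, _ in self.mir_gene_edges}
        orphans = circ_mirs ^ gene_mirs
        if orphans:
            raise ValueError(
                f"miRNAs must appear in both circ-miR and miR-gene edges: {sorted(orphans)}"
            )

    @property
    def circrnas(self) -> list[str]:
        return sorted({c for c, _ in self.circ_mir_edges})

    @property
    def mirnas(self) -> list[str]:
        return sorted({m for _, m in self.circ_mir_edges})

    @property
    def genes(self) -> list[str]:
        return sorted({g for _, g in self.mir_gene_edges})


@dataclass(frozen=True)
class PPITruth:
    """Intended protein-protein interaction wiring over network genes."""

    edges: tuple[Edge, ...]
    designed_hubs: tuple[str, ...]


@dataclass(frozen=True)
class StudyBlueprint:
    """All design constants of one synthetic study.

    ``planted_de_circ`` / ``planted_de_gene`` map feature id -> true log2
    fold change (case minus control); the sign is the direction.  Marker
    odds ratios are per standard deviation of log2 relative expression.
    """

    seed: int = 0
    n_features_circ: int = 1000
    n_features_gene: int = 4000
    n_samples_per_group_array: int = 5
    batch_sizes: tuple[tuple[int, int], ...] = ((49, 50), (110, 112))
    batch_additive: tuple[float, ...] = (0.0, 2.0)
    batch_scale: tuple[float, ...] = (1.0, 1.5)
    planted_de_circ: Mapping[str, float] = field(default_factory=dict)
    planted_de_gene: Mapping[str, float] = field(default_factory=dict)
    immune_gene_fraction: float = 0.125
    immune_de_genes: tuple[str, ...] = ()
    network_truth: NetworkTruth | None = None
    ppi_truth: PPITruth | None = None
    cohort_size_per_group: int = 100
    covariate_prevalences: Mapping[str, tuple[float, float]] = field(
        default_factory=dict
    )
    marker_effects: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.2
    n_decoy_circ_mir: int = 86
    n_decoy_mir_gene_lowconf: int = 1000
    n_decoy_mir_gene_overlap: int = 51
    inconsistent_mir_gene_edges: tuple[Edge, ...] = ()

    def __post_init__(self) -> None:
        counts = (
            self.n_features_circ,
            self.n_features_gene,
            self.n_samples_per_group_array,
            self.cohort_size_per_group,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.immune_gene_fraction <= 1.0:
            raise ValueError("immune_gene_fraction must be in [0, 1]")
        for name, (p0, p1) in self.covariate_prevalences.items():
            if not (0.0 <= p0 <= 1.0 and 0.0 <= p1 <= 1.0):
                raise ValueError(f"prevalences for {name!r} outside [0, 1]")
        circ_ids = set(self.circ_feature_ids())
        if not set(self.planted_de_circ) <= circ_ids:
            bad = sorted(set(self.planted_de_circ) - circ_ids)
            raise ValueError(f"planted circRNA ids out of range: {bad}")
        gene_ids = set(self.gene_feature_ids())
        if not set(self.planted_de_gene) <= gene_ids:
            bad = sorted(set(self.planted_de_gene) - gene_ids)
            raise ValueError(f"planted gene ids out of range: {bad}")

    def circ_feature_ids(self) -> list[str]:
        return [f"circ_{i:04d}" for i in range(1, self.n_features_circ + 1)]

    def gene_feature_ids(self) -> list[str]:
        return [f"gene_{i:04d}" for i in range(1, self.n_features_gene + 1)]

    def immune_gene_ids(self) -> list[str]:
        """The immune-related gene list: tagged planted genes plus a
        deterministic slice of non-differential genes up to the requested
        fraction of the gene panel."""
        immune = list(self.immune_de_genes)
        target = int(round(self.immune_gene_fraction * self.n_features_gene))
        pool = [
            g
            for g in self.gene_feature_ids()
            if g not in self.planted_de_gene
        ]
        immune += pool[: max(0, target - len(immune))]
        return sorted(immune)

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream so one stage's draws do not perturb another's."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        return np.random.default_rng(ss)

    def with_seed(self, seed: int) -> "StudyBlueprint":
        return replace(self, seed=seed)


_STREAMS = {
    "array": 1,
    "batched": 2,
    "interactions": 3,
    "ppi": 4,
    "cohort": 5,
}


def _paper_scale_network_truth() -> NetworkTruth:
    """Canonical truth wiring: 14 circRNAs, 24 miRNAs, 15 genes, 56 edges.

    Every miRNA sponges exactly one circRNA; six miRNAs bridge the four
    designed hub genes to five circRNAs so that the hub sub-network has
    the 5/6/4 composition.  One circRNA (and the two genes reachable from
    it) is down-regulated; everything else is up.
    """
    circ = {i: f"circ_{i:04d}" for i in range(1, 14)}
    circ[14] = "circ_0022"  # the single down-regulated circRNA
    mir = {i: f"mir_{i:02d}" for i in range(1, 25)}
    gene = {i: f"gene_{i:04d}" for i in range(1, 14)}
    gene[14], gene[15] = "gene_0230", "gene_0231"  # down-regulated partners

    cm = [(1, 1), (2, 2), (3, 3), (4, 4), (5, 5), (1, 6)]  # (circ, mir) hub side
    for k, m in enumerate(range(7, 25)):  # two miRNAs per remaining circRNA
        cm.append((6 + k // 2, m))
    circ_mir = tuple((circ[c], mir[m]) for c, m in cm)

    mg = [
        # hub genes 1-4 wired to miRNAs 1-6 only
        (1, 1), (2, 1), (3, 1), (4, 1),
        (1, 2), (5, 2), (6, 2),
        (2, 3), (5, 3),
        (3, 4), (6, 4),
        # one gene per remaining miRNA
        (7, 5), (8, 5), (9, 6), (10, 6), (11, 7), (12, 7),
        (13, 8), (14, 8), (15, 9), (16, 9), (17, 10), (18, 10),
        (19, 11), (20, 11), (21, 12), (22, 13), (23, 14), (24, 15),
        # extra edges to reach the 56-edge total
        (7, 6), (8, 7), (9, 8),
    ]
    mir_gene = tuple((mir[m], gene[g]) for m, g in mg)

    circ_direction = {circ[i]: "up" for i in range(1, 14)}
    circ_direction[circ[14]] = "down"
    gene_direction = {gene[i]: "up" for i in range(1, 14)}
    gene_direction[gene[14]] = gene_direction[gene[15]] = "down"
    return NetworkTruth(circ_mir, mir_gene, circ_direction, gene_direction)


def _paper_scale_ppi_truth() -> PPITruth:
    """PPI wiring: 12 connected genes, 23 edges, four designed hub genes.

    A clique over the four hubs plus hub-periphery spokes and a few
    periphery-periphery edges; the remaining three network genes stay
    unconnected and drop out of the centrality analysis.
    """
    h = [f"gene_{i:04d}" for i in range(1, 5)]
    p = [f"gene_{i:04d}" for i in range(5, 13)]
    edges = [
        (h[0], h[1]), (h[0], h[2]), (h[0], h[3]),
        (h[1], h[2]), (h[1], h[3]), (h[2], h[3]),
        (h[0], p[0]), (h[0], p[1]), (h[0], p[2]), (h[0], p[3]),
        (h[1], p[0]), (h[1], p[4]), (h[1], p[5]),
        (h[2], p[1]), (h[2], p[4]), (h[2], p[6]),
        (h[3], p[2]), (h[3], p[5]), (h[3], p[7]),
        (p[0], p[1]), (p[2], p[3]), (p[6], p[7]), (p[4], p[6]),
    ]
    return PPITruth(tuple(edges), tuple(h))


#: Table-2 covariate prevalences (control, case)
PAPER_COVARIATE_PREVALENCES: dict[str, tuple[float, float]] = {
    "smoking": (0.36, 0.50),
    "drinking": (0.18, 0.30),
    "hypertension": (0.55, 0.79),
    "diabetes": (0.16, 0.29),
}

#: Marker odds ratios per SD of log2 relative expression for the five
#: candidate circRNAs of the hub sub-network (two informative, three null).
PAPER_MARKER_EFFECTS: dict[str, float] = {
    "circ_0001": 1.514,
    "circ_0002": 1.0,
    "circ_0003": 1.633,
    "circ_0004": 1.0,
    "circ_0005": 1.0,
}


def paper_scale_blueprint(seed: int = 0) -> StudyBlueprint:
    """The canonical study blueprint at the published scale."""
    planted_circ = {f"circ_{i:04d}": 1.5 for i in range(1, 22)}
    planted_circ["circ_0022"] = -1.5
    planted_gene = {f"gene_{i:04d}": 1.0 for i in range(1, 230)}
    planted_gene.update({f"gene_{i:04d}": -1.0 for i in range(230, 440)})
    # 46 planted genes are tagged immune-related: the 15 network genes
    # plus a deterministic complement (29 up, 2 down elsewhere).
    immune_de = (
        [f"gene_{i:04d}" for i in range(1, 14)]
        + ["gene_0230", "gene_0231"]
        + [f"gene_{i:04d}" for i in range(14, 43)]  # extra up-regulated
        + ["gene_0232", "gene_0233"]  # extra down-regulated
    )
    truth = _paper_scale_network_truth()
    inconsistent = (
        ("mir_01", "gene_0230"),  # up-circRNA miRNA paired with a down gene
        ("mir_05", "gene_0231"),
        ("mir_23", "gene_0001"),  # down-circRNA miRNA paired with an up gene
        ("mir_24", "gene_0005"),
    )
    return StudyBlueprint(
        seed=seed,
        planted_de_circ=planted_circ,
        planted_de_gene=planted_gene,
        immune_de_genes=tuple(sorted(immune_de)),
        network_truth=truth,
        ppi_truth=_paper_scale_ppi_truth(),
        covariate_prevalences=dict(PAPER_COVARIATE_PREVALENCES),
        marker_effects=dict(PAPER_MARKER_EFFECTS),
        inconsistent_mir_gene_edges=inconsistent,
    )
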