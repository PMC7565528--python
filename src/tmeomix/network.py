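"""Focal-gene-centered gene–miRNA–protein ring networks.

The network places the focal gene at the center, the miRNAs targeting it on
ring 1, the proteins targeted by those miRNAs on ring 2 and the genes
targeted by them on the outer double ring (ring 3, reduced to genes whose
|ET − EC| group-mean difference stays below a filter, 0.3 log2 by default).
Every node carries the six cell×condition group means (EC, ET, IC, IT, KC,
KT) as its payload.  A companion summary contrasts tumor-vs-control
expression shifts of in-network molecules against the background of
molecules not targeted by the focal gene's miRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexp import DEResult
from .io_formats import ExpressionTable, UsageError
from .mirdiana import ConsensusMatrix, mirnas_targeting
from .preprocess import CELL_GROUPS, SampleDesign, group_means


@dataclass
class NetworkParams:
    focal_gene: str = "Brca1"
    min_consensus: int = 1
    #: outer-ring genes must satisfy |mean(ET) − mean(EC)| < ring_filter
    ring_filter: float = 0.3

    def __post_init__(self) -> None:
        if self.ring_filter < 0:
            raise UsageError("ring_filter must be non-negative")
        if self.min_consensus < 1:
            raise UsageError("min_consensus must be >= 1")


@dataclass
class RingNode:
    name: str
    ring: int  # 0 center gene, 1 miRNA, 2 protein, 3 outer gene double-ring
    kind: str  # gene | mirna | protein
    payload: dict[str, float]  # six group means; NaN allowed for proteins


@dataclass
class RingNetwork:
    """Layered network with canonical ordering (ring, then node name)."""

    focal_gene: str
    nodes: list[RingNode]
    edges: list[tuple[str, str]]  # (miRNA, target) pairs
    params: NetworkParams = field(default_factory=NetworkParams)

    def ring(self, index: int) -> list[RingNode]:
        return [n for n in self.nodes if n.ring == index]

    def node_names(self, index: int) -> list[str]:
        return [n.name for n in self.ring(index)]

    def to_dict(self) -> dict:
        return {
            "focal_gene": self.focal_gene,
            "params": {
                "focal_gene": self.params.focal_gene,
                "min_consensus": self.params.min_consensus,
                "ring_filter": self.params.ring_filter,
            },
            "nodes": [
                {
                    "name": n.name,
                    "ring": n.ring,
                    "kind": n.kind,
                    "payload": {
                        g: (None if v is None or (isinstance(v, float) and np.isnan(v)) else v)
                        for g, v in n.payload.items()
                    },
                }
                for n in self.nodes
            ],
            "edges": [list(e) for e in self.edges],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RingNetwork":
        params = NetworkParams(**d["params"])
        nodes = [
            RingNode(
                n["name"],
                n["ring"],
                n["kind"],
                {g: (np.nan if v is None else float(v)) for g, v in n["payload"].items()},
            )
            for n in d["nodes"]
        ]
        edges = [tuple(e) for e in d["edges"]]
        return cls(d["focal_gene"], nodes, edges, params)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph(focal_gene=self.focal_gene)
        for n in self.nodes:
            g.add_node(n.name, ring=n.ring, kind=n.kind, **{
                k: (float("nan") if v is None else v) for k, v in n.payload.items()
            })
        g.add_edges_from(self.edges)
        return g


def _payload(table: ExpressionTable, design: SampleDesign, molecule: str) -> dict[str, float]:
    gm = group_means(table, design, CELL_GROUPS)
    return {g: float(gm.loc[molecule, g]) for g in CELL_GROUPS}


def targeted_sets(
    consensus: ConsensusMatrix, focal_gene: str, min_consensus: int = 1
) -> tuple[list[str], set[str]]:
    """The miRNAs targeting the focal gene and the union of their targets."""
    ring1 = [m for m, _ in mirnas_targeting(consensus, focal_gene, min_consensus)]
    targets = {
        g
        for (m, g), memb in consensus.memberships.items()
        if m in set(ring1) and len(memb) >= 1
    }
    return ring1, targets


def build_ring_network(
    mrna: ExpressionTable,
    mirna: ExpressionTable,
    protein: ExpressionTable,
    design: SampleDesign,
    consensus: ConsensusMatrix,
    params: NetworkParams | None = None,
) -> RingNetwork:
    """Assemble the focal-gene ring network from the three layers.

    Ring-1 membership requires the miRNA to be measured (it must carry a
    six-group payload); ring-2 proteins and ring-3 genes are ring-1 targets
    present in their layer's table, the latter restricted to
    |mean(ET) − mean(EC)| < ring_filter and excluding the focal gene.
    """
    params = params or NetworkParams()
    focal = params.focal_gene
    if focal not in mrna.data.index:
        raise UsageError(f"focal gene {focal!r} absent from the mRNA table")

    ring1_all, target_union = targeted_sets(consensus, focal, params.min_consensus)
    ring1 = [m for m in ring1_all if m in mirna.data.index]

    gm_mrna = group_means(mrna, design, CELL_GROUPS)
    ring2 = sorted(t for t in target_union if t in protein.data.index)
    ring3 = []
    for t in sorted(target_union):
        if t == focal or t not in mrna.data.index:
            continue
        diff = abs(gm_mrna.loc[t, "ET"] - gm_mrna.loc[t, "EC"])
        if diff < params.ring_filter:
            ring3.append(t)

    gm_mirna = group_means(mirna, design, CELL_GROUPS)
    gm_protein = group_means(protein, design, CELL_GROUPS)

    nodes = [RingNode(focal, 0, "gene", {g: float(gm_mrna.loc[focal, g]) for g in CELL_GROUPS})]
    nodes += [
        RingNode(m, 1, "mirna", {g: float(gm_mirna.loc[m, g]) for g in CELL_GROUPS})
        for m in sorted(ring1)
    ]
    nodes += [
        RingNode(p, 2, "protein", {g: float(gm_protein.loc[p, g]) for g in CELL_GROUPS})
        for p in ring2
    ]
    nodes += [
        RingNode(t, 3, "gene", {g: float(gm_mrna.loc[t, g]) for g in CELL_GROUPS})
        for t in ring3
    ]

    node_names = {(n.ring, n.name) for n in nodes}
    ring1_set = set(ring1)
    member_names = {n.name for n in nodes}
    edges = sorted(
        {
            (m, g)
            for (m, g), memb in consensus.memberships.items()
            if m in ring1_set and (g in member_names or g == focal)
        }
    )
    assert len(node_names) == len(nodes), "duplicate nodes in the ring network"
    return RingNetwork(focal, nodes, edges, params)


def diff_distribution_summary(
    de_results: dict[str, DEResult],
    consensus: ConsensusMatrix,
    params: NetworkParams,
) -> pd.DataFrame:
    """Tumor-vs-control shift distributions, in-network vs background.

    ``de_results`` maps layer name (mrna/mirna/protein) to the DE result of
    one T-vs-C contrast.  For each layer the tested molecules are
    partitioned into *network* (targeted by — or being — a miRNA that
    targets the focal gene) and *background*, and summarized per direction
    (up/down by the sign of the shift, plus an ``all`` row): count, mean and
    quartiles of the tumor-minus-control mean differences.
    """
    ring1, target_union = targeted_sets(consensus, params.focal_gene, params.min_consensus)
    network_sets = {
        "mrna": set(target_union) | {params.focal_gene},
        "mirna": set(ring1),
        "protein": set(target_union),
    }
    rows = []
    for layer, de in de_results.items():
        tested = de.table[de.table["tested"]]
        in_net = tested.index.isin(network_sets.get(layer, set()))
        for membership, sub in (("network", tested[in_net]), ("background", tested[~in_net])):
            groups = {
                "all": sub,
                "up": sub[sub["mean_diff"] > 0],
                "down": sub[sub["mean_diff"] < 0],
            }
            for direction, block in groups.items():
                diffs = block["mean_diff"].to_numpy()
                rows.append(
                    {
                        "layer": layer,
                        "membership": membership,
                        "direction": direction,
                        "count": int(diffs.size),
                        "mean": float(diffs.mean()) if diffs.size else np.nan,
                        "q25": float(np.percentile(diffs, 25)) if diffs.size else np.nan,
                        "median": float(np.median(diffs)) if diffs.size else np.nan,
                        "q75": float(np.percentile(diffs, 75)) if diffs.size else np.nan,
                    }
                )
    return pd.DataFrame(rows)
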