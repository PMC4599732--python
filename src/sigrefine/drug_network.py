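"""The quantile-thresholded drug similarity network and its neighbourhood queries.

All n(n-1)/2 pairwise PRL distances are computed; an undirected edge joins
two drugs whenever their distance falls within a global quantile (5% by
default) of that distance multiset.  Querying a seed drug returns its
adjacent drugs sorted by distance, each with the global percentile of its
distance and its community label, plus per-prefix hypergeometric enrichment
of communities among the first n neighbours.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .gsea_engine import distance_matrix
from .null_model import bh_fdr
from .ranked_lists import DrugAnnotation, RankedList, ValidationError


def n_pairwise(n_drugs: int) -> int:
    """Number of unordered drug pairs considered when building the network."""
    return math.comb(n_drugs, 2)


@dataclass
class DrugNetwork:
    """Thresholded drug similarity graph plus the full distance background."""

    graph: nx.Graph
    distances: pd.DataFrame  # square symmetric, zero diagonal
    threshold: float
    quantile: float
    annotations: dict[str, DrugAnnotation] | None = None

    def __post_init__(self) -> None:
        vals = self.distances.values[np.triu_indices(len(self.distances), k=1)]
        self._sorted_pairwise = np.sort(vals)

    @property
    def drugs(self) -> list[str]:
        return list(self.distances.index)

    @property
    def all_pairwise(self) -> int:
        return int(self._sorted_pairwise.size)

    def distance_percentile(self, d: float) -> float:
        """Fraction of all pairwise distances <= d."""
        return float(
            np.searchsorted(self._sorted_pairwise, d, side="right") / self.all_pairwise
        )


@dataclass(frozen=True)
class Neighbourhood:
    """Seed-adjacent drugs sorted ascending by distance."""

    seed_id: str
    table: pd.DataFrame  # columns: drug, distance, percentile, community
    population: tuple[str, ...]  # networked drugs excluding the seed


def build_network(
    prls: Mapping[str, RankedList],
    k: int = 250,
    quantile: float = 0.05,
    annotations: Mapping[str, DrugAnnotation] | None = None,
    distances: pd.DataFrame | None = None,
) -> DrugNetwork:
    """Compute all pairwise distances and keep edges within the global quantile.

    The threshold is the linear-interpolation ("type 7") empirical quantile of
    the pairwise distance multiset; edges are pairs with distance <= threshold.
    A precomputed distance matrix can be supplied to skip the GSEA step.
    """
    if distances is None:
        if len(prls) < 3:
            raise ValidationError(f"need >= 3 drugs to build a network, got {len(prls)}")
        distances = distance_matrix(prls, k=k)
    elif len(distances) < 3:
        raise ValidationError("need >= 3 drugs to build a network")
    if not 0 < quantile < 1:
        raise ValidationError(f"quantile must be in (0, 1), got {quantile}")
    ids = list(distances.index)
    iu, ju = np.triu_indices(len(ids), k=1)
    vals = distances.values[iu, ju]
    threshold = float(np.quantile(vals, quantile))  # numpy default = type 7
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    if annotations is not None:
        for drug in ids:
            ann = annotations.get(drug)
            if ann is not None:
                graph.nodes[drug]["community"] = ann.community_id
                graph.nodes[drug]["moa"] = ";".join(sorted(ann.moa_labels))
    for a, b, d in zip(iu, ju, vals):
        if d <= threshold:
            graph.add_edge(ids[a], ids[b], distance=float(d))
    return DrugNetwork(
        graph=graph,
        distances=distances,
        threshold=threshold,
        quantile=quantile,
        annotations=dict(annotations) if annotations is not None else None,
    )


def query_neighbourhood(
    network: DrugNetwork,
    seed: str,
    mode: str = "edges",
    top_m: int | None = None,
) -> Neighbourhood:
    """Drugs around a seed, ascending by distance, with global distance percentiles.

    ``mode='edges'`` returns the thresholded-graph adjacency; ``mode='top-m'``
    returns the m closest drugs regardless of the threshold.
    """
    if seed not in network.distances.index:
        raise ValidationError(f"seed drug {seed!r} is not in the network")
    if mode == "edges":
        drugs = list(network.graph.neighbors(seed))
    elif mode == "top-m":
        if top_m is None or top_m < 1:
            raise ValidationError("mode='top-m' requires top_m >= 1")
        others = network.distances.loc[seed].drop(seed).sort_values(kind="stable")
        drugs = list(others.index[:top_m])
    else:
        raise ValidationError(f"mode must be 'edges' or 'top-m', got {mode!r}")
    dists = network.distances.loc[seed, drugs].astype(float)
    order = np.argsort(dists.values, kind="stable")
    rows = []
    ann = network.annotations or {}
    for i in order:
        drug = drugs[i]
        d = float(dists.values[i])
        rows.append(
            {
                "drug": drug,
                "distance": d,
                "percentile": network.distance_percentile(d),
                "community": ann[drug].community_id if drug in ann else None,
            }
        )
    table = pd.DataFrame(rows, columns=["drug", "distance", "percentile", "community"])
    population = tuple(d for d in network.distances.index if d != seed)
    return Neighbourhood(seed_id=seed, table=table, population=population)


def community_enrichment(
    nb: Neighbourhood,
    annotations: Mapping[str, DrugAnnotation],
) -> pd.DataFrame:
    """Per-prefix hypergeometric over-representation of communities.

    For each prefix length n of the neighbour list and each community c seen
    in that prefix, the upper-tail probability of drawing at least the
    observed number of c-members in n draws without replacement from the
    networked drugs (the seed itself is excluded from population and draws).
    P-values are BH-adjusted within each prefix.
    """
    missing = [r.drug for r in nb.table.itertuples() if r.drug not in annotations]
    if missing:
        raise ValidationError(f"unannotated neighbour(s): {missing}")
    population = [d for d in nb.population if d != nb.seed_id]
    unann = [d for d in population if d not in annotations]
    if unann:
        raise ValidationError(
            f"{len(unann)} networked drug(s) lack annotations, e.g. {unann[:3]}"
        )
    m_total = len(population)
    comm_sizes: dict[int, int] = {}
    for d in population:
        c = annotations[d].community_id
        comm_sizes[c] = comm_sizes.get(c, 0) + 1
    rows = []
    counts: dict[int, int] = {}
    for n_prefix, rec in enumerate(nb.table.itertuples(), start=1):
        c = annotations[rec.drug].community_id
        counts[c] = counts.get(c, 0) + 1
        prefix_rows = []
        for comm, k_c in sorted(counts.items()):
            p = float(hypergeom.sf(k_c - 1, m_total, comm_sizes[comm], n_prefix))
            prefix_rows.append(
                {
                    "prefix": n_prefix,
                    "community": comm,
                    "occurrence": k_c,
                    "community_size": comm_sizes[comm],
                    "pvalue": min(p, 1.0),
                }
            )
        qs = bh_fdr([r["pvalue"] for r in prefix_rows])
        for r, q in zip(prefix_rows, qs):
            r["fdr"] = float(q)
        rows.extend(prefix_rows)
    return pd.DataFrame(
        rows, columns=["prefix", "community", "occurrence", "community_size", "pvalue", "fdr"]
    )


def write_edge_list(network: DrugNetwork, path) -> None:
    with open(path, "w") as fh:
        for a, b, data in sorted(network.graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['distance']:.17g}\n")


def write_node_table(network: DrugNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("drug\tdegree\tcommunity\tmoa\n")
        for drug in sorted(network.graph.nodes):
            node = network.graph.nodes[drug]
            fh.write(
                f"{drug}\t{network.graph.degree[drug]}\t"
                f"{node.get('community', '')}\t{node.get('moa', '')}\n"
            )


def detect_communities(network: DrugNetwork, seed: int = 0) -> dict[str, int]:
    """Optional greedy-modularity communities on the thresholded graph.

    Provided as a convenience when no community table is available; the
    pipeline normally consumes communities as an input annotation.
    """
    comms = nx.algorithms.community.greedy_modularity_communities(
        network.graph, weight=None
    )
    out: dict[str, int] = {}
    for i, members in enumerate(comms, start=1):
        for drug in sorted(members):
            out[drug] = i
    return out
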