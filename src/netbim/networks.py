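"""Weighted bipartite HLA-peptide networks and their centrality features.

Every allele and every peptide in a dataset becomes a node; every measured
pair becomes an edge.  In the binding flavour the edge weight is the
transformed affinity in (0, 1] (exact zeros are replaced by a small epsilon,
since weights must stay positive); in the immunogenic flavour the weight is 1
for immunogenic pairs and epsilon for non-immunogenic ones.

Four classical centrality metrics are computed per node — degree (unweighted
adjacent-node count), closeness (inverse of the summed weighted shortest-path
distances to all reachable nodes), betweenness (frequency on weighted
shortest paths between node pairs) and eigenvector (principal eigenvector of
the weighted adjacency matrix, computed per connected component and
max-normalised within it).  Shuffle and random null networks permute or
resample edge weights while leaving the topology untouched, so that the
information content of correctly assigned weights can be measured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import Flavour, PairDataset, transform_affinity
from .encoding import encode_peptide

logger = logging.getLogger(__name__)

#: Substitute for zero edge weights (weights must be strictly positive).
EPSILON = 1e-10

HLA = "HLA"
PEPTIDE = "PEPTIDE"

METRICS = ("degree", "closeness", "betweenness", "eigenvector")


class WeightMode(str, Enum):
    """How edge weights enter shortest-path computations.

    ``cost``: the weight itself is the path length (igraph's default
    semantics for weighted closeness/betweenness).  ``inverse_strength``:
    length = 1/weight, so strongly bound pairs are topologically close.
    """

    COST = "cost"
    INVERSE_STRENGTH = "inverse_strength"


def build_network(ds: PairDataset) -> nx.Graph:
    """Construct the weighted bipartite graph for a validated dataset."""
    if len(ds) == 0:
        raise ValueError("cannot build a network from an empty dataset")
    g = nx.Graph(flavour=ds.flavour.value)
    for row in ds.df.itertuples(index=False):
        if ds.flavour is Flavour.BINDING:
            w = transform_affinity(float(row.ic50_nm))
            if w <= 0.0:
                w = EPSILON
        else:
            w = 1.0 if int(row.immunogenic) == 1 else EPSILON
        g.add_node(row.allele, node_class=HLA)
        g.add_node(row.peptide, node_class=PEPTIDE)
        g.add_edge(row.allele, row.peptide, weight=w)
    return g


@dataclass
class CentralityTable:
    """Per-node centrality metrics, raw and (after scaling) z-scored.

    ``df`` is indexed by node id with a ``node_class`` column, the four raw
    metric columns, and — once :func:`scale_metrics` has run — four
    ``*_scaled`` columns.  ``scaler`` maps (node_class, metric) to the fitted
    (mean, sd) so unseen data can be scaled consistently.
    """

    df: pd.DataFrame
    scaler: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    @property
    def is_scaled(self) -> bool:
        return bool(self.scaler)

    def nodes(self, node_class: str) -> pd.DataFrame:
        return self.df[self.df["node_class"] == node_class]

    def scaled_vector(self, node: str) -> np.ndarray:
        cols = [f"{m}_scaled" for m in METRICS]
        return self.df.loc[node, cols].to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="node")


def compute_centralities(
    g: nx.Graph, weight_mode: WeightMode | str = WeightMode.COST
) -> CentralityTable:
    """Compute degree, closeness, betweenness and eigenvector per node.

    Shortest-path metrics are delegated to igraph's C core for speed; the
    eigenvector is the principal eigenvector of the weighted adjacency,
    computed per connected component with scipy.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    import igraph as ig

    weight_mode = WeightMode(weight_mode)
    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges]
    weights = np.array([g.edges[e]["weight"] for e in g.edges], dtype=float)
    lengths = weights if weight_mode is WeightMode.COST else 1.0 / weights

    h = ig.Graph(n=len(nodes), edges=edges)
    h.es["length"] = list(lengths)

    degree = np.asarray(h.degree(), dtype=float)

    # closeness = 1 / (sum of weighted shortest-path distances, restricted to
    # each node's reachable set); betweenness = raw shortest-path pair counts
    closeness = np.nan_to_num(
        np.asarray(h.closeness(weights="length", normalized=False), dtype=float)
    )
    betweenness = np.asarray(h.betweenness(weights="length"), dtype=float)

    n_comp = len(h.connected_components())
    if n_comp > 1:
        logger.warning(
            "network is disconnected: closeness restricted to reachable sets, "
            "eigenvector computed per component"
        )
    eigenvector = _eigenvector_per_component(h, np.asarray(weights), len(nodes))

    df = pd.DataFrame(
        {
            "node_class": [g.nodes[n]["node_class"] for n in nodes],
            "degree": degree,
            "closeness": closeness,
            "betweenness": betweenness,
            "eigenvector": eigenvector,
        },
        index=nodes,
    )
    return CentralityTable(df=df)


def _eigenvector_per_component(h, weights: np.ndarray, n: int) -> np.ndarray:
    """Principal eigenvector of the weighted adjacency, per component.

    Each component's vector is taken non-negative (Perron-Frobenius) and
    normalised so its maximum entry within the component is 1.
    """
    import scipy.sparse as sp
    import scipy.sparse.linalg as spl

    rows = np.array([e.source for e in h.es], dtype=int)
    cols = np.array([e.target for e in h.es], dtype=int)
    a = sp.coo_matrix(
        (np.concatenate([weights, weights]),
         (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(n, n),
    ).tocsr()

    out = np.zeros(n)
    for comp in h.connected_components():
        idx = np.asarray(comp)
        sub = a[idx][:, idx]
        if len(idx) <= 64:
            vals, vecs = np.linalg.eigh(sub.toarray())
            v = vecs[:, np.argmax(vals)]
        else:
            _, vecs = spl.eigsh(sub.astype(float), k=1, which="LA",
                                v0=np.ones(len(idx)), maxiter=5000)
            v = vecs[:, 0]
        v = np.abs(v)
        if v.max() > 0:
            v = v / v.max()
        out[idx] = v
    return out


def scale_metrics(table: CentralityTable) -> CentralityTable:
    """Z-score each metric within each node class; fitted moments retained.

    HLA and peptide metrics live on incomparable scales, so standardisation
    is done separately per class.  Zero-variance columns scale to all zeros.
    """
    df = table.df.copy()
    scaler: dict[tuple[str, str], tuple[float, float]] = {}
    for cls in (HLA, PEPTIDE):
        mask = df["node_class"] == cls
        if not mask.any():
            continue
        for m in METRICS:
            vals = df.loc[mask, m].to_numpy(dtype=float)
            mean = float(vals.mean())
            sd = float(vals.std(ddof=0))
            scaler[(cls, m)] = (mean, sd)
            df.loc[mask, f"{m}_scaled"] = (vals - mean) / sd if sd > 0 else 0.0
    return CentralityTable(df=df, scaler=scaler)


def shuffle_network(g: nx.Graph, level: float, seed: int) -> nx.Graph:
    """Permute the weights of a random fraction ``level`` of the edges.

    round(level * |E|) edges are chosen uniformly at random and their weights
    permuted among themselves; the topology and the multiset of all edge
    weights are unchanged.  level=0 is the identity.
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError("shuffle level must be in [0, 1]")
    rng = np.random.default_rng(seed)
    h = g.copy()
    edges = sorted(h.edges)
    k = int(round(level * len(edges)))
    if k < 2:
        return h
    chosen_idx = rng.choice(len(edges), size=k, replace=False)
    chosen = [edges[i] for i in chosen_idx]
    weights = [h.edges[e]["weight"] for e in chosen]
    perm = rng.permutation(k)
    for e, j in zip(chosen, perm):
        h.edges[e]["weight"] = weights[j]
    return h


def randomize_network(g: nx.Graph, seed: int) -> nx.Graph:
    """Replace every edge weight with an independent Uniform(0, 1) draw."""
    if g.number_of_edges() == 0:
        raise ValueError("empty network")
    rng = np.random.default_rng(seed)
    h = g.copy()
    for e in sorted(h.edges):
        h.edges[e]["weight"] = float(rng.uniform(0.0, 1.0))
    return h


def nearest_training_peptide(peptide: str, training_encodings: dict[str, np.ndarray]) -> str:
    """Training peptide with the smallest Euclidean encoding distance.

    Ties break to the lexicographically smallest peptide, for determinism.
    """
    if not training_encodings:
        raise ValueError("no training peptides available for imputation")
    target = encode_peptide(peptide).flat()
    names = sorted(training_encodings)
    mats = np.stack([training_encodings[n].ravel() for n in names])
    d = np.linalg.norm(mats - target, axis=1)
    return names[int(np.argmin(d))]


def features_for_pair(
    allele: str,
    peptide: str,
    table: CentralityTable,
    training_encodings: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """The ordered 8-vector of scaled centralities for one (allele, peptide).

    Known nodes contribute their scaled table rows.  An unseen peptide is
    represented by the training peptide nearest in BLOSUM50-encoding space;
    an unseen allele by the per-metric median over all HLA nodes.
    """
    if not table.is_scaled:
        raise ValueError("centrality table must be scaled first")
    if len(table.df) == 0:
        raise ValueError("empty centrality table")
    cols = [f"{m}_scaled" for m in METRICS]

    hla_rows = table.nodes(HLA)
    if allele in hla_rows.index:
        hla_vec = hla_rows.loc[allele, cols].to_numpy(dtype=float)
    else:
        hla_vec = hla_rows[cols].median().to_numpy(dtype=float)

    pep_rows = table.nodes(PEPTIDE)
    if peptide in pep_rows.index:
        pep_vec = pep_rows.loc[peptide, cols].to_numpy(dtype=float)
    else:
        if training_encodings is None:
            training_encodings = {
                p: encode_peptide(p).matrix for p in pep_rows.index
            }
        proxy = nearest_training_peptide(peptide, training_encodings)
        pep_vec = pep_rows.loc[proxy, cols].to_numpy(dtype=float)

    return np.concatenate([hla_vec, pep_vec])


def features_for_pairs(
    pairs,
    table: CentralityTable,
    training_encodings: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Vectorised :func:`features_for_pair` over an iterable of (allele, peptide)."""
    if not table.is_scaled:
        raise ValueError("centrality table must be scaled first")
    pairs = list(pairs)
    cols = [f"{m}_scaled" for m in METRICS]
    hla_df = table.nodes(HLA)[cols]
    pep_df = table.nodes(PEPTIDE)[cols]

    alleles = [a for a, _ in pairs]
    peptides = [p for _, p in pairs]

    hla_mat = hla_df.reindex(alleles).to_numpy(dtype=float)
    unseen_h = np.isnan(hla_mat).any(axis=1)
    if unseen_h.any():
        hla_mat[unseen_h] = hla_df.median().to_numpy(dtype=float)

    pep_mat = pep_df.reindex(peptides).to_numpy(dtype=float)
    unseen_p = np.isnan(pep_mat).any(axis=1)
    if unseen_p.any():
        if training_encodings is None:
            training_encodings = {p: encode_peptide(p).matrix for p in pep_df.index}
        names = sorted(training_encodings)
        train_flat = np.stack([training_encodings[n].ravel() for n in names])
        unseen = sorted({peptides[i] for i in np.flatnonzero(unseen_p)})
        query = np.stack([encode_peptide(p).flat() for p in unseen])
        # nearest training peptide; argmin over the sorted name list breaks
        # distance ties toward the lexicographically smallest peptide
        d2 = (
            (query**2).sum(axis=1)[:, None]
            - 2.0 * query @ train_flat.T
            + (train_flat**2).sum(axis=1)[None, :]
        )
        proxy = {p: names[int(j)] for p, j in zip(unseen, np.argmin(d2, axis=1))}
        sub = pep_df.reindex([proxy[peptides[i]] for i in np.flatnonzero(unseen_p)])
        pep_mat[unseen_p] = sub.to_numpy(dtype=float)

    return np.concatenate([hla_mat, pep_mat], axis=1)


def write_edge_list(g: nx.Graph, path) -> None:
    """3-column TSV export: hla, peptide, weight."""
    rows = []
    for u, v, d in g.edges(data=True):
        if g.nodes[u]["node_class"] == HLA:
            rows.append((u, v, d["weight"]))
        else:
            rows.append((v, u, d["weight"]))
    pd.DataFrame(rows, columns=["hla", "peptide", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_node(row.hla, node_class=HLA)
        g.add_node(row.peptide, node_class=PEPTIDE)
        g.add_edge(row.hla, row.peptide, weight=float(row.weight))
    return g


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)
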