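"""Glue between datasets, network features, encodings and the deep model.

A :class:`FeatureContext` freezes everything derived from a *training*
dataset — the bipartite network (possibly a shuffle/random null variant),
its scaled centrality table and the encoded training peptides — so that any
pair, including pairs whose allele or peptide never appeared in training,
can be featurised consistently (nearest-peptide / median-HLA imputation).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .data_io import Flavour, PairDataset, transform_affinity
from .encoding import encode_batch, encode_peptide
from .model import ModelConfig, NetBimModel, build_model, train
from .networks import (
    CentralityTable,
    WeightMode,
    build_network,
    compute_centralities,
    features_for_pairs,
    randomize_network,
    scale_metrics,
    shuffle_network,
)


@dataclass
class FeatureContext:
    network: nx.Graph
    table: CentralityTable
    training_encodings: dict[str, np.ndarray]

    def featurize(self, pairs) -> tuple[np.ndarray, np.ndarray]:
        """(x_pep, x_net) arrays for an iterable of (allele, peptide)."""
        pairs = list(pairs)
        x_pep = encode_batch([p for _, p in pairs])
        x_net = features_for_pairs(pairs, self.table, self.training_encodings)
        return x_pep, x_net


def build_feature_context(
    train_ds: PairDataset,
    weight_mode: WeightMode | str = WeightMode.COST,
    network_variant: str = "original",
    shuffle_level: float = 1.0,
    seed: int = 0,
) -> FeatureContext:
    """Build the (possibly null-transformed) network and its scaled features.

    ``network_variant``: "original", "shuffle" (weights permuted at
    ``shuffle_level``) or "random" (weights redrawn Uniform(0,1)).
    """
    net = build_network(train_ds)
    if network_variant == "shuffle":
        net = shuffle_network(net, shuffle_level, seed)
    elif network_variant == "random":
        net = randomize_network(net, seed)
    elif network_variant != "original":
        raise ValueError(f"unknown network variant {network_variant!r}")
    table = scale_metrics(compute_centralities(net, weight_mode))
    encodings = {p: encode_peptide(p).matrix for p in train_ds.df["peptide"].unique()}
    return FeatureContext(network=net, table=table, training_encodings=encodings)


def targets_of(ds: PairDataset) -> np.ndarray:
    """Model targets: transformed affinity (binding) or binary label."""
    if ds.flavour is Flavour.BINDING:
        return transform_affinity(ds.df["ic50_nm"].to_numpy())
    return ds.df["immunogenic"].to_numpy(dtype=float)


def pairs_of(ds: PairDataset) -> list[tuple[str, str]]:
    return list(zip(ds.df["allele"], ds.df["peptide"]))


def train_on_dataset(
    train_ds: PairDataset,
    cfg: ModelConfig,
    context: FeatureContext | None = None,
    **context_kwargs,
) -> tuple[NetBimModel, FeatureContext]:
    """Featurise a training dataset and fit the model on it."""
    if context is None:
        context = build_feature_context(train_ds, **context_kwargs)
    x_pep, x_net = context.featurize(pairs_of(train_ds))
    y = targets_of(train_ds)
    model = build_model(cfg)
    model.preprocessing = {
        "n_train": int(len(y)),
        "scaler": {f"{cls}:{m}": list(v) for (cls, m), v in context.table.scaler.items()},
    }
    train(model, x_pep, x_net, y)
    return model, context


def predict_pairs(model: NetBimModel, context: FeatureContext, pairs) -> np.ndarray:
    x_pep, x_net = context.featurize(pairs)
    return model.predict(x_pep, x_net)
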