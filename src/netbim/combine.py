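"""Combining the binding and immunogenic models, ranking and evaluation.

The immunogenic model acts as a filter on the binding model: a pair
predicted non-immunogenic gets a combined score of 0, otherwise the
predicted transformed binding affinity passes through unchanged:

    combined = BA  if IC == 1
             = 0   if IC == 0

Also here: percentile ranks across a candidate set, confusion-matrix
summaries (accuracy, sensitivity, specificity, PPV), top-k neoantigen
recognition, and the fivefold cross-validation harness in which network
construction and feature scaling are redone from each fold's training
portion only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_io import Flavour, PairDataset, transform_affinity, BINDER_THRESHOLD_NM
from .model import ModelConfig
from .pipeline import pairs_of, predict_pairs, targets_of, train_on_dataset


def combined_score(ba, ic):
    """Binding affinity gated by the immunogenic category (vectorised)."""
    ba_arr = np.asarray(ba, dtype=float)
    ic_arr = np.asarray(ic)
    if not np.all(np.isin(ic_arr, (0, 1))):
        raise ValueError("immunogenic category must be 0 or 1")
    if np.any(ba_arr < 0) or np.any(ba_arr > 1):
        raise ValueError("BA must lie in [0, 1]")
    out = np.where(ic_arr == 1, ba_arr, 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class ConfusionSummary:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def confusion_metrics(predicted, truth) -> ConfusionSummary:
    """accuracy=(TP+TN)/(P+N), sensitivity=TP/(TP+FN), specificity=TN/(TN+FP),
    PPV=TP/(TP+FP); ratios with a zero denominator are reported as None."""
    pred = np.asarray(predicted).astype(int)
    true = np.asarray(truth).astype(int)
    if pred.shape != true.shape:
        raise ValueError("predicted and truth must have equal length")
    if len(pred) == 0:
        raise ValueError("empty inputs")
    tp = int(np.sum((pred == 1) & (true == 1)))
    tn = int(np.sum((pred == 0) & (true == 0)))
    fp = int(np.sum((pred == 1) & (true == 0)))
    fn = int(np.sum((pred == 0) & (true == 1)))

    def ratio(num, den):
        return num / den if den > 0 else None

    return ConfusionSummary(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        accuracy=ratio(tp + tn, tp + tn + fp + fn),
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
    )


def percentile_ranks(scores) -> np.ndarray:
    """Rank position (descending, mean ties) divided by N; in (0, 1]."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("empty score vector")
    return rankdata(-arr, method="average") / len(arr)


def topk_recognition(combined_scores, peptides, truth, ks=(10, 20, 30, 40, 50)) -> dict[int, float]:
    """Proportion of true positives among the top-k by combined score.

    Ties in score break by lexicographic peptide for determinism.
    """
    scores = np.asarray(combined_scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    n = len(scores)
    if max(ks) > n:
        raise ValueError(f"k={max(ks)} exceeds candidate set size {n}")
    order = sorted(range(n), key=lambda i: (-scores[i], peptides[i]))
    out = {}
    for k in ks:
        top = order[:k]
        out[int(k)] = float(truth[top].sum() / k)
    return out


@dataclass
class CombinedPrediction:
    df: pd.DataFrame  # allele, peptide, ba, ic_prob, ic, combined_score, ranks


def combine_predictions(
    pairs,
    ba_scores,
    ic_probs,
    ic_threshold: float = 0.5,
) -> CombinedPrediction:
    """Assemble per-pair combined predictions and percentile ranks."""
    ba = np.asarray(ba_scores, dtype=float)
    icp = np.asarray(ic_probs, dtype=float)
    ic = (icp >= ic_threshold).astype(int)
    df = pd.DataFrame(
        {
            "allele": [a for a, _ in pairs],
            "peptide": [p for _, p in pairs],
            "ba": ba,
            "ic_prob": icp,
            "ic": ic,
            "combined_score": combined_score(ba, ic),
            "percentile_rank_binding": percentile_ranks(ba),
            "percentile_rank_immunogenic": percentile_ranks(icp),
        }
    )
    return CombinedPrediction(df=df)


def predicted_positive(ba, ic, ba_threshold_nm: float = BINDER_THRESHOLD_NM):
    """Combined-model positive call: predicted binder AND predicted immunogenic."""
    cut = transform_affinity(ba_threshold_nm)
    return ((np.asarray(ba) >= cut) & (np.asarray(ic) == 1)).astype(int)


# ---------------------------------------------------------------------------
# cross-validation


def fivefold_cv(
    ds: PairDataset,
    cfg: ModelConfig,
    seed: int = 0,
    n_folds: int = 5,
    weight_mode: str = "cost",
    stratify_by_allele: bool = False,
    keep_networks: bool = False,
) -> dict:
    """Seeded fivefold cross-validation with fold-local feature pipelines.

    The dataset is randomly partitioned into ``n_folds`` non-overlapping
    subsets.  Within each fold the bipartite network, the centrality scaling
    and the peptide encodings are rebuilt from the training portion only;
    test alleles/peptides absent from the training network are treated as
    newly added and served by median-HLA / nearest-peptide imputation.
    Reports MAE per fold for binding, accuracy for immunogenic.
    """
    n = len(ds)
    if n < n_folds:
        raise ValueError("dataset too small for the requested folds")
    rng = np.random.default_rng(seed)
    if stratify_by_allele:
        fold_of = np.empty(n, dtype=int)
        for _, idx in ds.df.groupby("allele").indices.items():
            idx = np.asarray(idx)
            fold_of[idx] = rng.permuted(np.arange(len(idx)) % n_folds)
    else:
        fold_of = rng.permuted(np.arange(n) % n_folds)

    folds = []
    metric_name = "mae" if ds.flavour is Flavour.BINDING else "accuracy"
    for f in range(n_folds):
        test_idx = np.where(fold_of == f)[0]
        train_idx = np.where(fold_of != f)[0]
        train_ds = PairDataset(df=ds.df.iloc[train_idx].reset_index(drop=True), flavour=ds.flavour)
        test_df = ds.df.iloc[test_idx].reset_index(drop=True)
        test_ds = PairDataset(df=test_df, flavour=ds.flavour)

        fold_cfg = ModelConfig(**{**cfg.__dict__, "seed": cfg.seed + f})
        model, context = train_on_dataset(
            train_ds, fold_cfg, weight_mode=weight_mode, seed=seed + f
        )
        scores = predict_pairs(model, context, pairs_of(test_ds))
        y_true = targets_of(test_ds)
        if ds.flavour is Flavour.BINDING:
            metric = float(np.mean(np.abs(scores - y_true)))
        else:
            metric = float(np.mean((scores >= 0.5).astype(int) == y_true.astype(int)))
        fold_out = {
            "fold": f,
            "train_index": train_idx,
            "test_index": test_idx,
            metric_name: metric,
        }
        if keep_networks:
            fold_out["network"] = context.network
        folds.append(fold_out)

    values = [fo[metric_name] for fo in folds]
    return {
        "metric": metric_name,
        "per_fold": values,
        "mean": float(np.mean(values)),
        "folds": folds,
        "fold_of": fold_of,
    }
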