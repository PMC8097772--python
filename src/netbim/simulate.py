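"""Seeded synthetic HLA-peptide datasets with known ground truth.

The generator emulates the statistical shape of an IEDB-style export: many
alleles, each measured against at least six 9-mer peptides, some peptides
shared across alleles (so the bipartite network is non-trivially connected),
allele-specific anchor-position preferences (positions 2 and 9, the class I
anchor residues) driving affinity, plus latent per-allele and per-peptide
propensity effects.  The latent linear predictor for a pair (h, p) is

    eta = motif_strength * motif(h, p)
        + network_strength * (a_h + b_p)
        + N(0, noise_sd)

with a_h, b_p ~ N(0, 1).  Binding data sets BA = sigmoid(eta) and converts
back to IC50 in [1, 50000] nM; immunogenic data draws Bernoulli labels from
a re-centred sigmoid calibrated so the marginal positive rate (after
label-noise flips) matches ``positive_rate``.  The node effects a_h, b_p are
what the network centrality features can recover, the motif is what the
sequence branch can recover — so ablation experiments have known ground
truth.  Everything is a pure function of the config (same config, same
bytes).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data_io import Flavour, PairDataset, inverse_transform_affinity

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Relative importance of each of the 9 positions in the allele motif;
#: anchors at positions 2 and 9 dominate, as for HLA class I.
POSITION_WEIGHTS = np.array([0.3, 3.0, 0.3, 0.3, 0.3, 0.3, 0.3, 0.3, 3.0])


@dataclass(frozen=True)
class SimConfig:
    n_alleles: int = 30
    peptides_per_allele: int = 30
    motif_strength: float = 1.0
    network_strength: float = 1.0
    noise_sd: float = 0.3
    label_noise: float = 0.05
    positive_rate: float = 0.5
    mean_peptide_degree: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_alleles < 1 or self.peptides_per_allele < 6:
            raise ValueError("need >=1 allele and >=6 peptides per allele")
        if not 0.0 <= self.label_noise <= 0.5:
            raise ValueError("label_noise must be in [0, 0.5]")
        if self.motif_strength < 0 or self.network_strength < 0 or self.noise_sd < 0:
            raise ValueError("strengths and noise_sd must be non-negative")
        if not 0.0 < self.positive_rate < 1.0:
            raise ValueError("positive_rate must be in (0, 1)")
        if not 1.0 <= self.mean_peptide_degree <= self.n_alleles:
            raise ValueError("mean_peptide_degree must lie in [1, n_alleles]")


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _random_peptide(rng) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=9))


def _simulate_pairs(cfg: SimConfig):
    """Common scaffold: pairs, latent linear predictor, ground truth."""
    rng = np.random.default_rng(cfg.seed)
    alleles = [f"HLA-S*{i + 1:02d}:01" for i in range(cfg.n_alleles)]

    # peptide pool sized so each peptide is measured against
    # ~mean_peptide_degree alleles, as in IEDB exports where the same epitope
    # recurs across alleles
    n_pairs = cfg.n_alleles * cfg.peptides_per_allele
    pool_size = max(
        cfg.peptides_per_allele, int(round(n_pairs / cfg.mean_peptide_degree))
    )
    pool: list[str] = []
    seen: set[str] = set()
    while len(pool) < pool_size:
        p = _random_peptide(rng)
        if p not in seen:
            seen.add(p)
            pool.append(p)

    # allele-specific residue preferences at each position
    profiles = {
        h: rng.normal(0.0, 1.0, size=(9, len(AMINO_ACIDS))) for h in alleles
    }
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}

    pairs: list[tuple[str, str]] = []
    for h in alleles:
        chosen = rng.choice(pool, size=cfg.peptides_per_allele, replace=False)
        pairs.extend((h, str(p)) for p in chosen)

    peptides = sorted({p for _, p in pairs})
    a_h = {h: float(e) for h, e in zip(alleles, rng.normal(0, 1, len(alleles)))}
    b_p = {p: float(e) for p, e in zip(peptides, rng.normal(0, 1, len(peptides)))}

    w = POSITION_WEIGHTS / POSITION_WEIGHTS.sum()
    motif = np.array(
        [
            sum(w[k] * profiles[h][k, aa_index[p[k]]] for k in range(9))
            for h, p in pairs
        ]
    )
    # normalise the motif score to unit variance so motif_strength is comparable
    # with the unit-variance node effects
    if motif.std() > 0:
        motif = (motif - motif.mean()) / motif.std()

    node = np.array([a_h[h] + b_p[p] for h, p in pairs])
    noise = rng.normal(0.0, cfg.noise_sd, size=len(pairs))
    eta = cfg.motif_strength * motif + cfg.network_strength * node + noise

    truth = {
        "allele_effects": a_h,
        "peptide_effects": b_p,
        "motif_scores": motif.tolist(),
        "eta": eta.tolist(),
        "config": asdict(cfg),
    }
    return rng, pairs, eta, truth


def simulate_binding_dataset(cfg: SimConfig) -> tuple[PairDataset, dict]:
    """Quantitative IC50 dataset plus its generating ground truth."""
    _, pairs, eta, truth = _simulate_pairs(cfg)
    ba = _sigmoid(eta)
    ic50 = inverse_transform_affinity(ba)
    df = pd.DataFrame(
        {
            "allele": [h for h, _ in pairs],
            "peptide": [p for _, p in pairs],
            "ic50_nm": ic50,
        }
    )
    truth["latent_ba"] = ba.tolist()
    return PairDataset(df=df, flavour=Flavour.BINDING), truth


def simulate_immunogenic_dataset(cfg: SimConfig) -> tuple[PairDataset, dict]:
    """Binary immunogenic dataset plus ground truth.

    The intercept is solved numerically so that the expected positive rate,
    after random label flips at ``label_noise``, equals ``positive_rate``.
    """
    rng, pairs, eta, truth = _simulate_pairs(cfg)
    # target pre-flip rate r0 with r0(1-2q) + q = positive_rate
    q = cfg.label_noise
    r0 = (cfg.positive_rate - q) / (1.0 - 2.0 * q) if q < 0.5 else 0.5
    r0 = min(max(r0, 1e-6), 1.0 - 1e-6)

    def gap(c):
        return _sigmoid(eta + c).mean() - r0

    c = brentq(gap, -50.0, 50.0)
    prob = _sigmoid(eta + c)
    labels = (rng.random(len(prob)) < prob).astype(int)
    flips = rng.random(len(labels)) < q
    labels[flips] = 1 - labels[flips]
    df = pd.DataFrame(
        {
            "allele": [h for h, _ in pairs],
            "peptide": [p for _, p in pairs],
            "immunogenic": labels,
        }
    )
    truth["probabilities"] = prob.tolist()
    truth["intercept"] = float(c)
    return PairDataset(df=df, flavour=Flavour.IMMUNOGENIC), truth


def write_dataset_tsv(ds: PairDataset, path) -> None:
    """Emit the same TSV dialect ``load_pairs`` consumes."""
    ds.df.to_csv(path, sep="\t", index=False)
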