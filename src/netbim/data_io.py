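"""Parsing, validation, transformation and filtering of HLA-peptide pair tables.

Two dataset flavours are supported: *binding* records carry a quantitative
IC50 (nM) per (allele, peptide) pair, *immunogenic* records carry a binary
label from T-cell activation / MHC binding / ligand-elution assays.  The
binding affinity is mapped onto [0, 1] with the standard log-transform
``BA = 1 - log(IC50)/log(50000)`` so that the conventional 500 nM binder
threshold corresponds to BA = 0.426.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Saturating IC50 (nM) of the affinity transform; BA hits 0 here.
IC50_MAX_NM = 50000.0
#: Conventional HLA class I binder threshold (nM).
BINDER_THRESHOLD_NM = 500.0

CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

PEPTIDE_LENGTH = 9


class Flavour(str, Enum):
    """Which kind of measurement a dataset carries."""

    BINDING = "binding"
    IMMUNOGENIC = "immunogenic"


class AssayGroup(str, Enum):
    T_CELL = "t_cell"
    MHC_BINDING = "mhc_binding"
    MHC_LIGAND_ELUTION = "mhc_ligand_elution"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class PairRecord:
    """One (allele, peptide) observation."""

    allele: str
    peptide: str
    ic50_nm: float | None = None
    immunogenic: int | None = None
    assay_group: AssayGroup = AssayGroup.UNKNOWN


@dataclass
class PairDataset:
    """An ordered table of pair records of one flavour.

    The table is a pandas DataFrame with columns ``allele``, ``peptide`` and
    either ``ic50_nm`` (binding) or ``immunogenic`` (immunogenic flavour).
    """

    df: pd.DataFrame
    flavour: Flavour
    rejection_log: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def value_column(self) -> str:
        return "ic50_nm" if self.flavour is Flavour.BINDING else "immunogenic"

    @property
    def alleles(self) -> list[str]:
        return sorted(self.df["allele"].unique())

    @property
    def peptides(self) -> list[str]:
        return sorted(self.df["peptide"].unique())

    def records(self) -> list[PairRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            if self.flavour is Flavour.BINDING:
                out.append(PairRecord(row.allele, row.peptide, ic50_nm=row.ic50_nm))
            else:
                out.append(
                    PairRecord(row.allele, row.peptide, immunogenic=int(row.immunogenic))
                )
        return out

    def to_tsv(self, path) -> None:
        """Write the canonical TSV: allele, peptide, ba or ic."""
        out = self.df[["allele", "peptide"]].copy()
        if self.flavour is Flavour.BINDING:
            out["ba"] = transform_affinity(self.df["ic50_nm"].to_numpy())
        else:
            out["ic"] = self.df["immunogenic"].astype(int)
        out.to_csv(path, sep="\t", index=False)


def _validate_positive(ic50_nm):
    arr = np.asarray(ic50_nm, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("IC50 values must be finite and strictly positive (nM)")
    return arr


def transform_affinity(ic50_nm):
    """Map IC50 (nM) to a transformed binding affinity in [0, 1].

    ``BA = 1 - log(x)/log(50000)``, clamped to [0, 1]: affinities at or below
    1 nM saturate at 1, at or above 50000 nM at 0.  Accepts scalars or arrays.
    """
    arr = _validate_positive(ic50_nm)
    ba = 1.0 - np.log(arr) / math.log(IC50_MAX_NM)
    ba = np.clip(ba, 0.0, 1.0)
    return float(ba) if np.isscalar(ic50_nm) or arr.ndim == 0 else ba


def inverse_transform_affinity(ba):
    """Invert the affinity transform: BA in [0,1] -> IC50 in [1, 50000] nM."""
    arr = np.asarray(ba, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("transformed affinity must lie in [0, 1]")
    ic50 = np.power(IC50_MAX_NM, 1.0 - arr)
    return float(ic50) if np.isscalar(ba) or arr.ndim == 0 else ic50


def classify_binder(ic50_nm):
    """Binary binder call: 1 iff IC50 <= 500 nM."""
    arr = _validate_positive(ic50_nm)
    call = (arr <= BINDER_THRESHOLD_NM).astype(int)
    return int(call) if np.isscalar(ic50_nm) or arr.ndim == 0 else call


def sanitize_peptide(raw: str) -> str:
    """Uppercase and map every non-canonical residue (X, B, U, J, O, ...) to 'Z'.

    Raises ``ValueError`` if the result is not a 9-mer.
    """
    if not raw:
        raise ValueError("empty peptide")
    pep = "".join(c if c in CANONICAL_AA else "Z" for c in raw.strip().upper())
    if len(pep) != PEPTIDE_LENGTH:
        raise ValueError(f"not 9-mer: {raw!r}")
    return pep


DEFAULT_COLUMN_MAP = {
    "allele": "allele",
    "peptide": "peptide",
    "ic50_nm": "ic50_nm",
    "immunogenic": "immunogenic",
    "assay_group": "assay_group",
}


def load_pairs(
    path,
    flavour: Flavour | str,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> PairDataset:
    """Load a CSV/TSV of (allele, peptide, value) rows into a ``PairDataset``.

    ``column_map`` maps logical names (allele, peptide, ic50_nm / immunogenic)
    to the file's column headers so IEDB-style exports parse without code
    changes.  Rows rejected during validation are counted by reason in the
    returned dataset's ``rejection_log``.
    """
    flavour = Flavour(flavour)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=sep, engine="python")

    value_col = "ic50_nm" if flavour is Flavour.BINDING else "immunogenic"
    for logical in ("allele", "peptide", value_col):
        if cmap[logical] not in raw.columns:
            raise ValueError(
                f"missing required column {cmap[logical]!r} (logical {logical!r})"
            )

    rejections: dict[str, int] = {}

    def reject(reason: str, n: int = 1) -> None:
        rejections[reason] = rejections.get(reason, 0) + n

    rows = []
    for _, r in raw.iterrows():
        allele = str(r[cmap["allele"]]).strip()
        try:
            peptide = sanitize_peptide(str(r[cmap["peptide"]]))
        except ValueError:
            reject("not 9-mer")
            continue
        try:
            value = float(r[cmap[value_col]])
        except (TypeError, ValueError):
            reject("unparseable value")
            continue
        if flavour is Flavour.BINDING:
            if not math.isfinite(value) or value <= 0:
                reject("non-positive ic50")
                continue
        else:
            if value not in (0.0, 1.0):
                reject("non-binary label")
                continue
        rows.append((allele, peptide, value))

    df = pd.DataFrame(rows, columns=["allele", "peptide", value_col])
    df = _aggregate_duplicates(df, flavour)
    if rejections:
        logger.info("load_pairs rejected rows: %s", rejections)
    return PairDataset(df=df.reset_index(drop=True), flavour=flavour, rejection_log=rejections)


def _aggregate_duplicates(df: pd.DataFrame, flavour: Flavour) -> pd.DataFrame:
    """Collapse duplicated (allele, peptide) keys.

    IC50s are log-scale quantities, so replicates aggregate by geometric mean;
    binary labels by majority vote with ties resolved to positive (conservative
    for a filter model).
    """
    if df.duplicated(["allele", "peptide"]).sum() == 0:
        return df
    if flavour is Flavour.BINDING:
        agg = (
            df.groupby(["allele", "peptide"], sort=False)["ic50_nm"]
            .apply(lambda s: float(np.exp(np.mean(np.log(s)))))
            .reset_index()
        )
    else:
        agg = (
            df.groupby(["allele", "peptide"], sort=False)["immunogenic"]
            .apply(lambda s: int(s.mean() >= 0.5))
            .reset_index()
        )
    return agg


def filter_dataset(ds: PairDataset, min_entries_per_allele: int = 6) -> PairDataset:
    """Keep 9-mers, deduplicate, and drop alleles with too few records.

    "More than 5 entries per allele" is read as >= 6, configurable.  The
    operation is deterministic given input order and idempotent.
    """
    df = ds.df.copy()
    keep = df["peptide"].str.len() == PEPTIDE_LENGTH
    df = df[keep]
    df = _aggregate_duplicates(df, ds.flavour)
    counts = df["allele"].value_counts()
    good = counts[counts >= min_entries_per_allele].index
    df = df[df["allele"].isin(good)].reset_index(drop=True)
    if df.empty:
        logger.warning("filter_dataset produced an empty dataset")
    return PairDataset(df=df, flavour=ds.flavour, rejection_log=dict(ds.rejection_log))
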