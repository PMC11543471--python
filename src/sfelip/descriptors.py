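"""Molecular-descriptor computation and redundancy pruning.

The regression features for each lipid are 2D molecular descriptors computed
from its representative SMILES.  The full descriptor catalogue (~210 entries
in current RDKit releases) is first reduced by removing degenerate columns
(missing values, too few distinct values) and then by greedy Pearson
correlation pruning at |r| > 0.75, keeping the earlier column in catalogue
order.  Both reductions are deterministic given column order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .io_core import ValidationError, get_logger

__all__ = [
    "DEFAULT_CORRELATION_THRESHOLD",
    "Standardizer",
    "available_descriptors",
    "compute_descriptors",
    "drop_degenerate",
    "prune_correlated",
    "clean_descriptors",
    "standardize",
]

log = get_logger("descriptors")

#: Pairwise |Pearson r| above which the later of two descriptor columns is
#: considered redundant and dropped.
DEFAULT_CORRELATION_THRESHOLD = 0.75


def available_descriptors() -> list[str]:
    """Names of the full RDKit 2D descriptor catalogue, in catalogue order."""
    return [name for name, _ in Descriptors.descList]


def compute_descriptors(
    smiles_list: list[str], descriptor_names: list[str] | None = None
) -> pd.DataFrame:
    """Compute molecular descriptors for each SMILES.

    Returns a DataFrame with one row per molecule (in input order, indexed by
    position-stable keys ``m0, m1, ...`` unless ``smiles_list`` is a mapping)
    and one column per descriptor.  A descriptor that fails on a molecule is
    recorded as NaN, not raised; an unparseable SMILES is fatal.
    """
    if isinstance(smiles_list, dict):
        keys = list(smiles_list.keys())
        smiles = list(smiles_list.values())
    else:
        smiles = list(smiles_list)
        keys = [f"m{i}" for i in range(len(smiles))]
    names = list(descriptor_names) if descriptor_names is not None else available_descriptors()
    catalogue = dict(Descriptors.descList)
    unknown = [n for n in names if n not in catalogue]
    if unknown:
        raise ValidationError(f"unknown descriptors: {', '.join(unknown)}")

    rows = np.full((len(smiles), len(names)), np.nan)
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValidationError(f"invalid SMILES for molecule {keys[i]!r}: {smi!r}")
        for j, name in enumerate(names):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    v = catalogue[name](mol)
                rows[i, j] = v if np.isfinite(v) else np.nan
            except Exception:
                rows[i, j] = np.nan
    return pd.DataFrame(rows, index=keys, columns=names)


def drop_degenerate(
    matrix: pd.DataFrame,
    max_missing_fraction: float = 0.0,
    min_unique: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove descriptor columns with too many missing values or too few
    distinct values.

    Returns the reduced matrix and a report DataFrame with columns
    (column, reason) — reason is "missing" or "constant".
    """
    dropped: list[tuple[str, str]] = []
    keep: list[str] = []
    n = len(matrix)
    for col in matrix.columns:
        series = matrix[col]
        miss = series.isna().mean() if n else 0.0
        if miss > max_missing_fraction:
            dropped.append((col, "missing"))
            continue
        if series.dropna().nunique() < min_unique:
            dropped.append((col, "constant"))
            continue
        keep.append(col)
    report = pd.DataFrame(dropped, columns=["column", "reason"])
    if dropped:
        log.info("dropped %d degenerate descriptors", len(dropped))
    return matrix[keep], report


def prune_correlated(
    matrix: pd.DataFrame, threshold: float = DEFAULT_CORRELATION_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Greedy correlation pruning in column order.

    Scanning columns left to right, a column is dropped if its |Pearson r|
    with any already-retained column exceeds ``threshold``; the survivor set
    therefore has all pairwise |r| <= threshold, and of any correlated pair
    the earlier column in catalogue order is kept.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValidationError(f"correlation threshold must be in (0, 1], got {threshold}")
    if matrix.isna().any().any():
        raise ValidationError("prune_correlated requires a matrix without missing values")
    values = matrix.to_numpy(dtype=float)
    cols = list(matrix.columns)
    kept_idx: list[int] = []
    dropped: list[tuple[str, str, float]] = []
    # incremental standardised columns so each pairwise r is a dot product
    std = values - values.mean(axis=0)
    norms = np.linalg.norm(std, axis=0)
    if np.any(norms == 0):
        bad = cols[int(np.argwhere(norms == 0)[0][0])]
        raise ValidationError(f"constant column {bad!r} reached prune_correlated")
    std = std / norms
    for j in range(len(cols)):
        partner = None
        r_at_partner = 0.0
        for i in kept_idx:
            r = float(std[:, i] @ std[:, j])
            if abs(r) > threshold:
                partner, r_at_partner = cols[i], r
                break
        if partner is None:
            kept_idx.append(j)
        else:
            dropped.append((cols[j], partner, r_at_partner))
    report = pd.DataFrame(dropped, columns=["column", "partner", "r"])
    if dropped:
        log.info("pruned %d correlated descriptors at |r|>%g", len(dropped), threshold)
    return matrix.iloc[:, kept_idx], report


def clean_descriptors(
    matrix: pd.DataFrame,
    max_missing_fraction: float = 0.0,
    min_unique: int = 2,
    threshold: float = DEFAULT_CORRELATION_THRESHOLD,
    preset: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full cleaning pipeline: degenerate drop, then correlation pruning.

    ``preset`` bypasses data-driven pruning with an explicit column list (for
    users who want to reuse a previously published descriptor selection).
    Returns (cleaned matrix, combined drop report).
    """
    if preset is not None:
        missing = [c for c in preset if c not in matrix.columns]
        if missing:
            raise ValidationError(f"preset descriptors not computed: {', '.join(missing)}")
        return matrix[list(preset)], pd.DataFrame(columns=["column", "reason", "partner", "r"])
    m1, rep1 = drop_degenerate(matrix, max_missing_fraction, min_unique)
    m2, rep2 = prune_correlated(m1, threshold)
    parts = []
    if len(rep1):
        parts.append(rep1.assign(partner=pd.NA, r=pd.NA))
    if len(rep2):
        parts.append(rep2.assign(reason="correlated")[["column", "reason", "partner", "r"]])
    if not parts:
        return m2, pd.DataFrame(columns=["column", "reason", "partner", "r"])
    return m2, pd.concat(parts, ignore_index=True)


@dataclass
class Standardizer:
    """Invertible per-column affine transform (z-scoring)."""

    mean: pd.Series
    std: pd.Series

    def apply(self, matrix: pd.DataFrame) -> pd.DataFrame:
        return (matrix[self.mean.index] - self.mean) / self.std

    def invert(self, matrix: pd.DataFrame) -> pd.DataFrame:
        return matrix[self.mean.index] * self.std + self.mean


def standardize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, Standardizer]:
    """Z-score each column; returns the transformed matrix and the stored
    (invertible) transform.  Uses the population (ddof=0) standard deviation."""
    if len(matrix) < 2:
        raise ValidationError(f"cannot standardize n={len(matrix)}")
    mean = matrix.mean()
    std = matrix.std(ddof=0)
    if (std == 0).any():
        bad = std.index[std == 0][0]
        raise ValidationError(f"constant column {bad!r}: drop before standardizing")
    t = Standardizer(mean=mean, std=std)
    return t.apply(matrix), t
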