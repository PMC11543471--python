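"""Representative-structure selection for ambiguous lipid annotations.

LC-MS lipid annotation frequently resolves only to a shorthand (e.g.
"PC 16:0_18:1") that matches several positional/geometric isomers.  Downstream
featurisation needs one concrete structure per annotation, so each candidate
family is collapsed to a single representative by one of three methods:

* ``kmedoids_centroid`` — K-Medoids (PAM) clustering in standardized
  descriptor space; within the target cluster, the candidate nearest the
  cluster's mean descriptor vector (centroid) is chosen;
* ``tanimoto`` — highest mean pairwise Tanimoto similarity on circular
  (Morgan) fingerprints;
* ``idac`` — smallest squared deviation of the candidate's infinite-dilution
  activity-coefficient curve from the family's mean curve.

A concordance report compares the choices across methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit import DataStructs

from .io_core import ValidationError

__all__ = [
    "CandidateFamily",
    "SelectionResult",
    "pam_kmedoids",
    "select_by_clustering",
    "tanimoto_matrix",
    "rank_by_tanimoto",
    "rank_by_idac",
    "compare_selections",
]


@dataclass
class CandidateFamily:
    """One ambiguous shorthand annotation and its isomeric candidates.

    ``descriptors`` rows align with ``candidates`` order (standardized for
    distance computations); ``idac_curves`` rows (optional) hold ln(gamma_inf)
    evaluated on a grid shared across candidates.
    """

    shorthand: str
    candidates: list[tuple[str, str]]  # (candidate_id, smiles)
    descriptors: pd.DataFrame | None = None
    idac_curves: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValidationError(f"family {self.shorthand!r} has no candidates")
        if self.descriptors is not None and len(self.descriptors) != len(self.candidates):
            raise ValidationError(
                f"family {self.shorthand!r}: descriptor rows do not align with candidates"
            )

    @property
    def candidate_ids(self) -> list[str]:
        return [cid for cid, _ in self.candidates]


@dataclass
class SelectionResult:
    shorthand: str
    method: str
    chosen: str
    scores: np.ndarray
    tie: bool = False

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size and not np.all(np.isfinite(self.scores)):
            raise ValidationError(f"non-finite selection scores for {self.shorthand!r}")


# ---------------------------------------------------------------------------
# K-Medoids (PAM) — deterministic BUILD initialisation + SWAP refinement
# ---------------------------------------------------------------------------


def pam_kmedoids(dist: np.ndarray, k: int, max_iter: int = 100) -> tuple[list[int], np.ndarray]:
    """Partition-around-medoids on a precomputed distance matrix.

    BUILD greedily seeds medoids (first: minimal total distance; ties by
    index), then SWAP exchanges (medoid, non-medoid) pairs while total cost
    decreases.  Entirely deterministic, so k=1 selection needs no seed.

    Returns (medoid indices, cluster label per point).
    """
    n = dist.shape[0]
    if not (1 <= k <= n):
        raise ValidationError(f"k={k} out of range for {n} candidates")
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        # gain of adding each non-medoid j: sum of reductions in assignment cost
        gains = np.array(
            [
                np.maximum(current - dist[:, j], 0.0).sum() if j not in medoids else -np.inf
                for j in range(n)
            ]
        )
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)
    for _ in range(max_iter):
        cost = dist[:, medoids].min(axis=1).sum()
        best = (0.0, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                delta = dist[:, trial].min(axis=1).sum() - cost
                if delta < best[0] - 1e-12:
                    best = (delta, (mi, h))
        if best[1] is None:
            break
        mi, h = best[1]
        medoids[mi] = h
        medoids = sorted(medoids)
    labels = np.argmin(dist[:, medoids], axis=1)
    return medoids, labels


def select_by_clustering(
    family: CandidateFamily, k: int = 1, pure_medoid: bool = False
) -> SelectionResult:
    """K-Medoids based selection of the representative candidate.

    Candidates are clustered with PAM (k clusters) on Euclidean distances in
    standardized descriptor space.  In the target cluster — the largest, ties
    broken towards the earliest candidate — the mean descriptor vector is
    computed and the candidate closest to it is chosen (``pure_medoid=True``
    returns the cluster medoid instead).  Ties break by candidate order.
    """
    if family.descriptors is None:
        raise ValidationError(f"family {family.shorthand!r} lacks descriptors")
    X = family.descriptors.to_numpy(dtype=float)
    n = len(family.candidates)
    if n == 1:
        return SelectionResult(family.shorthand, "kmedoids_centroid",
                               family.candidate_ids[0], np.zeros(1))
    dist = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    medoids, labels = pam_kmedoids(dist, k)
    sizes = np.bincount(labels, minlength=len(medoids))
    order_of_first = [int(np.argmax(labels == c)) for c in range(len(medoids))]
    target = min(
        range(len(medoids)), key=lambda c: (-sizes[c], order_of_first[c])
    )
    members = np.flatnonzero(labels == target)
    centroid = X[members].mean(axis=0)
    d_centroid = np.linalg.norm(X - centroid, axis=1)
    if pure_medoid:
        chosen_idx = medoids[target]
    else:
        in_cluster = d_centroid.copy()
        in_cluster[labels != target] = np.inf
        chosen_idx = int(np.argmin(in_cluster))
    within = d_centroid[members]
    tie = bool(np.sum(np.isclose(within, within.min(), rtol=0, atol=1e-12)) > 1)
    return SelectionResult(
        family.shorthand, "kmedoids_centroid", family.candidate_ids[chosen_idx],
        d_centroid, tie=tie,
    )


# ---------------------------------------------------------------------------
# Tanimoto mean-similarity ranking
# ---------------------------------------------------------------------------


def tanimoto_matrix(
    smiles_list: list[str], fp_radius: int = 2, fp_bits: int = 2048
) -> np.ndarray:
    """Pairwise Tanimoto similarity on Morgan fingerprints."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=fp_radius, fpSize=fp_bits)
    fps = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValidationError(f"fingerprint failure: invalid SMILES {smi!r}")
        fps.append(gen.GetFingerprint(mol))
    n = len(fps)
    T = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            T[i, j] = T[j, i] = DataStructs.TanimotoSimilarity(fps[i], fps[j])
    return T


def rank_by_tanimoto(
    family: CandidateFamily, fp_radius: int = 2, fp_bits: int = 2048
) -> SelectionResult:
    """Choose the candidate with the highest mean Tanimoto similarity to the
    rest of its family (most structurally central); ties break by order."""
    ids = family.candidate_ids
    if len(ids) == 1:
        return SelectionResult(family.shorthand, "tanimoto", ids[0], np.array([]))
    T = tanimoto_matrix([smi for _, smi in family.candidates], fp_radius, fp_bits)
    n = len(ids)
    scores = (T.sum(axis=1) - 1.0) / (n - 1)
    best = float(scores.max())
    chosen_idx = int(np.argmax(scores))
    tie = bool(np.sum(np.isclose(scores, best, rtol=0, atol=1e-12)) > 1)
    return SelectionResult(family.shorthand, "tanimoto", ids[chosen_idx], scores, tie=tie)


# ---------------------------------------------------------------------------
# IDAC-curve squared-error ranking
# ---------------------------------------------------------------------------


def rank_by_idac(family: CandidateFamily, curves: np.ndarray | None = None) -> SelectionResult:
    """Choose the candidate whose ln(gamma_inf) curve has the smallest summed
    squared error against the family's pointwise mean curve."""
    ids = family.candidate_ids
    if curves is None:
        curves = family.idac_curves
    if len(ids) == 1:
        return SelectionResult(family.shorthand, "idac", ids[0], np.zeros(1))
    if curves is None:
        raise ValidationError(f"family {family.shorthand!r} lacks IDAC curves")
    curves = np.asarray(curves, dtype=float)
    if curves.ndim != 2 or curves.shape[0] != len(ids):
        raise ValidationError(
            f"family {family.shorthand!r}: IDAC curve grids not aligned across candidates"
        )
    mean_curve = curves.mean(axis=0)
    scores = ((curves - mean_curve) ** 2).sum(axis=1)
    best = float(scores.min())
    chosen_idx = int(np.argmin(scores))
    tie = bool(np.sum(np.isclose(scores, best, rtol=0, atol=1e-12)) > 1)
    return SelectionResult(family.shorthand, "idac", ids[chosen_idx], scores, tie=tie)


# ---------------------------------------------------------------------------
# Concordance across methods
# ---------------------------------------------------------------------------


def compare_selections(results_by_method: dict[str, list[SelectionResult]]) -> pd.DataFrame:
    """Tabulate per-family choices across >=2 selection methods.

    Returns a DataFrame indexed by shorthand with one column per method plus
    an ``agree`` flag; the overall concordance (fraction of families where all
    methods agree) is stored in ``df.attrs["concordance"]``.
    """
    if len(results_by_method) < 2:
        raise ValidationError("compare_selections needs at least two methods")
    per_method = {
        m: {r.shorthand: r.chosen for r in results} for m, results in results_by_method.items()
    }
    keysets = [set(d) for d in per_method.values()]
    if any(ks != keysets[0] for ks in keysets[1:]):
        raise ValidationError("mismatched family sets across methods")
    shorthands = sorted(keysets[0])
    df = pd.DataFrame(
        {m: [per_method[m][s] for s in shorthands] for m in per_method}, index=shorthands
    )
    df["agree"] = df.nunique(axis=1) == 1
    df.attrs["concordance"] = float(df["agree"].mean()) if len(df) else float("nan")
    return df
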