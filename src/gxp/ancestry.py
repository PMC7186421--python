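"""Ancestry principal components from the GRM and the rectangle-based
population partition.

PCs are the leading eigenvectors of the genomic relationship matrix, which
coincide (up to scaling) with the left singular vectors of the standardized
genotype matrix.  The partition assigns a reference group to POP1, draws the
bounding rectangle of the reference group's (PC1, PC2) cloud, and splits the
remaining individuals into POP3 (inside the rectangle, boundary inclusive)
and POP2 (outside).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .grm import GRMatrix

__all__ = ["PCSet", "PopulationPartition", "compute_pcs", "rectangle_partition"]


@dataclass
class PCSet:
    scores: np.ndarray        # n x k, columns PC1..PCk
    eigenvalues: np.ndarray   # k, decreasing
    standardized: bool

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def column(self, name: str) -> np.ndarray:
        """Score column by name, e.g. 'PC1'."""
        idx = int(name.replace("PC", "")) - 1
        return self.scores[:, idx]

    def to_frame(self, sample_ids: pd.DataFrame) -> pd.DataFrame:
        out = sample_ids[["fid", "iid"]].copy()
        for j in range(self.k):
            out[f"PC{j + 1}"] = self.scores[:, j]
        return out


@dataclass
class PopulationPartition:
    labels: np.ndarray                  # per-individual POP1/POP2/POP3
    rectangle: tuple                    # (min PC1, max PC1, min PC2, max PC2)


def compute_pcs(A, k: int = 2, standardize: bool = False,
                precomputed_eig=None) -> PCSet:
    """Top-k principal components of a GRM.

    Sign convention: the largest-magnitude loading of each PC is positive.
    With ``standardize`` each score column is rescaled to mean 0, variance 1
    (the form used as the reaction-norm covariate); unstandardized scores are
    the raw orthonormal eigenvectors.
    """
    vals = A.values if isinstance(A, GRMatrix) else np.asarray(A, dtype=float)
    n = vals.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the sample size")
    if not np.allclose(vals, vals.T, atol=1e-8):
        raise ValueError("GRM must be symmetric")

    if precomputed_eig is not None:
        w, U = precomputed_eig
    else:
        w, U = linalg.eigh(vals, subset_by_index=[n - k, n - 1])
    order = np.argsort(w)[::-1][:k]
    eigvals = np.asarray(w)[order]
    scores = np.asarray(U)[:, order].copy()

    for j in range(k):
        col = scores[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            scores[:, j] = -col

    if standardize:
        scores = (scores - scores.mean(axis=0)) / scores.std(axis=0)
    return PCSet(scores=scores, eigenvalues=eigvals, standardized=standardize)


def rectangle_partition(pcs: PCSet, reference_labels) -> PopulationPartition:
    """Partition individuals into POP1/POP2/POP3 by the reference rectangle.

    ``reference_labels`` marks each individual REF or OTHER.  REF individuals
    become POP1; their [min, max] ranges of PC1 and PC2 define the rectangle;
    OTHER individuals inside the rectangle (boundaries inclusive) become
    POP3, the rest POP2.
    """
    ref = np.asarray(reference_labels) == "REF"
    if not ref.any():
        raise ValueError("at least one REF individual is required")
    if ref.all():
        raise RuntimeError("no OTHER individuals to partition")
    pc1 = pcs.scores[:, 0]
    pc2 = pcs.scores[:, 1]
    rect = (pc1[ref].min(), pc1[ref].max(), pc2[ref].min(), pc2[ref].max())
    inside = ((pc1 >= rect[0]) & (pc1 <= rect[1])
              & (pc2 >= rect[2]) & (pc2 <= rect[3]))
    labels = np.where(ref, "POP1", np.where(inside, "POP3", "POP2"))
    return PopulationPartition(labels=labels, rectangle=rect)
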