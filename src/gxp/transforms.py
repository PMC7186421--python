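"""Fixed-effect (confounder) adjustment and the rank-based inverse-normal
transformation (INT).

Confounders are removed by ordinary least squares before the mixed-model
stage, so the REML fits carry only an intercept.  The INT maps average ranks
through the Blom formula value_i = Phi^-1((r_i - 3/8) / (n + 1/4)); it is
invariant to any strictly monotone transform of the input and is the
robustness check against phenotypic heteroscedasticity and non-normality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = ["AdjustedPhenotype", "adjust_fixed_effects", "rank_int",
           "encode_confounders"]


@dataclass
class AdjustedPhenotype:
    values: np.ndarray
    adjusted_for: list = field(default_factory=list)
    int_applied: bool = False


def encode_confounders(df: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode categorical columns (first level dropped); keep numerics."""
    parts = []
    for col in df.columns:
        s = df[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float))
        else:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True).astype(float)
            parts.append(dummies)
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=df.index)


def adjust_fixed_effects(y, X=None) -> AdjustedPhenotype:
    """OLS residuals of y on [1, X]; with no confounders, y is just centered."""
    y = np.asarray(y, dtype=float)
    names: list = []
    if X is None or (hasattr(X, "shape") and np.size(X) == 0):
        return AdjustedPhenotype(values=y - y.mean(), adjusted_for=names)

    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = encode_confounders(X)
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.atleast_2d(np.asarray(X, dtype=float))
        if Xv.shape[0] != y.shape[0]:
            Xv = Xv.T
        names = [f"x{j}" for j in range(Xv.shape[1])]

    design = np.column_stack([np.ones(y.shape[0]), Xv])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by incremental rank
        collinear = []
        cur = design[:, :1]
        for j in range(Xv.shape[1]):
            cand = np.column_stack([cur, Xv[:, j]])
            if np.linalg.matrix_rank(cand) == cur.shape[1]:
                collinear.append(names[j])
            else:
                cur = cand
        raise ValueError(f"confounder design is rank deficient; "
                         f"collinear columns: {collinear}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return AdjustedPhenotype(values=resid, adjusted_for=names)


def rank_int(y) -> AdjustedPhenotype:
    """Rank-based inverse-normal transformation with the Blom offset 3/8.

    Ties receive the average rank, so tied inputs map to equal outputs.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    if np.all(y == y[0]):
        raise RuntimeError("all phenotype values identical; INT undefined")
    r = rankdata(y, method="average")
    values = norm.ppf((r - 3.0 / 8.0) / (n + 0.25))
    return AdjustedPhenotype(values=values, int_applied=True)
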