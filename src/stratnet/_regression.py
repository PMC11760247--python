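"""Covariate residualization shared by the association machinery.

Covariate tables are small DataFrames (site, sex, age, optionally polygenic
scores).  Columns that are non-numeric, pandas-categorical, or named
``site`` are dummy-coded (first level dropped); everything else enters as-is.
An intercept is always included.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CATEGORICAL_NAMES = frozenset({"site"})


def design_matrix(covariates: pd.DataFrame | None, n: int) -> tuple[np.ndarray, int]:
    """Build an (n, 1 + k) design with intercept; returns (design, k)."""
    if covariates is None or (hasattr(covariates, "shape") and covariates.shape[1] == 0):
        return np.ones((n, 1)), 0
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    if len(cov) != n:
        raise ValueError(
            f"covariate table has {len(cov)} rows, expected {n}"
        )
    cols = [pd.Series(np.ones(n), name="const")]
    for name in cov.columns:
        col = cov[name]
        if (
            name in CATEGORICAL_NAMES
            or col.dtype == object
            or isinstance(col.dtype, pd.CategoricalDtype)
        ):
            dummies = pd.get_dummies(col, prefix=str(name), drop_first=True)
            cols.append(dummies.astype(float))
        else:
            cols.append(col.astype(float))
    design = pd.concat(cols, axis=1).to_numpy(dtype=float)
    return design, design.shape[1] - 1


def orthonormal_basis(design: np.ndarray) -> np.ndarray:
    """Orthonormal column basis of the design (rank-deficiency tolerated)."""
    q, r = np.linalg.qr(design)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return q[:, keep]


def residualize(arr: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Project out the span of ``basis`` (orthonormal columns)."""
    arr = np.asarray(arr, dtype=float)
    return arr - basis @ (basis.T @ arr)
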