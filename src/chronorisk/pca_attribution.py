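"""PCA attribution of extinction events to environmental variability.

Standardized (correlation-matrix) principal component analysis of the
environmental values extracted at extinction records, via singular value
decomposition.  Variables mix units (persons, millimetres, degrees), so
each column is centred and scaled to unit variance before decomposition.
The per-variable "contribution rate" to a component is 100 x squared
loading, which sums to 100 over variables for each component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CovariateStack

__all__ = ["PcaResult", "extract_env_at_records", "pca", "variance_summary"]


@dataclass
class PcaResult:
    variables: list[str]
    loadings: np.ndarray  # (p, n_components), orthonormal columns
    explained_ratio: np.ndarray  # (n_components,), sums to 1
    scores: np.ndarray  # (n, n_components)
    contributions: np.ndarray  # (p, n_components), percent, columns sum to 100

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.loadings.shape[1])]
        return pd.DataFrame(self.loadings, index=self.variables, columns=cols)

    def contributions_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.contributions.shape[1])]
        return pd.DataFrame(self.contributions, index=self.variables, columns=cols)


def extract_env_at_records(
    records: pd.DataFrame,
    stack: CovariateStack,
    variables: list[str],
    slice_index: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Layer values at each record's cell; nodata records are dropped.

    Returns (matrix records x variables, number dropped).  Unknown variable
    names raise ``KeyError``.
    """
    for v in variables:
        if v not in stack.layers:
            raise KeyError(f"unknown variable '{v}'; stack has {stack.names}")
    ix, iy = stack.grid.assign_xy(records["lon"].to_numpy(float), records["lat"].to_numpy(float))
    cells = stack.grid.cell_id(ix, iy)
    mat = stack.env_matrix(cells, variables, slice_index)
    ok = np.isfinite(mat.to_numpy()).all(axis=1) & stack.valid[iy, ix]
    dropped = int((~ok).sum())
    return mat.iloc[np.flatnonzero(ok)].reset_index(drop=True), dropped


def pca(matrix: pd.DataFrame | np.ndarray, standardize: bool = True) -> PcaResult:
    """SVD-based PCA with a deterministic sign convention.

    Components are ordered by decreasing variance; within each component the
    largest-magnitude loading is made positive.  With ``standardize`` the
    decomposition is of the correlation matrix; a zero-variance column is an
    error in that case.
    """
    if isinstance(matrix, pd.DataFrame):
        variables = list(matrix.columns)
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        variables = [f"v{i}" for i in range(x.shape[1])]
    n, p = x.shape
    if n < 2 or p < 2:
        raise ValueError("pca needs at least 2 rows and 2 columns")
    if not np.isfinite(x).all():
        raise ValueError("pca input contains non-finite values")
    xc = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if len(zero):
            raise ValueError(f"zero-variance column(s): {[variables[i] for i in zero]}")
        xc = xc / sd
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # sign convention: largest-|loading| positive per component
    for j in range(vt.shape[0]):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    var = s**2
    ratio = var / var.sum() if var.sum() > 0 else var
    loadings = vt.T
    scores = u * s
    contributions = 100.0 * loadings**2
    return PcaResult(variables, loadings, ratio, scores, contributions)


def variance_summary(result: PcaResult, n_components: int = 2) -> float:
    """Cumulative percent variance of the first ``n_components``, 2 decimals."""
    if n_components > len(result.explained_ratio):
        raise ValueError("n_components exceeds available components")
    return round(100.0 * float(result.explained_ratio[:n_components].sum()), 2)
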