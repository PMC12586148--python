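"""Population-level structure: response-distribution overlap and PCA.

``response_overlap`` quantifies how similar two populations' response
distributions are as the integral of the pointwise minimum of their Gaussian
kernel density estimates (1 = identical), reported alongside a two-sample
Kolmogorov-Smirnov test.  ``build_response_matrix`` assembles a registered
cells x (stimulus, paradigm/stage) matrix of mean evoked responses, and
``pca`` eigendecomposes its correlation matrix with a deterministic sign
convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import statcore

logger = logging.getLogger(__name__)

__all__ = ["PCAResult", "response_overlap", "build_response_matrix", "pca"]


def response_overlap(
    responses_a,
    responses_b,
    bandwidth: str | float = "silverman",
    grid_size: int = 2048,
) -> dict:
    """Overlap coefficient of two response distributions.

    Gaussian KDEs are evaluated on a shared grid spanning both samples plus
    a 4-bandwidth margin; overlap = integral of min(fA, fB), in [0, 1].
    A two-sample Kolmogorov-Smirnov p-value accompanies the coefficient.
    """
    a = np.asarray(responses_a, dtype=float)
    b = np.asarray(responses_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("need at least 5 values per sample")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant sample: kernel bandwidth would be 0")
    kde_a = sps.gaussian_kde(a, bw_method=bandwidth)
    kde_b = sps.gaussian_kde(b, bw_method=bandwidth)
    bw_a = float(np.sqrt(kde_a.covariance[0, 0]))
    bw_b = float(np.sqrt(kde_b.covariance[0, 0]))
    lo = min(a.min() - 4 * bw_a, b.min() - 4 * bw_b)
    hi = max(a.max() + 4 * bw_a, b.max() + 4 * bw_b)
    grid = np.linspace(lo, hi, grid_size)
    fa = kde_a(grid)
    fb = kde_b(grid)
    overlap = float(np.trapezoid(np.minimum(fa, fb), grid))
    ks = statcore.ks_two_sample(a, b)
    return {
        "overlap": min(overlap, 1.0),
        "ks_statistic": ks.statistic,
        "ks_p": ks.p_value,
        "n": (int(a.size), int(b.size)),
    }


def build_response_matrix(
    responses: pd.DataFrame,
    cell_col: str = "registration_id",
    condition_cols: tuple[str, ...] = ("stimulus", "stage"),
    value_col: str = "response",
) -> pd.DataFrame:
    """Registered-cell x condition matrix of mean evoked responses.

    ``responses`` is tidy: one row per (registered cell, stimulus,
    paradigm/stage) mean response (from peri-event window means).  Cells
    missing any condition are excluded with a logged count; columns are
    z-normalized across cells (sample s.d.).  Zero-variance columns are an
    error — they carry no population structure.
    """
    wide = responses.pivot_table(
        index=cell_col,
        columns=list(condition_cols),
        values=value_col,
        aggfunc="mean",
    )
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        logger.info("build_response_matrix: %d cells missing a condition dropped", dropped)
    if complete.empty:
        raise ValueError("no cell is registered in every condition")
    sd = complete.std(ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance response columns: {zero}")
    normalized = (complete - complete.mean()) / sd
    normalized.columns = [
        "|".join(map(str, c)) if isinstance(c, tuple) else str(c)
        for c in normalized.columns
    ]
    return normalized


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    scores: np.ndarray  # observations x components
    loadings: np.ndarray  # variables x components (orthonormal columns)
    columns: list[str]

    def biplot_coordinates(self) -> np.ndarray:
        """Variable arrows: loadings scaled by sqrt(eigenvalue)."""
        return self.loadings * np.sqrt(self.eigenvalues)


def pca(matrix) -> PCAResult:
    """PCA via eigendecomposition of the correlation matrix of the columns.

    Components ordered by decreasing eigenvalue; each loading vector's sign
    is fixed so its largest-magnitude entry is positive.  Scores are the
    standardized data projected onto the loadings.
    """
    if isinstance(matrix, pd.DataFrame):
        cols = [str(c) for c in matrix.columns]
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        cols = [f"v{i}" for i in range(X.shape[1])]
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [cols[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant columns cannot be standardized: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for j in range(eigvec.shape[1]):
        i_max = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i_max, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    fractions = eigval / eigval.sum()
    scores = Z @ eigvec
    return PCAResult(
        eigenvalues=eigval,
        variance_fractions=fractions,
        scores=scores,
        loadings=eigvec,
        columns=cols,
    )
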