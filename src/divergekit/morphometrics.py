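"""Trait transforms, the relative fin-redness statistic, lighting QC, and
correlation-matrix PCA of the phenotypic characteristics.

Areas are linearized (sqrt then ln) so every characteristic shares body
length's linear scale before allometric or multivariate analysis.  Fin
colour is summarised as dR/G: the fin's red-to-green channel ratio minus the
body's, removing diet-driven baseline redness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "delta_rg",
    "lighting_qc",
    "linearize_area",
    "PcaResult",
    "pca_correlation",
    "LIGHTING_SD_THRESHOLD",
]

#: Photographs with any colour-standard channel SD at or above this value
#: are rejected (the threshold is exclusive: accept requires SD < 2.5).
LIGHTING_SD_THRESHOLD = 2.5


def delta_rg(fin_R: float, fin_G: float, body_R: float, body_G: float) -> float:
    """Relative dorsal-fin redness: fin R/G minus body R/G."""
    if fin_G <= 0 or body_G <= 0:
        raise ValueError("green channel means must be positive")
    return fin_R / fin_G - body_R / body_G


def lighting_qc(channel_sds: Sequence[float]) -> bool:
    """Accept a photograph iff every colour-standard channel SD is < 2.5."""
    sds = list(channel_sds)
    if not sds:
        raise ValueError("channel_sds must be non-empty")
    return all(sd < LIGHTING_SD_THRESHOLD for sd in sds)


def linearize_area(area_mm2) -> float:
    """ln(sqrt(area)) = 0.5 * ln(area): puts an area on body length's
    log-linear scale."""
    area = np.asarray(area_mm2, dtype=float)
    if np.any(area <= 0):
        raise ValueError("area must be positive")
    result = 0.5 * np.log(area)
    return float(result) if result.ndim == 0 else result


@dataclass
class PcaResult:
    """Unrotated correlation-matrix PCA.

    ``loadings`` are eigenvector * sqrt(eigenvalue), so the squared loadings
    of a variable sum to 1 across components.  ``cumulative_pct`` is
    100 * cumsum(eigenvalues) / n_variables.
    """

    variables: list
    loadings: np.ndarray
    eigenvalues: np.ndarray
    cumulative_pct: np.ndarray


def cumulative_variance_pct(eigenvalues, n_variables=None) -> np.ndarray:
    """Cumulative percentage of variance for a correlation-matrix PCA.

    The denominator is the variable count (the eigenvalue sum of a
    correlation matrix), so printed eigenvalue subsets reproduce printed
    cumulative percentages.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if n_variables is None:
        n_variables = len(ev)
    return 100.0 * np.cumsum(ev) / float(n_variables)


def pca_correlation(trait_matrix, variables=None) -> PcaResult:
    """PCA of the correlation matrix of *trait_matrix* (rows = individuals).

    Components are unrotated; the sign of each component is fixed so its
    largest-|loading| entry is positive.
    """
    X = np.asarray(trait_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("trait_matrix must be 2-D with >= 2 rows")
    n, p = X.shape
    if variables is None:
        variables = [f"var{j}" for j in range(p)]
    sds = X.std(axis=0, ddof=1)
    for j, sd in enumerate(sds):
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(
                f"column {variables[j]!r} has zero variance; PCA of the "
                "correlation matrix is undefined"
            )
    corr = np.corrcoef(X, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    loadings = eigvec * np.sqrt(eigval)
    for k in range(p):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] = -loadings[:, k]
    return PcaResult(
        variables=list(variables),
        loadings=loadings,
        eigenvalues=eigval,
        cumulative_pct=cumulative_variance_pct(eigval, p),
    )
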