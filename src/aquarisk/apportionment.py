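"""Correlation analysis and principal-factor source apportionment.

Pollution sources are inferred from the structure of the parameter
correlation matrix: principal factors are the eigenvectors of the
correlation matrix, ordered by eigenvalue, with loadings scaled by the
square root of the eigenvalue.  Variance accounting follows the reporting
conventions of multivariate water-quality studies: explained-variance
percentages per factor, the percentage contribution of each variable to a
factor (loading² / eigenvalue), and the percentage contribution of each
observation (score² over the column's total squared score) — the quantities
used to tie factors to specific wells and boreholes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "FactorModel",
    "correlation_matrix",
    "extract_factors",
    "variable_contributions",
    "observation_contributions",
]


def _as_frame(data) -> pd.DataFrame:
    df = pd.DataFrame(data)
    if not np.all(np.isfinite(df.to_numpy(dtype=float))):
        raise DomainError("data contain non-finite values")
    return df.astype(float)


def correlation_matrix(data) -> pd.DataFrame:
    """Pearson correlation matrix of an observations × variables table."""
    df = _as_frame(data)
    if len(df) < 3:
        raise DomainError("correlation requires at least 3 observations")
    stds = df.std(ddof=1)
    constant = [str(c) for c in df.columns[stds == 0]]
    if constant:
        raise DomainError(f"constant column(s) {constant} have undefined correlations")
    corr = df.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass
class FactorModel:
    """Eigen-structure of the correlation matrix, all factors retained.

    ``loadings`` holds eigenvector × √eigenvalue per factor (columns F1..Fp);
    ``n_retained`` marks how many leading factors the retention rule kept.
    ``scores`` are the standardized data projected on the eigenvectors.
    """

    eigenvalues: np.ndarray
    loadings: pd.DataFrame
    scores: pd.DataFrame
    n_retained: int

    @property
    def variables(self) -> list[str]:
        return [str(v) for v in self.loadings.index]

    @property
    def explained_variance_pct(self) -> np.ndarray:
        return 100.0 * self.eigenvalues / self.eigenvalues.sum()

    @property
    def cumulative_variance_pct(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_pct)

    def retained_variance_pct(self) -> float:
        return float(self.cumulative_variance_pct[self.n_retained - 1])


def extract_factors(data, n_factors=None) -> FactorModel:
    """Principal-factor extraction from the correlation matrix.

    ``n_factors`` may be an integer count, a fractional cumulative-variance
    threshold in (0, 1), or ``None`` for the Kaiser rule (eigenvalue >= 1).
    All factors are computed; ``n_factors`` only sets the retention mark.
    The sign of each factor is fixed so its largest-|loading| entry is
    positive, making loadings reproducible across platforms.
    """
    df = _as_frame(data)
    corr = correlation_matrix(df)
    evals, evecs = np.linalg.eigh(corr.to_numpy())
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)

    for j in range(evecs.shape[1]):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]

    p = len(corr)
    names = [f"F{j + 1}" for j in range(p)]
    loadings = pd.DataFrame(
        evecs * np.sqrt(evals), index=corr.index, columns=names
    )
    z = (df - df.mean()) / df.std(ddof=1)
    scores = pd.DataFrame(z.to_numpy() @ evecs, index=df.index, columns=names)

    if n_factors is None:
        n_ret = max(1, int(np.count_nonzero(evals >= 1.0)))
    elif isinstance(n_factors, float) and 0 < n_factors < 1:
        cum = np.cumsum(evals) / evals.sum()
        n_ret = int(np.searchsorted(cum, n_factors) + 1)
    else:
        n_ret = int(n_factors)
        if not 1 <= n_ret <= p:
            raise DomainError(f"n_factors must lie in [1, {p}]")
    return FactorModel(eigenvalues=evals, loadings=loadings, scores=scores,
                       n_retained=n_ret)


def variable_contributions(model: FactorModel) -> pd.DataFrame:
    """Percent contribution of each variable to each factor.

    contribution(v, f) = 100 · loading(v, f)² / eigenvalue(f); columns sum
    to 100%.  Zero-eigenvalue factors get uniform shares.
    """
    lam = model.eigenvalues
    out = {}
    for j, col in enumerate(model.loadings.columns):
        if lam[j] > 0:
            out[col] = 100.0 * model.loadings[col] ** 2 / lam[j]
        else:
            out[col] = pd.Series(
                100.0 / len(model.loadings), index=model.loadings.index
            )
    return pd.DataFrame(out)


def observation_contributions(model: FactorModel) -> pd.DataFrame:
    """Percent contribution of each observation to each factor's score variance."""
    sq = model.scores**2
    total = sq.sum(axis=0)
    out = {}
    for col in model.scores.columns:
        if total[col] > 0:
            out[col] = 100.0 * sq[col] / total[col]
        else:
            out[col] = pd.Series(100.0 / len(sq), index=sq.index)
    return pd.DataFrame(out)
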