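"""Signed percentage contributions of stochastic inputs to a simulated risk.

Contribution of input j = 100 · sign(ρ_j) · ρ_j² / Σ_k ρ_k², with ρ_j the
Spearman rank correlation between the draws of input j and the risk output.
Squared-correlation shares with sign restoration reproduce tornado-style
reports where body weight appears as a negative driver; the raw-|ρ| share
normalization is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError

__all__ = ["ContributionReport", "contribution_analysis"]


@dataclass(frozen=True)
class ContributionReport:
    """Signed contributions (%) ordered by decreasing magnitude."""

    contributions: dict[str, float]
    correlations: dict[str, float]

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.contributions.items(), key=lambda kv: -abs(kv[1]))

    def __getitem__(self, variable: str) -> float:
        return self.contributions[variable]


def contribution_analysis(
    input_draws, output_draws, method: str = "squared"
) -> ContributionReport:
    """Rank-correlation contribution shares of each input to the output.

    ``input_draws`` is a mapping variable -> 1-D sample (or a DataFrame);
    all columns and the output must share a length n >= 10.  A constant
    input cannot carry rank information and is reported as 0% with a
    warning.  ``method`` selects the normalization: ``"squared"`` (shares of
    ρ²) or ``"absolute"`` (shares of |ρ|).
    """
    if hasattr(input_draws, "items"):
        columns = {str(k): np.asarray(v, dtype=float) for k, v in input_draws.items()}
    else:  # DataFrame-like
        columns = {str(c): np.asarray(input_draws[c], dtype=float)
                   for c in input_draws.columns}
    if method not in ("squared", "absolute"):
        raise DomainError(f"unknown normalization {method!r}")
    y = np.asarray(output_draws, dtype=float)
    n = y.size
    if n < 10:
        raise DomainError("contribution analysis needs at least 10 draws")
    for name, col in columns.items():
        if col.size != n:
            raise DomainError(f"input {name!r} has length {col.size}, expected {n}")
    if np.ptp(y) == 0:
        raise DomainError("output is constant; contributions are undefined")

    rho: dict[str, float] = {}
    for name, col in columns.items():
        if np.ptp(col) == 0:
            warnings.warn(
                f"input {name!r} is constant; its contribution is reported as 0%",
                stacklevel=2,
            )
            rho[name] = 0.0
            continue
        r = stats.spearmanr(col, y).statistic
        rho[name] = float(r) if np.isfinite(r) else 0.0

    weights = {
        name: (r**2 if method == "squared" else abs(r)) for name, r in rho.items()
    }
    total = sum(weights.values())
    if total == 0:
        contributions = {name: 0.0 for name in rho}
    else:
        contributions = {
            name: 100.0 * np.sign(rho[name]) * w / total
            for name, w in weights.items()
        }
    return ContributionReport(contributions=contributions, correlations=rho)
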