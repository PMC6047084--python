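"""The Poisson-to-Gaussian mean-variance crossover and map resolution.

Sequencing a contact library samples ligation events, so with perfectly
homogeneous pair probabilities the count N of a pair with mean mu is
Poisson: Var = mu.  Real pairs differ in re-ligation propensity; modelling
the count as N ~ Poisson(mu * lambda) with a unit-mean latent factor lambda
of coefficient of variation c gives the mixed-Poisson law

    Var(N) = mu + c^2 * mu^2.

The Poisson term dominates below the crossover mean mu* = 1 / c^2 and the
Gaussian-like heterogeneity term above it.  Choosing the bin size at which
the mean count per pair at a given distance s reaches mu* is an operational
definition of the map's resolution at s.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from ..contacts.matrix import ContactMatrix, bin_matrix
from .strata import DistanceStratum, stratify


@dataclass
class CrossoverFit:
    """Results of the quadratic mean-variance fit.

    Attributes
    ----------
    c : latent relative heterogeneity (dimensionless CV of lambda)
    c_se : approximate standard error of c
    mu_star : crossover mean count, 1/c^2 (inf when c is indistinguishable
        from zero)
    significant : whether c exceeds twice its standard error
    points : the (mu, var) grid the fit used
    residuals : var - (mu + c^2 mu^2) per point
    """

    c: float
    c_se: float
    points: pd.DataFrame
    residuals: np.ndarray

    @property
    def mu_star(self) -> float:
        return 1.0 / self.c**2 if self.c > 0 else float("inf")

    @property
    def significant(self) -> bool:
        return self.c > 2 * self.c_se

    def predicted_var(self, mu) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        return mu + self.c**2 * mu**2

    def summary(self) -> str:
        lines = [
            "Mean-variance crossover fit (Var = mu + c^2 mu^2)",
            "-" * 50,
            f"points used        : {len(self.points)}",
            f"c (latent CV)      : {self.c:.4g} +/- {self.c_se:.2g}",
            f"mu* = 1/c^2        : "
            + (f"{self.mu_star:.4g} reads/pair" if np.isfinite(self.mu_star) else "inf (Poisson-compatible)"),
            f"heterogeneity sig. : {'yes' if self.significant else 'no'}",
            f"rms residual       : {float(np.sqrt(np.mean(self.residuals ** 2))):.4g}",
        ]
        return "\n".join(lines)


def mean_variance_fit(strata: Sequence[DistanceStratum]) -> CrossoverFit:
    """Least-squares fit of Var = mu + c^2 mu^2 over distance strata.

    The fit is distribution-agnostic: only each stratum's mean and unbiased
    variance enter.  c^2 is the LS solution of (Var - mu) = c^2 mu^2,
    clipped at zero; its standard error propagates the sampling variance of
    each stratum variance (~ 2 sigma^4 / (n - 1), normal approximation).
    """
    mu = np.array([st.mu for st in strata], dtype=float)
    var = np.array([st.var for st in strata], dtype=float)
    n = np.array([st.n for st in strata], dtype=float)
    if len(mu) < 2:
        raise ValueError("need strata spanning several mean levels")
    r = var - mu
    denom = float(np.sum(mu**4))
    if denom == 0:
        raise ValueError("all strata have zero mean")
    c2 = float(np.sum(r * mu**2)) / denom
    var_of_var = 2.0 * var**2 / np.maximum(n - 1, 1)
    c2_var = float(np.sum(mu**4 * var_of_var)) / denom**2
    c2 = max(c2, 0.0)
    c = float(np.sqrt(c2))
    # delta method: se(c) = se(c^2) / (2 c); fall back to sqrt scale at c=0
    c2_se = float(np.sqrt(c2_var))
    c_se = c2_se / (2 * c) if c > 0 else float(np.sqrt(c2_se))
    points = pd.DataFrame({"mu": mu, "var": var, "n": n})
    residuals = var - (mu + c2 * mu**2)
    return CrossoverFit(c=c, c_se=c_se, points=points, residuals=residuals)


def resolution_estimate(
    events: pd.DataFrame,
    chrom: str,
    chrom_len: int,
    s: float,
    fit: CrossoverFit,
    bin_grid: Optional[Sequence[int]] = None,
) -> Optional[int]:
    """Smallest bin size whose mean contact count per bin pair at distance
    ``s`` reaches the crossover mean mu*.

    The mean count per pair grows monotonically with bin size (and with
    depth), so a linear scan over an ascending grid finds the transition
    point.  Returns None when mu* is unreachable at any bin size <= s
    ("unresolved at s").
    """
    if not np.isfinite(fit.mu_star):
        raise ValueError("crossover mean is infinite; resolution undefined")
    if bin_grid is None:
        b = 400
        bin_grid = []
        while b <= s:
            bin_grid.append(int(b))
            b *= 2
    for b in sorted(bin_grid):
        if b > s:
            break
        m = mean_count_at(events, chrom, chrom_len, s, int(b))
        if m is not None and m >= fit.mu_star:
            return int(b)
    return None


def mean_count_at(
    events: pd.DataFrame, chrom: str, chrom_len: int, s: float, bin_size: int
) -> Optional[float]:
    """Mean contact count per bin pair at distance ~s for one bin size."""
    mat = bin_matrix(events, bin_size=bin_size, chroms=[(chrom, chrom_len)])
    half = bin_size / 2.0
    try:
        strata = stratify(
            mat.counts, mat.positions, [s], half_width=half, s_max=s
        )
    except ValueError:
        return None
    return strata[0].mu
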