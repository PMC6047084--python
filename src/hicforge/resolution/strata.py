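"""Distance-stratified contact statistics.

A stratum collects the contact counts of every locus pair lying at genomic
distance ``s +/- half_width``.  Pairs near the matrix edge are trimmed so
that the number of pairs per stratum stays constant across the declared
``s`` range (otherwise long-distance strata would systematically lose
pairs, biasing their means downward).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

DEFAULT_HALF_WIDTH = 350


@dataclass
class DistanceStratum:
    s: float
    half_width: float
    counts: np.ndarray

    mu: float = field(init=False)
    sigma: float = field(init=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.size == 0:
            raise ValueError(f"empty stratum at s={self.s}")
        self.mu = float(self.counts.mean())
        # unbiased (n-1) estimator
        self.sigma = float(self.counts.std(ddof=1)) if self.counts.size > 1 else 0.0

    @property
    def n(self) -> int:
        return self.counts.size

    @property
    def var(self) -> float:
        return self.sigma**2

    @property
    def cv(self) -> float:
        return self.sigma / self.mu if self.mu > 0 else np.nan


def stratify(
    counts: np.ndarray,
    positions: Sequence[float],
    s_values: Sequence[float],
    half_width: float = DEFAULT_HALF_WIDTH,
    s_max: Optional[float] = None,
) -> List[DistanceStratum]:
    """Build distance strata from a symmetric count matrix.

    ``positions`` are the axis midpoints (fragment or bin centers, bp).
    Fragments whose midpoint lies within ``s_max + half_width`` of the right
    edge are excluded as left members of any pair, which keeps stratum
    cardinality constant across ``s`` on a regular map.
    """
    counts = np.asarray(counts, dtype=float)
    pos = np.asarray(positions, dtype=float)
    if counts.shape[0] != pos.size:
        raise ValueError("positions must match the matrix axis")
    s_values = np.asarray(s_values, dtype=float)
    if s_max is None:
        s_max = float(s_values.max())
    span = pos.max()
    left_ok = pos <= span - (s_max + half_width)
    if not left_ok.any():
        raise ValueError("edge trimming removed every fragment; lower s_max")

    strata = []
    li = np.flatnonzero(left_ok)
    for s in s_values:
        vals = []
        for i in li:
            d = pos - pos[i]
            sel = np.flatnonzero((d >= s - half_width) & (d <= s + half_width))
            vals.append(counts[i, sel])
        allv = np.concatenate(vals) if vals else np.empty(0)
        strata.append(DistanceStratum(float(s), float(half_width), allv))
    return strata


def stratum_table(strata: Sequence[DistanceStratum]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "s": [st.s for st in strata],
            "n": [st.n for st in strata],
            "mu": [st.mu for st in strata],
            "sigma": [st.sigma for st in strata],
            "cv": [st.cv for st in strata],
        }
    )


@dataclass
class CumulativeDistribution:
    values: np.ndarray  # sorted counts
    cdf: np.ndarray
    median: float
    q25: float
    q75: float
    blind_fraction: float  # fraction of pair bins with zero contacts

    @property
    def iqr(self) -> float:
        return self.q75 - self.q25


def cumulative_distribution(stratum: DistanceStratum) -> CumulativeDistribution:
    """Empirical CDF of a stratum's pair counts with quartiles and the
    fraction of blind (empty) pair bins."""
    v = np.sort(stratum.counts)
    cdf = np.arange(1, v.size + 1) / v.size
    return CumulativeDistribution(
        values=v,
        cdf=cdf,
        median=float(np.median(v)),
        q25=float(np.percentile(v, 25)),
        q75=float(np.percentile(v, 75)),
        blind_fraction=float((v == 0).mean()),
    )
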