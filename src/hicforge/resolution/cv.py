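"""Coefficient-of-variation curves and region comparison.

CV = sigma/mu of the contact counts at fixed distance s is used as an
inverse signal-to-noise measure: purely Poisson counts give CV = 1/sqrt(mu),
and any pair-to-pair heterogeneity (uneven fragment lengths, real structure)
inflates it.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .strata import DistanceStratum, stratify


def cv_curve(
    counts: np.ndarray,
    positions: Sequence[float],
    s_values: Sequence[float],
    half_width: float = 350,
    s_max: Optional[float] = None,
    bin_size: Optional[int] = None,
) -> pd.DataFrame:
    """CV as a function of s for one matrix; mu = 0 strata are masked."""
    strata = stratify(counts, positions, s_values, half_width, s_max)
    return pd.DataFrame(
        {
            "bin_size": bin_size,
            "s": [st.s for st in strata],
            "mu": [st.mu for st in strata],
            "cv": [st.cv for st in strata],
            "n": [st.n for st in strata],
        }
    )


@dataclass
class CvImprovement:
    log_ratios: np.ndarray  # pooled per-(control, s) log(CV_target / CV_control)
    target_mean: float  # mean over s of the target's log ratio
    null_means: np.ndarray  # control-vs-control means (null distribution)
    rank: float  # fraction of null means below the target mean

    @property
    def significant(self) -> bool:
        return self.rank <= 0.05 or self.rank >= 0.95


def cv_improvement(
    target_cv: Sequence[float], control_cvs: Sequence[Sequence[float]]
) -> CvImprovement:
    """Compare a region's CV(s) profile against same-size control regions.

    Pools ``log(CV_target / CV_control)`` over controls and distances;
    the summary is the mean over s, ranked within the distribution of
    control-vs-control means.  A single control yields a degenerate null
    (warning raised via the rank being uninformative).
    """
    t = np.asarray(target_cv, dtype=float)
    controls = [np.asarray(c, dtype=float) for c in control_cvs]
    if not controls:
        raise ValueError("need at least one control region")
    for c in controls:
        if c.shape != t.shape:
            raise ValueError("size mismatch between target and control regions")
    ratios = np.concatenate([np.log(t / c) for c in controls])
    target_mean = float(np.nanmean(ratios))
    null = []
    for i, a in enumerate(controls):
        for j, b in enumerate(controls):
            if i != j:
                null.append(float(np.nanmean(np.log(a / b))))
    null = np.asarray(null) if null else np.array([0.0])
    rank = float((null < target_mean).mean())
    return CvImprovement(ratios, target_mean, null, rank)


@dataclass
class CollapseResult:
    statistic: float  # max pairwise two-sample KS distance
    rescaled: List[np.ndarray]


def rescale_collapse(strata: Sequence[DistanceStratum]) -> CollapseResult:
    """Overlay count distributions rescaled by their means.

    In the Gaussian regime (sigma proportional to mu) the rescaled
    distributions collapse onto one shape, so the max pairwise
    Kolmogorov-Smirnov distance is small and mu-independent; in the Poisson
    regime the shape depends on mu and no collapse occurs.
    """
    if len(strata) < 2:
        raise ValueError("need at least two strata")
    rescaled = [st.counts / st.mu for st in strata if st.mu > 0]
    stat = 0.0
    for i in range(len(rescaled)):
        for j in range(i + 1, len(rescaled)):
            stat = max(stat, float(stats.ks_2samp(rescaled[i], rescaled[j]).statistic))
    return CollapseResult(stat, rescaled)
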