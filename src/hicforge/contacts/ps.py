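"""Distance-decay contact probability p(s) with logarithmic binning.

Intra-arm read pairs are binned by ``bin = floor(log_1.1(s))``; the count in
each bin is weighted by the bin size ``1.1**(1 + bin)`` and by the number of
admissible loci at that distance (arm length minus s), which makes p(s) flat
for uniformly drawn pairs.  The representative distance of a bin is its
geometric midpoint.
"""
from __future__ import annotations

import math
from typing import Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

LOG_BASE = 1.1


def log_bin(s, base: float = LOG_BASE):
    """``floor(log_base(s))``; s must be positive."""
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("genomic distance must be positive")
    return np.floor(np.log(s) / math.log(base)).astype(np.int64)


def bin_mid(bins, base: float = LOG_BASE) -> np.ndarray:
    """Geometric midpoint of each log bin."""
    return np.power(base, np.asarray(bins, dtype=float) + 0.5)


def ps_curve(
    events: pd.DataFrame,
    arms: Iterable[Tuple[str, int, int]],
    base: float = LOG_BASE,
    min_pairs: int = 1,
) -> pd.DataFrame:
    """Weighted contact probability versus genomic distance.

    ``arms`` lists ``(chrom, start, end)`` intervals; pairs are partitioned
    by arm (both ends inside), per-arm curves computed, then averaged over
    arms.  Input events should already be filtered in ``ps`` mode.

    Returns a DataFrame with columns ``bin``, ``s`` (geometric midpoint,
    bp), ``p`` (weighted frequency) and ``n`` (raw pair count).
    """
    per_arm: List[pd.DataFrame] = []
    for chrom, start, end in arms:
        L_arm = end - start
        sel = events[
            (events["chrom1"] == chrom)
            & (events["chrom2"] == chrom)
            & (events["pos1"] >= start)
            & (events["pos2"] < end)
        ]
        if len(sel) == 0:
            continue
        s = (sel["pos2"] - sel["pos1"]).abs().to_numpy(float)
        s = s[s > 0]
        bins = log_bin(s, base)
        uniq, counts = np.unique(bins, return_counts=True)
        s_rep = bin_mid(uniq, base)
        width = np.power(base, 1.0 + uniq.astype(float))
        valid = s_rep < L_arm
        p = np.full(uniq.shape, np.nan)
        p[valid] = counts[valid] / (width[valid] * (L_arm - s_rep[valid]))
        per_arm.append(
            pd.DataFrame({"bin": uniq, "s": s_rep, "p": p, "n": counts})
        )
    if not per_arm:
        return pd.DataFrame(columns=["bin", "s", "p", "n"])
    allarms = pd.concat(per_arm)
    out = (
        allarms.groupby("bin")
        .agg(s=("s", "first"), p=("p", "mean"), n=("n", "sum"))
        .reset_index()
    )
    return out[out["n"] >= min_pairs].reset_index(drop=True)


def fit_decay_exponent(
    ps: pd.DataFrame, s_min: float, s_max: float
) -> Tuple[float, float]:
    """Log-log slope (and standard error) of p(s) over [s_min, s_max]."""
    from scipy import stats

    sel = ps[(ps["s"] >= s_min) & (ps["s"] <= s_max) & (ps["p"] > 0)]
    if len(sel) < 3:
        raise ValueError("not enough bins to fit a slope")
    res = stats.linregress(np.log(sel["s"]), np.log(sel["p"]))
    return float(res.slope), float(res.stderr)
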