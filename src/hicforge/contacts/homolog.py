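"""Homolog-resolved statistics: trans-contact fraction and the
inter-homolog contact profile.

Both operate on events carrying ``homolog1``/``homolog2`` labels, with the
two homologs diverged by substitutions only so they share one coordinate
frame.
"""
from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd

Region = Tuple[str, int, int]  # (homolog label, start, end)


def _in_region(hom: pd.Series, pos: pd.Series, region: Region) -> pd.Series:
    label, start, end = region
    return (hom == label) & (pos >= start) & (pos < end)


def trans_fraction(
    events: pd.DataFrame, region_a: Region, region_b: Region
) -> float:
    """Percentage of pairs bridging the two homolog regions among all pairs
    aligning within them."""
    a1 = _in_region(events["homolog1"], events["pos1"], region_a)
    a2 = _in_region(events["homolog2"], events["pos2"], region_a)
    b1 = _in_region(events["homolog1"], events["pos1"], region_b)
    b2 = _in_region(events["homolog2"], events["pos2"], region_b)
    inside = (a1 | b1) & (a2 | b2)
    bridging = (a1 & b2) | (b1 & a2)
    denom = int(inside.sum())
    if denom == 0:
        raise ValueError("no pairs align within the two regions")
    return 100.0 * float(bridging.sum()) / denom


def inter_homolog_profile(
    events: pd.DataFrame,
    homologs: Tuple[str, str],
    L: int,
    bin_size: int = 2500,
    max_offset: Optional[int] = None,
) -> pd.DataFrame:
    """Mean contact count between homolog loci versus their coordinate offset.

    Trans pairs (one end per homolog) are stratified by
    ``|pos1 - pos2|`` and each offset bin's count is divided by the number
    of admissible locus pairs at that offset (``(L - offset) / bin_size``),
    so a uniform trans background yields a flat profile.
    """
    h1, h2 = homologs
    if max_offset is None:
        max_offset = L
    trans = events[
        ((events["homolog1"] == h1) & (events["homolog2"] == h2))
        | ((events["homolog1"] == h2) & (events["homolog2"] == h1))
    ]
    edges = np.arange(0, max_offset + bin_size, bin_size)
    centers = (edges[:-1] + edges[1:]) / 2.0
    if len(trans) == 0:
        return pd.DataFrame({"offset": centers, "mean_contacts": np.zeros(len(centers)),
                             "n": np.zeros(len(centers), dtype=int)})
    off = (trans["pos1"] - trans["pos2"]).abs().to_numpy(float)
    counts, _ = np.histogram(off, bins=edges)
    n_pairs = np.maximum((L - centers) / bin_size, 1e-12)
    return pd.DataFrame(
        {"offset": centers, "mean_contacts": counts / n_pairs, "n": counts}
    )
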