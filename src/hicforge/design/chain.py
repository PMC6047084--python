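"""Greedy chaining of candidate sites at a target spacing, and MAD scoring.

The chain starts at the leftmost candidate inside ``[0, spacing]``; each next
member must lie within ``spacing * (1 +/- tolerance_frac)`` of the previous
one, the qualifying candidate closest to the ideal distance winning (ties go
to the smaller position).  When nothing qualifies, a gap is recorded and the
chain restarts at the nearest candidate beyond the admissible band.
"""
from __future__ import annotations

import math
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .records import GapRecord

INF = float("inf")


def chain_sites(
    candidates: Sequence[int],
    spacing: int,
    tolerance_frac: float = 0.10,
    window_end: Optional[int] = None,
) -> Tuple[List[int], List[GapRecord]]:
    """Greedy spacing chain over sorted candidate positions.

    ``window_end`` bounds the region the chain should cover; a terminal gap
    is recorded when the chain dies more than one admissible band short of
    it.  Defaults to just past the last candidate (no terminal gap for a
    chain that consumed its candidates).
    """
    cands = sorted(int(c) for c in candidates)
    lo_f, hi_f = 1 - tolerance_frac, 1 + tolerance_frac
    if window_end is None:
        window_end = (cands[-1] + 1) if cands else spacing
    if not cands:
        return [], [GapRecord(None, None, float(window_end), max(1, window_end // spacing))]

    gaps: List[GapRecord] = []
    arr = np.asarray(cands)

    # first member: leftmost candidate in [0, spacing]; otherwise a leading
    # gap down to the first candidate at all
    first_in = [c for c in cands if 0 <= c <= spacing]
    if first_in:
        current = first_in[0]
    else:
        current = cands[0]
        gaps.append(GapRecord(None, current, float(current), max(1, round(current / spacing))))
    chain = [current]

    while True:
        ideal = chain[-1] + spacing
        lo, hi = chain[-1] + spacing * lo_f, chain[-1] + spacing * hi_f
        i0, i1 = np.searchsorted(arr, [math.ceil(lo), math.floor(hi)], side="left")
        if i1 < len(arr) and arr[i1] <= hi:
            i1 += 1
        band = arr[i0:i1]
        band = band[band > chain[-1]]
        if band.size:
            nxt = int(min(band, key=lambda c: (abs(c - ideal), c)))
            chain.append(nxt)
            continue
        # restart at the nearest candidate beyond the admissible band
        beyond = arr[arr > hi]
        if beyond.size:
            nxt = int(beyond[0])
            length = nxt - chain[-1]
            gaps.append(
                GapRecord(chain[-1], nxt, float(length), max(1, round(length / spacing) - 1))
            )
            chain.append(nxt)
            continue
        # terminal gap, if the window extends beyond reach
        remaining = window_end - chain[-1]
        if remaining > spacing * hi_f:
            gaps.append(
                GapRecord(chain[-1], None, float(remaining), max(1, int(remaining // spacing)))
            )
        return chain, gaps


def interval_score(
    chain: Sequence[int], spacing: int, gaps: Sequence[GapRecord] = ()
) -> float:
    """Median absolute deviation of consecutive gaps, plus ``spacing`` per
    failed placement.  Fewer than two positions scores +inf."""
    if len(chain) < 2:
        return INF
    d = np.diff(np.asarray(sorted(chain), dtype=float))
    mad = float(np.median(np.abs(d - np.median(d))))
    penalty = spacing * sum(g.n_missed for g in gaps)
    return mad + penalty
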