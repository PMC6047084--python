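"""Comparative map views: log-ratio maps and anchor pile-ups."""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .matrix import ContactMatrix


def log_ratio_map(a: ContactMatrix, b: ContactMatrix) -> np.ndarray:
    """Element-wise log2(A/B); entries where either map is zero are masked
    (NaN, no pseudocount).  Maps must share binning; totals should be
    matched by subsampling upstream."""
    if a.bin_size != b.bin_size or a.counts.shape != b.counts.shape:
        raise ValueError("binning mismatch between maps")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(a.counts / b.counts)
    out[(a.counts == 0) | (b.counts == 0)] = np.nan
    return out


@dataclass
class AnchorSet:
    """Anchor bins (global indices into a matrix) with provenance."""

    bins: Sequence[int]
    provenance: str = ""


@dataclass
class PileupResult:
    ratio: np.ndarray  # log2(anchor mean / control mean), window x window bins
    anchor_mean: np.ndarray
    control_mean: np.ndarray
    n_anchors: int
    n_control: int
    skipped: List[int]


def _aggregate(M: np.ndarray, centers: Sequence[int], half: int, size: int):
    stack = np.zeros((size, size))
    k = 0
    for a in centers:
        lo = a - half
        sub = M[lo : lo + size, lo : lo + size]
        stack += sub
        k += 1
    return stack / max(k, 1), k


def pileup_ratio(
    matrix: ContactMatrix,
    anchors: Union[AnchorSet, Sequence[int]],
    window: int = 145_000,
    control: str = "non_anchor_random",
    n_control: Optional[int] = None,
    seed: Optional[Union[int, np.random.Generator]] = None,
) -> PileupResult:
    """Aggregate sub-maps centered on anchor bins, ratioed to a control draw.

    The sub-map spans ``window / bin_size`` bins centered on each anchor;
    anchors too close to the matrix edge are skipped.  The control is a
    seed-reproducible draw of the same number of bins (``non_anchor_random``
    excludes the anchor set; ``random`` draws from all bins).  Returns
    ``log2(anchor mean / control mean)`` with zero-denominator entries
    masked.
    """
    if matrix.bin_size is None:
        raise ValueError("pile-ups need a fixed-bin matrix")
    bins = list(anchors.bins) if isinstance(anchors, AnchorSet) else list(anchors)
    size = int(round(window / matrix.bin_size))
    half = size // 2
    n = matrix.n
    usable, skipped = [], []
    for a in bins:
        if a - half >= 0 and a - half + size <= n:
            usable.append(int(a))
        else:
            skipped.append(int(a))
    if not usable:
        raise ValueError("no usable anchors (all within half a window of an edge)")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_control is None:
        n_control = len(usable)
    eligible = np.arange(half, n - size + half)
    if control == "non_anchor_random":
        eligible = np.setdiff1d(eligible, np.asarray(bins))
    elif control != "random":
        raise ValueError("control must be 'non_anchor_random' or 'random'")
    if eligible.size == 0:
        raise ValueError("no eligible control bins")
    ctrl = rng.choice(eligible, size=min(n_control, eligible.size), replace=False)

    A, ka = _aggregate(matrix.counts, usable, half, size)
    C, kc = _aggregate(matrix.counts, sorted(int(c) for c in ctrl), half, size)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(A / C)
    ratio[(A == 0) | (C == 0)] = np.nan
    return PileupResult(ratio, A, C, ka, kc, skipped)
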