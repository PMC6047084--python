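"""Fragment maps and contact matrices.

A :class:`FragmentMap` holds the restriction fragments tiling each
chromosome; a :class:`ContactMatrix` is a dense symmetric count (or
normalized) matrix over fragments or fixed-size bins, with enough metadata
to map genomic coordinates to matrix axes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass
class FragmentMap:
    """Restriction fragments tiling each chromosome exactly."""

    boundaries: Dict[str, np.ndarray]  # chrom -> cut boundaries incl. 0 and L

    def __post_init__(self):
        for chrom, b in self.boundaries.items():
            b = np.asarray(b, dtype=np.int64)
            if b[0] != 0 or np.any(np.diff(b) <= 0):
                raise ValueError(f"bad fragment boundaries for {chrom}")
            self.boundaries[chrom] = b
        self.chroms: List[str] = list(self.boundaries)
        self._n = {c: len(b) - 1 for c, b in self.boundaries.items()}
        self._offset = {}
        off = 0
        for c in self.chroms:
            self._offset[c] = off
            off += self._n[c]
        self.n_fragments = off

    @classmethod
    def from_fragments(cls, fragments: Dict[str, Sequence[Tuple[int, int, int]]]):
        return cls(
            {
                c: np.array([f[0] for f in fr] + [fr[-1][1]], dtype=np.int64)
                for c, fr in fragments.items()
            }
        )

    def chrom_length(self, chrom: str) -> int:
        return int(self.boundaries[chrom][-1])

    def n_in(self, chrom: str) -> int:
        return self._n[chrom]

    def offset(self, chrom: str) -> int:
        return self._offset[chrom]

    def locate(self, chrom: str, pos) -> np.ndarray:
        """Global fragment index for position(s) on a chromosome."""
        b = self.boundaries[chrom]
        pos = np.asarray(pos)
        if np.any(pos < 0) or np.any(pos >= b[-1]):
            bad = pos[(pos < 0) | (pos >= b[-1])]
            raise ValueError(f"position(s) outside {chrom}: {bad[:5]}")
        return np.searchsorted(b, pos, side="right") - 1 + self._offset[chrom]

    def midpoints(self, chrom: Optional[str] = None) -> np.ndarray:
        if chrom is not None:
            b = self.boundaries[chrom]
            return (b[:-1] + b[1:]) / 2.0
        return np.concatenate([self.midpoints(c) for c in self.chroms])

    def lengths(self, chrom: Optional[str] = None) -> np.ndarray:
        if chrom is not None:
            return np.diff(self.boundaries[chrom])
        return np.concatenate([self.lengths(c) for c in self.chroms])

    def to_bed(self) -> pd.DataFrame:
        rows = []
        for c in self.chroms:
            b = self.boundaries[c]
            for i, (a, e) in enumerate(zip(b[:-1], b[1:])):
                rows.append((c, int(a), int(e), f"frag_{self._offset[c] + i}"))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


@dataclass
class ContactMatrix:
    """Symmetric contact matrix over fragments or fixed-size bins."""

    counts: np.ndarray
    bin_size: Optional[int]  # None for fragment-level
    chroms: List[Tuple[str, int]]  # (name, length in bp)
    normalized: bool = False
    total_contacts: Optional[int] = None
    positions: Optional[np.ndarray] = None  # axis midpoints (bp, concatenated)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be square")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    def chrom_bins(self, chrom: str) -> Tuple[int, int]:
        """Half-open bin-index range occupied by a chromosome."""
        start = 0
        for name, length in self.chroms:
            nb = self._nbins(length)
            if name == chrom:
                return start, start + nb
            start += nb
        raise KeyError(chrom)

    def _nbins(self, length: int) -> int:
        if self.bin_size is None:
            raise ValueError("fragment-level matrix has no fixed bin size")
        return -(-length // self.bin_size)

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            self.counts.copy(), self.bin_size, list(self.chroms), self.normalized,
            self.total_contacts,
            None if self.positions is None else self.positions.copy(),
        )


def n_bins(length: int, bin_size: int) -> int:
    return -(-length // bin_size)


def _locate_column(events, chrom_col, pos_col, fragment_map) -> np.ndarray:
    out = np.empty(len(events), dtype=np.int64)
    for chrom, idx in events.groupby(chrom_col, sort=False).indices.items():
        out[idx] = fragment_map.locate(chrom, events[pos_col].to_numpy()[idx])
    return out


def bin_matrix(
    events: pd.DataFrame,
    bin_size: Optional[int] = None,
    fragment_map: Optional[FragmentMap] = None,
    chroms: Optional[List[Tuple[str, int]]] = None,
) -> ContactMatrix:
    """Aggregate filtered events into a contact matrix.

    With ``bin_size`` None the axis is restriction fragments (requires
    ``fragment_map``).  With a fixed ``bin_size``, events that carry fragment
    assignments are binned by fragment midpoint (fragments are never split
    across bins); raw positions are used otherwise.
    """
    if bin_size is not None and bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if bin_size is None:
        if fragment_map is None:
            raise ValueError("fragment-level binning needs a fragment_map")
        n = fragment_map.n_fragments
        chrom_list = [(c, fragment_map.chrom_length(c)) for c in fragment_map.chroms]
        if len(events):
            if "frag1" in events.columns:
                i = events["frag1"].to_numpy(np.int64)
                j = events["frag2"].to_numpy(np.int64)
            else:
                i = _locate_column(events, "chrom1", "pos1", fragment_map)
                j = _locate_column(events, "chrom2", "pos2", fragment_map)
        positions = fragment_map.midpoints()
    else:
        if chroms is None:
            if fragment_map is not None:
                chroms = [(c, fragment_map.chrom_length(c)) for c in fragment_map.chroms]
            else:
                raise ValueError("fixed-size binning needs chroms=[(name, length)]")
        chrom_list = list(chroms)
        offsets, off = {}, 0
        for c, L in chrom_list:
            offsets[c] = off
            off += n_bins(L, bin_size)
        n = off
        if len(events):
            if "frag1" in events.columns and fragment_map is not None:
                mids = fragment_map.midpoints()
                g1 = events["frag1"].to_numpy(np.int64)
                g2 = events["frag2"].to_numpy(np.int64)
                p1, p2 = mids[g1], mids[g2]
            else:
                p1 = events["pos1"].to_numpy(float)
                p2 = events["pos2"].to_numpy(float)
            o1 = events["chrom1"].map(offsets).to_numpy(np.int64)
            o2 = events["chrom2"].map(offsets).to_numpy(np.int64)
            i = o1 + (p1 // bin_size).astype(np.int64)
            j = o2 + (p2 // bin_size).astype(np.int64)
        centers = []
        for c, L in chrom_list:
            nb = n_bins(L, bin_size)
            centers.append(np.arange(nb) * bin_size + bin_size / 2.0)
        positions = np.concatenate(centers) if centers else np.empty(0)

    M = np.zeros((n, n))
    total = 0
    if len(events):
        np.add.at(M, (i, j), 1.0)
        total = len(events)
        M = M + M.T
        np.fill_diagonal(M, np.diag(M) / 2.0)  # diagonal events counted once
    return ContactMatrix(
        M, bin_size, chrom_list, normalized=False, total_contacts=total,
        positions=positions,
    )


def rebin(matrix: ContactMatrix, factor: int) -> ContactMatrix:
    """Coarsen a binned matrix by an integer factor (block sums)."""
    if matrix.bin_size is None:
        raise ValueError("rebin requires a fixed-bin matrix")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    new_bs = matrix.bin_size * factor
    blocks = []
    starts = []
    s = 0
    for name, length in matrix.chroms:
        nb = n_bins(length, matrix.bin_size)
        starts.append((s, nb, n_bins(length, new_bs)))
        s += nb
    n_new = sum(t[2] for t in starts)
    M = np.zeros((n_new, n_new))
    # work on the doubled-diagonal representation so that block sums count
    # within-block pairs consistently; halve the new diagonal afterwards
    work = matrix.counts.copy()
    work[np.diag_indices_from(work)] *= 2.0
    # per-chromosome block aggregation (bins never span chromosomes)
    row_new = 0
    for (s1, nb1, nn1) in starts:
        col_new = 0
        for (s2, nb2, nn2) in starts:
            sub = work[s1 : s1 + nb1, s2 : s2 + nb2]
            agg = np.zeros((nn1, nn2))
            ridx = np.arange(nb1) // factor
            cidx = np.arange(nb2) // factor
            np.add.at(agg, (ridx[:, None], cidx[None, :]), sub)
            M[row_new : row_new + nn1, col_new : col_new + nn2] = agg
            col_new += nn2
        row_new += nn1
    M[np.diag_indices_from(M)] /= 2.0
    return ContactMatrix(
        M, new_bs, list(matrix.chroms), matrix.normalized, matrix.total_contacts
    )
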