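"""Restriction-site scanning, putative (Hamming-1) site discovery, digestion."""
from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple, Union

import numpy as np

from .records import DNA_ALPHABET, Enzyme, Mutation, SequenceRecord

SeqLike = Union[str, SequenceRecord]


def _as_str(seq: SeqLike) -> str:
    return seq.seq if isinstance(seq, SequenceRecord) else seq


def _validate(seq: str) -> None:
    bad = set(seq) - DNA_ALPHABET
    if bad:
        pos = next(i for i, b in enumerate(seq) if b in bad)
        raise ValueError(f"non-ACGT character {seq[pos]!r} at position {pos}")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _mismatch_profile(arr: np.ndarray, site: np.ndarray) -> np.ndarray:
    """Number of mismatches to ``site`` for every window start."""
    m, L = len(site), len(arr)
    if L < m:
        return np.empty(0, dtype=np.int16)
    mism = np.zeros(L - m + 1, dtype=np.int16)
    for k in range(m):
        mism += (arr[k : L - m + 1 + k] != site[k]).astype(np.int16)
    return mism


def scan_sites(seq: SeqLike, enzyme: Enzyme) -> List[int]:
    """Start positions of every exact recognition site (single-strand scan;
    the panel sites are palindromic so each site is found exactly once)."""
    s = _as_str(seq)
    _validate(s)
    mism = _mismatch_profile(_encode(s), _encode(enzyme.site))
    return np.flatnonzero(mism == 0).tolist()


def find_putative_sites(seq: SeqLike, enzyme: Enzyme) -> List[Tuple[int, Mutation]]:
    """Windows one substitution away from a recognition site.

    Returns ``(window_start, mutation)`` pairs where applying ``mutation``
    turns the window into an exact site.  Exact sites (distance 0) are
    excluded.
    """
    s = _as_str(seq)
    _validate(s)
    arr, site = _encode(s), _encode(enzyme.site)
    mism = _mismatch_profile(arr, site)
    out: List[Tuple[int, Mutation]] = []
    for p in np.flatnonzero(mism == 1):
        p = int(p)
        for k in range(len(site)):
            if arr[p + k] != site[k]:
                out.append(
                    (
                        p,
                        Mutation(
                            pos=p + k,
                            ref=chr(arr[p + k]),
                            alt=chr(site[k]),
                            reason="create_site",
                            enzyme=enzyme.name,
                        ),
                    )
                )
                break
    return out


def digest(
    seq: SeqLike, enzymes: Union[Enzyme, Iterable[Enzyme]]
) -> List[Tuple[int, int, int]]:
    """In-silico digestion: fragments ``(start, end, length)`` tiling [0, L).

    Cut coordinates are ``site start + cut_offset`` for every site of every
    enzyme; a multi-enzyme digestion is the union of cuts.
    """
    s = _as_str(seq)
    if isinstance(enzymes, Enzyme):
        enzymes = [enzymes]
    L = len(s)
    cuts = set()
    for enz in enzymes:
        for p in scan_sites(s, enz):
            c = p + enz.cut_offset
            if 0 < c < L:
                cuts.add(c)
    bounds = [0] + sorted(cuts) + [L]
    return [(a, b, b - a) for a, b in zip(bounds[:-1], bounds[1:])]


def fragment_lengths(fragments: Sequence[Tuple[int, int, int]]) -> np.ndarray:
    return np.array([f[2] for f in fragments], dtype=np.int64)
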