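"""PCRTag design: short windows that distinguish the designed sequence from
the native one under exact-match primer semantics.

A tag is a window where the two same-length, substitution-diverged sequences
differ at >= ``min_mismatches`` positions: a primer matching one template
exactly then has guaranteed mismatches on the other.  Windows inside CDS are
preferred; overlapping hits are resolved greedily left to right.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .mask import revcomp
from .records import Feature, SequenceRecord


@dataclass(frozen=True)
class PCRTag:
    start: int
    end: int
    syn_fwd: str
    syn_rev: str
    native_fwd: str
    native_rev: str
    n_mismatches: int
    in_cds: bool

    @property
    def locus(self):
        return (self.start, self.end)


def design_pcrtags(
    native: SequenceRecord,
    syn: SequenceRecord,
    tag_len: int = 20,
    min_mismatches: int = 3,
    features: Sequence[Feature] = (),
) -> List[PCRTag]:
    """Non-overlapping tag windows with clustered divergence.

    Identical inputs yield an empty list.  Each returned tag provides the
    forward primer and its reverse complement for both templates.
    """
    if len(native) != len(syn):
        raise ValueError("sequences must be the same length (substitution-only)")
    a = np.frombuffer(native.seq.encode(), dtype=np.uint8)
    b = np.frombuffer(syn.seq.encode(), dtype=np.uint8)
    diff = (a != b).astype(np.int32)
    L = len(diff)
    if tag_len > L or diff.sum() == 0:
        return []
    # mismatches per window via cumulative sum
    cs = np.concatenate([[0], np.cumsum(diff)])
    win = cs[tag_len:] - cs[:-tag_len]

    cds_mask = np.zeros(L, dtype=bool)
    for f in features:
        if f.kind == "CDS":
            cds_mask[f.start : f.end] = True

    tags: List[PCRTag] = []
    i = 0
    while i <= L - tag_len:
        if win[i] >= min_mismatches:
            # within the run of qualifying windows, prefer a CDS-contained one
            j = i
            best: Optional[int] = None
            while j <= L - tag_len and win[j] >= min_mismatches:
                if best is None or (
                    cds_mask[j : j + tag_len].all()
                    and not cds_mask[best : best + tag_len].all()
                ):
                    best = j
                j += 1
            s, e = best, best + tag_len
            tags.append(
                PCRTag(
                    start=s,
                    end=e,
                    syn_fwd=syn.seq[s:e],
                    syn_rev=revcomp(syn.seq[s:e]),
                    native_fwd=native.seq[s:e],
                    native_rev=revcomp(native.seq[s:e]),
                    n_mismatches=int(win[best]),
                    in_cds=bool(cds_mask[s:e].all()),
                )
            )
            i = j + tag_len  # no overlap with the consumed run
        else:
            i += 1
    return tags
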