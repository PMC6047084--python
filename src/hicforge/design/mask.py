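"""Forbidden-position mask and codon-level synonymy checks.

Annotated functional elements (TFBSs, ARS cores, intron borders, centromeres,
tRNAs, telomeres, start/stop codons of ORFs, ...) must never be touched by a
substitution.  Only CDS bodies (where synonymous changes are allowed) and
retrotransposons stay mutable.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np
from Bio.Data import CodonTable

from .records import Feature, MUTABLE_KINDS

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# codon -> amino acid, stops as '*', standard nuclear code
_table = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_table.forward_table)
for _stop in _table.stop_codons:
    CODON_TO_AA[_stop] = "*"


def revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class ForbiddenMask:
    mask: np.ndarray  # bool per position
    provenance: list = field(default_factory=list)

    def __getitem__(self, pos) -> bool:
        return bool(self.mask[pos])

    def __len__(self) -> int:
        return len(self.mask)

    def any_in(self, start: int, end: int) -> bool:
        return bool(self.mask[start:end].any())


def build_forbidden_mask(features: Iterable[Feature], L: int) -> ForbiddenMask:
    """Boolean mask of untouchable positions.

    Every annotated feature forbids its whole body except CDS (only its
    start and stop codons are forbidden) and retrotransposons (fully
    mutable).  Overlaps resolve as forbidden-wins.
    """
    mask = np.zeros(L, dtype=bool)
    provenance = []
    for f in features:
        if not (0 <= f.start and f.end <= L):
            raise ValueError(f"feature {f} outside [0, {L})")
        if f.kind == "CDS":
            mask[f.start : f.start + 3] = True
            mask[max(f.start, f.end - 3) : f.end] = True
        elif f.kind in MUTABLE_KINDS:  # retrotransposon
            continue
        else:
            mask[f.start : f.end] = True
        provenance.append(f.kind)
    return ForbiddenMask(mask, provenance)


class CdsIndex:
    """Maps positions to codon context and answers synonymy queries.

    Codons are read on the feature strand; a substitution overlapping
    several CDS must be synonymous in every one of them.
    """

    def __init__(self, features: Iterable[Feature]):
        self.cds: List[Feature] = sorted(
            (f for f in features if f.kind == "CDS"), key=lambda f: f.start
        )
        self._starts = np.array([f.start for f in self.cds], dtype=np.int64)
        self._max_len = max((len(f) for f in self.cds), default=0)

    def covering(self, pos: int) -> List[Feature]:
        if not self.cds:
            return []
        hi = int(np.searchsorted(self._starts, pos, side="right"))
        # CDS overlap is rare and shallow in yeast: a bounded lookback suffices
        return [f for f in self.cds[max(0, hi - 64) : hi] if f.start <= pos < f.end]

    @staticmethod
    def _codon_span(f: Feature, pos: int) -> Optional[tuple]:
        """(codon_index, [three genomic positions in feature-strand order])."""
        if f.strand == "+":
            idx = pos - (f.start + f.frame)
            if idx < 0:
                return None
            ci = idx // 3
            p0 = f.start + f.frame + 3 * ci
            span = [p0, p0 + 1, p0 + 2]
        else:
            idx = (f.end - 1 - f.frame) - pos
            if idx < 0:
                return None
            ci = idx // 3
            p0 = f.end - 1 - f.frame - 3 * ci
            span = [p0, p0 - 1, p0 - 2]
        if not all(f.start <= p < f.end for p in span):
            return None  # incomplete terminal codon
        return ci, span

    def codon_context(self, seq: Sequence[str], pos: int, alt: str):
        """(feature id, codon index, synonymous) for the first covering CDS,
        or None outside CDS."""
        for f in self.covering(pos):
            span = self._codon_span(f, pos)
            if span is None:
                return (f.id, -1, False)
            ci, positions = span
            return (f.id, ci, self._syn_one(seq, f, positions, pos, alt))
        return None

    def _syn_one(self, seq, f: Feature, positions, pos: int, alt: str) -> bool:
        def base(p):
            b = seq[p] if p != pos else alt
            return b if f.strand == "+" else b.translate(_COMPLEMENT)

        ref = "".join(
            (seq[p] if f.strand == "+" else seq[p].translate(_COMPLEMENT))
            for p in positions
        )
        mut = "".join(base(p) for p in positions)
        return CODON_TO_AA[ref] == CODON_TO_AA[mut]

    def is_synonymous(self, seq: Sequence[str], pos: int, alt: str) -> bool:
        """True iff substituting ``alt`` at ``pos`` preserves every
        overlapping protein (vacuously true outside CDS)."""
        for f in self.covering(pos):
            span = self._codon_span(f, pos)
            if span is None:
                return False  # cannot verify an incomplete codon: reject
            if not self._syn_one(seq, f, span[1], pos, alt):
                return False
        return True

    def in_cds(self, pos: int) -> bool:
        return bool(self.covering(pos))


def translate_cds(seq: str, f: Feature) -> str:
    """Protein (with '*' stops) of a CDS feature read on its strand."""
    sub = seq[f.start : f.end]
    if f.strand == "-":
        sub = revcomp(sub)
    sub = sub[f.frame :]
    return "".join(
        CODON_TO_AA[sub[i : i + 3]] for i in range(0, len(sub) - len(sub) % 3, 3)
    )
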