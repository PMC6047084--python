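"""Random annotated genomic windows for exercising the design engine.

Generates a sequence of alternating intergenic spacers and complete ORFs
(start codon, sense codons, stop codon, random strand) at a target coding
fraction, with optional extra forbidden features sprinkled into the
intergenic space — the annotation regime a designer faces on a real
chromosome window.
"""
from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from ..design.mask import CODON_TO_AA, revcomp
from ..design.records import Feature, SequenceRecord
from .model import _rng

SENSE_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")
STOPS = ("TAA", "TAG", "TGA")
BASES = "ACGT"


def _random_dna(n: int, rng) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _random_orf(n_codons: int, rng) -> str:
    body = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n_codons)]
    return "ATG" + "".join(body) + STOPS[rng.integers(0, 3)]


def make_annotated_window(
    L: int = 150_000,
    cds_fraction: float = 0.6,
    seed=None,
    mean_orf_codons: int = 350,
    extra_forbidden: Optional[List[Tuple[str, int]]] = None,
    id: str = "synthetic_window",
) -> Tuple[SequenceRecord, List[Feature]]:
    """A random window with complete ORFs covering ~``cds_fraction`` of it.

    The intergenic spacer length is set so that on average an ORF of
    ``mean_orf_codons`` codons occupies ``cds_fraction`` of each
    gene+spacer cycle.  ``extra_forbidden`` lists (kind, length) features to
    drop into intergenic space (e.g. ``[("ARS_core", 200), ("tRNA", 80)]``).
    """
    if not 0 < cds_fraction < 1:
        raise ValueError("cds_fraction must be in (0, 1)")
    rng = _rng(seed)
    mean_orf_len = mean_orf_codons * 3 + 6
    mean_gap = mean_orf_len * (1 - cds_fraction) / cds_fraction
    pieces: List[str] = []
    features: List[Feature] = []
    pos = 0
    gene_idx = 0
    extra = list(extra_forbidden or [])
    while pos < L:
        gap = max(50, int(rng.exponential(mean_gap)))
        gap_seq = _random_dna(min(gap, L - pos), rng)
        if extra and len(gap_seq) > extra[0][1] + 20:
            kind, flen = extra.pop(0)
            fstart = pos + 10
            features.append(Feature(kind, fstart, fstart + flen, id=f"{kind}_{fstart}"))
        pieces.append(gap_seq)
        pos += len(gap_seq)
        if pos >= L:
            break
        n_codons = max(30, int(rng.normal(mean_orf_codons, mean_orf_codons / 3)))
        orf = _random_orf(n_codons, rng)
        if pos + len(orf) > L:
            pieces.append(_random_dna(L - pos, rng))
            pos = L
            break
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            orf = revcomp(orf)
        features.append(
            Feature("CDS", pos, pos + len(orf), strand=strand, frame=0,
                    id=f"gene_{gene_idx}")
        )
        gene_idx += 1
        pieces.append(orf)
        pos += len(orf)
    seq = "".join(pieces)[:L]
    features = [f for f in features if f.end <= len(seq)]
    return SequenceRecord(id, seq), features
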