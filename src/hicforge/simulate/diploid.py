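"""Diploid homologs: substitution-diverged sequences and homolog-labelled
contact events with a tunable trans (inter-homolog) rate."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

from ..design.records import SequenceRecord
from .config import SyntheticConfig
from .model import _rng, build_contact_model, make_restriction_map, sample_reads

BASES = np.array(list("ACGT"))


def random_sequence(L: int, rng) -> str:
    return "".join(BASES[_rng(rng).integers(0, 4, size=L)])


def substitute(seq: str, snp_rate: float, rng) -> Tuple[str, np.ndarray]:
    """Apply i.i.d. substitutions; returns the new sequence and positions."""
    rng = _rng(rng)
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < snp_rate)
    for p in hits:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
    return "".join(arr), hits


@dataclass
class DiploidData:
    homolog1: SequenceRecord
    homolog2: SequenceRecord
    events: pd.DataFrame  # homolog-labelled read pairs
    snp_positions: np.ndarray


def make_diploid(config: SyntheticConfig, seed=None) -> DiploidData:
    """Two homologs plus homolog-labelled contact events.

    Cis pairs are split evenly between the homologs and drawn from the same
    pair model; a fraction ``trans_rate`` of pairs bridges the homologs,
    with the offset between the two loci drawn from a two-sided exponential
    pairing kernel concentrated at offset 0.  A read end is resolvable to a
    homolog only if its ``read_len`` window covers a substituted position;
    unresolvable ends get the label ``ambiguous``.
    """
    if config.diploid is None:
        raise ValueError("config.diploid must be set")
    spec = config.diploid
    rng = _rng(config.seed if seed is None else seed)
    L = config.L

    seq1 = random_sequence(L, rng)
    seq2, snps = substitute(seq1, spec.snp_rate, rng)
    h1 = SequenceRecord("hom1", seq1)
    h2 = SequenceRecord("hom2", seq2)

    fm = make_restriction_map(config, seed=rng)
    model = build_contact_model(fm, config, seed=rng)

    n_trans = int(rng.binomial(config.R, spec.trans_rate))
    n_cis = config.R - n_trans

    cis = sample_reads(model, n_cis, seed=rng)
    cis_hom = np.where(rng.random(n_cis) < 0.5, "hom1", "hom2")
    cis["homolog1"] = cis_hom
    cis["homolog2"] = cis_hom

    # trans pairs: locus on one homolog paired near the same coordinate on
    # the other
    lens = fm.lengths(config.chrom).astype(float)
    frag_p = lens / lens.sum()
    fi = rng.choice(lens.size, size=n_trans, p=frag_p)
    b = fm.boundaries[config.chrom]
    pos1 = rng.integers(b[:-1][fi], b[1:][fi]) if n_trans else np.empty(0, dtype=int)
    offset = rng.exponential(spec.pairing_scale, size=n_trans) * rng.choice(
        [-1.0, 1.0], size=n_trans
    )
    pos2 = np.clip(np.rint(pos1 + offset), 0, L - 1).astype(np.int64)
    first_is_h1 = rng.random(n_trans) < 0.5
    strands = np.array(["+", "-"])
    trans = pd.DataFrame(
        {
            "chrom1": np.full(n_trans, config.chrom, dtype=object),
            "pos1": np.minimum(pos1, pos2),
            "strand1": strands[rng.integers(0, 2, size=n_trans)],
            "chrom2": np.full(n_trans, config.chrom, dtype=object),
            "pos2": np.maximum(pos1, pos2),
            "strand2": strands[rng.integers(0, 2, size=n_trans)],
            "homolog1": np.where(first_is_h1, "hom1", "hom2"),
            "homolog2": np.where(first_is_h1, "hom2", "hom1"),
        }
    )

    events = pd.concat([cis, trans], ignore_index=True)
    events = events.iloc[rng.permutation(len(events))].reset_index(drop=True)

    # mappability: an end is homolog-resolvable iff its read window covers a
    # substituted position
    if spec.mappability and len(snps):
        for side in ("1", "2"):
            pos = events[f"pos{side}"].to_numpy(np.int64)
            k = np.searchsorted(snps, pos, side="left")
            nxt = snps[np.minimum(k, len(snps) - 1)]
            covered = (nxt >= pos) & (nxt < pos + spec.read_len)
            events[f"resolvable{side}"] = covered
            events.loc[~covered, f"homolog{side}"] = "ambiguous"
    return DiploidData(h1, h2, events, snps)
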