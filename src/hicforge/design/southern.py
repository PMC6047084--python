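"""Predicted Southern-blot fragment lengths at a probed locus.

Two homologs diverged only by substitutions share a coordinate system, so a
restriction-site polymorphism turns each parent's probed fragment into a
distinct band, and a crossover between the two flanking cuts produces the
two reciprocal recombinant bands.  Parental lengths always sum to the
recombinant lengths (boundary arithmetic).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Tuple, Union

from .mask import revcomp
from .records import Enzyme, SequenceRecord
from .sites import digest


class SouthernError(ValueError):
    pass


@dataclass(frozen=True)
class SouthernPrediction:
    parental_native: int
    parental_syn: int
    recombinant_small: int
    recombinant_large: int
    probe: Tuple[int, int]

    def as_dict(self) -> Dict[str, int]:
        return {
            "parental_native": self.parental_native,
            "parental_syn": self.parental_syn,
            "recombinant_small": self.recombinant_small,
            "recombinant_large": self.recombinant_large,
        }


def _locate_once(seq: str, primer: str, name: str) -> int:
    n = seq.count(primer)
    if n == 0:
        raise SouthernError(f"primer {name!r} not found")
    if n > 1:
        raise SouthernError(f"primer {name!r} matches {n} times")
    return seq.index(primer)


def probe_interval(seq: str, primer_fwd: str, primer_rev: str) -> Tuple[int, int]:
    """Span from the forward primer start to the end of the reverse primer's
    (reverse-complement) match downstream."""
    f = _locate_once(seq, primer_fwd, "forward")
    rc = revcomp(primer_rev)
    r = _locate_once(seq, rc, "reverse")
    end = r + len(rc)
    if end <= f:
        raise SouthernError("reverse primer does not lie downstream of forward primer")
    return f, end


def _fragment_over(fragments, start: int, end: int) -> Tuple[int, int]:
    for a, b, _ in fragments:
        if a <= start and end <= b:
            return a, b
    raise SouthernError(
        f"probe [{start}, {end}) spans a cut site; it must sit inside one fragment"
    )


def predict_southern(
    native: SequenceRecord,
    syn: SequenceRecord,
    primer_fwd: str,
    primer_rev: str,
    enzymes: Iterable[Enzyme],
) -> SouthernPrediction:
    """Parental and crossover band lengths for a probe amplified by the two
    primers, after digestion with ``enzymes``.

    Parent fragments are the digestion fragments containing the probe;
    recombinants pair the left boundary of one parent with the right
    boundary of the other.
    """
    if len(native) != len(syn):
        raise SouthernError("homologs must be the same length (substitution-only)")
    enzymes = list(enzymes)
    p_start, p_end = probe_interval(native.seq, primer_fwd, primer_rev)
    # probe must sit at the same coordinates on both homologs
    q_start, q_end = probe_interval(syn.seq, primer_fwd, primer_rev)
    if (p_start, p_end) != (q_start, q_end):
        raise SouthernError("probe locates at different coordinates on the homologs")

    nat_a, nat_b = _fragment_over(digest(native, enzymes), p_start, p_end)
    syn_a, syn_b = _fragment_over(digest(syn, enzymes), p_start, p_end)

    rec1 = nat_b - syn_a  # native right boundary with designed left boundary
    rec2 = syn_b - nat_a
    return SouthernPrediction(
        parental_native=nat_b - nat_a,
        parental_syn=syn_b - syn_a,
        recombinant_small=min(rec1, rec2),
        recombinant_large=max(rec1, rec2),
        probe=(p_start, p_end),
    )


def predict_from_cuts(
    native_cuts: Iterable[int],
    syn_cuts: Iterable[int],
    probe_pos: int,
    L: int,
) -> SouthernPrediction:
    """Same boundary arithmetic from bare cut coordinates (no sequences)."""
    def frag(cuts):
        bounds = [0] + sorted(cuts) + [L]
        for a, b in zip(bounds[:-1], bounds[1:]):
            if a <= probe_pos < b:
                return a, b
        raise SouthernError("probe outside [0, L)")

    na, nb = frag(native_cuts)
    sa, sb = frag(syn_cuts)
    rec1, rec2 = nb - sa, sb - na
    return SouthernPrediction(
        parental_native=nb - na,
        parental_syn=sb - sa,
        recombinant_small=min(rec1, rec2),
        recombinant_large=max(rec1, rec2),
        probe=(probe_pos, probe_pos + 1),
    )
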